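"""LD-block construction from index SNPs and proxy tables.

An LD block is the min-to-max span of the proxies in high linkage
disequilibrium (r^2 >= 0.9 within 500 kb, the SNAP-style defaults) with a
genotyped index SNP, the index SNP's own position included. Index SNPs whose
blocks have identical spans are grouped into a single block, mirroring how
risk loci sharing a haplotype are reported as one region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genomic_intervals import GenomicInterval

_FIXTURE = "jia_ld_blocks_table.tsv"

PROXY_COLUMNS = ["index_snp", "proxy_snp", "chrom", "position", "r2", "distance"]


@dataclass(frozen=True)
class ProxyRecord:
    """One proxy-SNP row of a SNAP-style query: position is 1-based."""

    index_snp: str
    proxy_snp: str
    chrom: str
    position: int
    r2: float
    distance: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")
        if self.distance < 0:
            raise ValueError(f"distance must be >= 0, got {self.distance}")


@dataclass(frozen=True)
class LDConfig:
    """Proxy-filtering settings: minimum r^2 and maximum distance (kb) from the index SNP."""

    r2_threshold: float = 0.9
    distance_limit_kb: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError(f"r2_threshold must be in (0, 1], got {self.r2_threshold}")
        if self.distance_limit_kb <= 0:
            raise ValueError(f"distance_limit_kb must be > 0, got {self.distance_limit_kb}")


@dataclass
class LDBlock:
    """A risk locus: the span of an index-SNP group plus its member SNPs."""

    block_id: str
    chrom: str
    span: GenomicInterval
    member_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.member_snps:
            raise ValueError("LDBlock requires at least one member SNP")
        if self.span.chrom != self.chrom:
            raise ValueError("span chromosome does not match block chromosome")


def define_ld_block(
    index_snp: str,
    proxies: Sequence[ProxyRecord],
    config: LDConfig = LDConfig(),
    index_position: int | None = None,
) -> LDBlock:
    """Build one block: filter proxies, then span = [min, max] of surviving positions.

    Positions are 1-based (as queried); the stored span is converted to the
    internal 0-based half-open convention. The index SNP's own position (from a
    self-proxy row or ``index_position``) always enters the min/max, so an index
    with zero passing proxies yields a degenerate 1-bp block.
    """
    chroms = {p.chrom for p in proxies}
    if len(chroms) > 1:
        raise ValueError(f"proxies for {index_snp} span multiple chromosomes: {sorted(chroms)}")
    wrong = [p for p in proxies if p.index_snp != index_snp]
    if wrong:
        raise ValueError(f"proxy rows reference a different index SNP than {index_snp}")

    positions = [
        p.position
        for p in proxies
        if p.r2 >= config.r2_threshold and p.distance <= config.distance_limit_kb * 1000
    ]
    if index_position is not None:
        positions.append(index_position)
    else:
        self_rows = [p.position for p in proxies if p.proxy_snp == index_snp]
        positions.extend(self_rows)
    if not positions:
        raise ValueError(
            f"no proxies for {index_snp} pass r2 >= {config.r2_threshold} and "
            f"no index position was supplied"
        )
    chrom = chroms.pop() if chroms else None
    if chrom is None:
        raise ValueError(f"cannot determine chromosome for {index_snp}")
    lo, hi = min(positions), max(positions)
    # 1-based inclusive [lo, hi] -> 0-based half-open [lo-1, hi); lo == hi gives 1 bp
    span = GenomicInterval(chrom, lo - 1, hi, name=index_snp)
    return LDBlock(block_id=index_snp, chrom=chrom, span=span, member_snps=[index_snp])


def group_snps_into_blocks(blocks: Iterable[LDBlock]) -> list[LDBlock]:
    """Merge blocks with identical (chrom, span); overlapping-but-unequal spans stay distinct.

    Exact span equality is the merge criterion: two overlapping risk loci with
    different proxy sets remain separate blocks. Idempotent.
    """
    merged: dict[tuple, LDBlock] = {}
    for b in blocks:
        key = (b.chrom, b.span.start, b.span.end)
        if key in merged:
            existing = merged[key]
            for snp in b.member_snps:
                if snp not in existing.member_snps:
                    existing.member_snps.append(snp)
        else:
            merged[key] = LDBlock(
                block_id=b.block_id,
                chrom=b.chrom,
                span=b.span,
                member_snps=list(b.member_snps),
            )
    out = sorted(merged.values(), key=lambda b: (b.chrom, b.span.start, b.span.end))
    for b in out:
        b.member_snps.sort()
        b.block_id = ";".join(b.member_snps)
    return out


def read_proxy_table(path: str | Path) -> list[ProxyRecord]:
    """TSV with columns index_snp, proxy_snp, chrom, position, r2, distance."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PROXY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"proxy table missing columns: {sorted(missing)}")
    return [
        ProxyRecord(
            index_snp=str(r.index_snp),
            proxy_snp=str(r.proxy_snp),
            chrom=str(r.chrom),
            position=int(r.position),
            r2=float(r.r2),
            distance=int(r.distance),
        )
        for r in df.itertuples(index=False)
    ]


def blocks_from_proxy_table(
    path: str | Path, config: LDConfig = LDConfig()
) -> list[LDBlock]:
    """Read a proxy table, build one block per index SNP, and group identical spans."""
    proxies = read_proxy_table(path)
    by_index: dict[str, list[ProxyRecord]] = {}
    for p in proxies:
        by_index.setdefault(p.index_snp, []).append(p)
    blocks = [define_ld_block(snp, rows, config) for snp, rows in by_index.items()]
    return group_snps_into_blocks(blocks)


def write_blocks_bed(blocks: Iterable[LDBlock], path: str | Path) -> None:
    """BED4: member SNPs semicolon-separated in the name column."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.span.start}\t{b.span.end}\t{';'.join(b.member_snps)}\n")


def load_table1_fixture() -> tuple[list[LDBlock], pd.DataFrame]:
    """The packaged 23-region JIA risk-locus table with its histone-mark matrix.

    Returns the blocks (coordinates converted from the printed 1-based inclusive
    spans to the internal convention) and a DataFrame with boolean columns
    neutrophil_h3k4me1 / neutrophil_h3k27ac / cd4_h3k4me1 / cd4_h3k27ac indexed
    by block_id.
    """
    with resources.files("ldscape.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    blocks = []
    for r in df.itertuples(index=False):
        snps = r.snps.split(",")
        span = GenomicInterval(r.chrom, int(r.start) - 1, int(r.end))
        blocks.append(
            LDBlock(block_id=";".join(snps), chrom=r.chrom, span=span, member_snps=snps)
        )
    marks = df[
        ["neutrophil_h3k4me1", "neutrophil_h3k27ac", "cd4_h3k4me1", "cd4_h3k27ac"]
    ].apply(lambda col: col.map({"Y": True, "N": False}))
    marks.index = pd.Index([b.block_id for b in blocks], name="block_id")
    return blocks, marks
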