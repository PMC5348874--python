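"""Gene models with strand-aware TSS and promoter windows; FPKM tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genomic_intervals import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

# promoter window: 5 kb upstream to 1 kb downstream of the TSS
DEFAULT_PROMOTER_WINDOW = (5000, 1000)


@dataclass(frozen=True)
class GeneModel:
    """A gene body [start, end) with strand; the TSS is the strand-aware 5' end."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str | None = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    @property
    def effective_strand(self) -> str:
        """Missing strand is treated as plus (logged at parse time)."""
        return self.strand if self.strand in ("+", "-") else "+"

    @property
    def tss(self) -> int:
        return self.start if self.effective_strand == "+" else self.end

    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id,
                               strand=self.effective_strand)

    def promoter(self, upstream: int = 5000, downstream: int = 1000) -> GenomicInterval | None:
        """[TSS-upstream, TSS+downstream) on the plus strand, mirrored on minus.

        Returns None for a zero-width window (upstream = downstream = 0).
        """
        if self.effective_strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream, self.tss + upstream
        lo = max(lo, 0)
        if hi <= lo:
            return None
        return GenomicInterval(self.chrom, lo, hi, name=self.gene_id)


def promoter_windows(
    genes: Iterable[GeneModel],
    window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> IntervalSet:
    """Strand-aware promoter windows for a gene set, as a normalized IntervalSet."""
    upstream, downstream = window
    ivs = []
    for g in genes:
        p = g.promoter(upstream, downstream)
        if p is not None:
            ivs.append(p)
    return IntervalSet(ivs)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Minimal gene-model TSV: gene_id, chrom, start, end, strand (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    genes = []
    n_unstranded = 0
    for r in df.itertuples(index=False):
        strand = r.strand if r.strand in ("+", "-") else None
        if strand is None:
            n_unstranded += 1
        genes.append(GeneModel(str(r.gene_id), str(r.chrom), int(r.start), int(r.end), strand))
    if n_unstranded:
        logger.warning("%d genes lack strand; treated as plus strand", n_unstranded)
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand or ".") for g in genes],
        columns=GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_fpkm_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (gene_id, fpkm) -> mapping; FPKM must be >= 0."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("FPKM table needs two columns (gene_id, fpkm)")
    gene_col, fpkm_col = df.columns[:2]
    out: dict[str, float] = {}
    for r in df.itertuples(index=False):
        val = float(getattr(r, fpkm_col))
        if val < 0:
            raise ValueError(f"negative FPKM for {getattr(r, gene_col)}")
        out[str(getattr(r, gene_col))] = val
    return out


def write_fpkm_table(fpkm: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(sorted(fpkm.items()), columns=["gene_id", "fpkm"]).to_csv(
        path, sep="\t", index=False
    )
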