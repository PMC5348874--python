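"""Seeded generator for every input the pipeline consumes, with planted ground truth.

The generator emulates the study's data sources on a small toy genome (one
2-Mb and one 1-Mb chromosome by default): proxy tables that reconstruct the
planted LD-block spans exactly, ChIP-Seq-style histone peak BEDs per cell
type, a clustered-TFBS-style BED with per-TF in-block enrichment multipliers,
gene models, a BEDPE interaction catalogue with planted pair classes, anchor
histone categories and duplicates, and an FPKM table whose both-marks genes
are shifted upward. Identical seeds yield byte-identical bundles.

Peaks and TFBS follow a thinned Poisson placement: a background rate per kb
outside blocks, multiplied by theta inside blocks. ``peak_mode="binwise"``
instead draws an independent Bernoulli per genome bin and emits bin-aligned
peaks; under theta = 1 this realizes the exact null of the binned Fisher test
and is the mode used for calibration studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chia_pet import ChIAInteraction, write_bedpe
from .gene_models import GeneModel, write_fpkm_table, write_gene_table
from .genomic_intervals import (
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_chrom_sizes,
)
from .ld_blocks import LDBlock, load_table1_fixture, write_blocks_bed
from .tfbs_enrichment import TFEnrichmentResult

CELL_MARKS = (
    ("neutrophil", "h3k4me1"),
    ("neutrophil", "h3k27ac"),
    ("cd4_t", "h3k4me1"),
    ("cd4_t", "h3k27ac"),
)

# zone boundaries as fractions of each chromosome: blocks | genes | gene desert
_BLOCK_ZONE_END = 0.60
_GENE_ZONE_END = 0.85
_DESERT_MARGIN = 6_000  # keeps desert anchors clear of gene-zone promoter spill


@dataclass(frozen=True)
class TFSpec:
    """One synthetic TF: background site rate (per kb) and in-block multiplier."""

    name: str
    site_rate_per_kb: float = 0.2
    theta: float = 1.0

    def __post_init__(self) -> None:
        if self.site_rate_per_kb < 0 or self.theta <= 0:
            raise ValueError("site rate must be >= 0 and theta > 0")


@dataclass(frozen=True)
class InteractionSpec:
    """Planted interaction counts: pair classes, duplicates, decoys, anchor categories.

    Defaults mirror the study's in-block tallies: 42 unique interactions
    (20 promoter-promoter, 21 promoter-distal, 1 distal-distal), 6 duplicate
    records (48 in-block records in all), and an 84-anchor histone-category
    split of 66 both / 2 ac-only / 11 me1-only / 5 neither.
    """

    n_promoter_promoter: int = 20
    n_promoter_distal: int = 21
    n_distal_distal: int = 1
    n_duplicates: int = 6
    n_decoys: int = 6
    anchor_category_counts: dict | None = field(
        default_factory=lambda: {"both_marks": 66, "ac_only": 2, "me1_only": 11, "neither": 5}
    )

    @property
    def n_unique(self) -> int:
        return self.n_promoter_promoter + self.n_promoter_distal + self.n_distal_distal

    def __post_init__(self) -> None:
        if self.n_duplicates > self.n_unique:
            raise ValueError("cannot duplicate more interactions than exist")
        if self.anchor_category_counts is not None:
            total = sum(self.anchor_category_counts.values())
            if total != 2 * self.n_unique:
                raise ValueError(
                    f"anchor category counts sum to {total}, expected {2 * self.n_unique}"
                )


@dataclass(frozen=True)
class FPKMSpec:
    """Lognormal expression model; both-marks genes get a multiplicative shift."""

    log_mean: float = 1.5
    log_sigma: float = 1.0
    both_marks_multiplier: float = 4.0


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_sizes: dict = field(
        default_factory=lambda: {"chrS1": 2_000_000, "chrS2": 1_000_000}
    )
    bin_size: int = 100
    n_blocks: int = 12
    block_width_range: tuple[int, int] = (40_000, 80_000)
    n_multi_snp_blocks: int = 1  # blocks carrying two index SNPs with identical spans
    peak_rate_out: float = 0.05  # peaks per kb outside blocks
    theta_peak: float = 5.0
    peak_width_range: tuple[int, int] = (200, 1_000)
    peak_mode: str = "poisson"  # or "binwise"
    tf_specs: list = field(
        default_factory=lambda: [
            TFSpec("TF_ENR1", 0.2, 5.0),
            TFSpec("TF_ENR2", 0.2, 5.0),
            TFSpec("TF_NULL1", 0.2, 1.0),
            TFSpec("TF_NULL2", 0.2, 1.0),
            TFSpec("TF_DEP1", 0.2, 0.2),
        ]
    )
    tf_site_width_range: tuple[int, int] = (100, 300)
    n_genes: int = 30
    gene_width_range: tuple[int, int] = (5_000, 30_000)
    interaction_spec: InteractionSpec | None = field(default_factory=InteractionSpec)
    fpkm_spec: FPKMSpec = field(default_factory=FPKMSpec)
    planted_mark_flags: dict | None = None  # {(cell_type, mark): {block_id: bool}}

    def __post_init__(self) -> None:
        if self.peak_rate_out < 0 or self.theta_peak <= 0:
            raise ValueError("rates must be >= 0 and theta_peak > 0")
        if self.peak_mode not in ("poisson", "binwise"):
            raise ValueError(f"unknown peak_mode {self.peak_mode!r}")


@dataclass
class GroundTruth:
    blocks: list  # LDBlock
    mark_flags: dict  # {(cell_type, mark): {block_id: bool}} realized flags
    tf_truth: dict  # {tf_name: TFSpec}
    interaction_truth: pd.DataFrame
    gene_truth: pd.DataFrame


@dataclass
class SyntheticBundle:
    outdir: Path
    paths: dict
    truth: GroundTruth


# ---------------------------------------------------------------- placement


def _place_blocks(rng: np.random.Generator, config: SyntheticConfig) -> list[LDBlock]:
    """Non-overlapping blocks in the block zone, filled chromosome by chromosome."""
    lo_w, hi_w = config.block_width_range
    blocks: list[LDBlock] = []
    i = 0
    snp_no = 0
    for chrom, size in config.chrom_sizes.items():
        zone_end = int(size * _BLOCK_ZONE_END)
        cursor = int(rng.integers(2_000, 10_000))
        while i < config.n_blocks:
            width = int(rng.integers(lo_w, hi_w + 1))
            if cursor + width > zone_end:
                break
            span = GenomicInterval(chrom, cursor, cursor + width)
            n_snps = 2 if i < config.n_multi_snp_blocks else 1
            snps = [f"snp{snp_no + k:03d}" for k in range(n_snps)]
            snp_no += n_snps
            blocks.append(
                LDBlock(block_id=";".join(snps), chrom=chrom, span=span, member_snps=snps)
            )
            cursor += width + int(rng.integers(5_000, 20_000))
            i += 1
    if i < config.n_blocks:
        raise ValueError(
            f"infeasible placement: only {i} of {config.n_blocks} blocks fit the block zone"
        )
    return blocks


def _block_segments(
    config: SyntheticConfig, blocks: Sequence[LDBlock]
) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_sizes}
    for b in blocks:
        by_chrom[b.chrom].append((b.span.start, b.span.end))
    for segs in by_chrom.values():
        segs.sort()
    return by_chrom


def _sample_poisson_intervals(
    rng: np.random.Generator,
    config: SyntheticConfig,
    block_segs: dict[str, list[tuple[int, int]]],
    rate_out_per_kb: float,
    theta: float,
    width_range: tuple[int, int],
    name: str | None = None,
) -> list[GenomicInterval]:
    """Thinned Poisson placement: rate theta x rate inside blocks, rate outside."""
    lo_w, hi_w = width_range
    out: list[GenomicInterval] = []
    for chrom, size in config.chrom_sizes.items():
        # complement segments around blocks
        segments: list[tuple[int, int, float]] = []
        prev = 0
        for s, e in block_segs.get(chrom, []):
            if s > prev:
                segments.append((prev, s, rate_out_per_kb))
            segments.append((s, e, rate_out_per_kb * theta))
            prev = e
        if prev < size:
            segments.append((prev, size, rate_out_per_kb))
        for s, e, rate in segments:
            lam = rate * (e - s) / 1000.0
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            starts = np.sort(rng.integers(s, e, size=n))
            widths = rng.integers(lo_w, hi_w + 1, size=n)
            for st, w in zip(starts, widths):
                out.append(GenomicInterval(chrom, int(st), min(int(st + w), size), name=name))
    return out


def _sample_binwise_intervals(
    rng: np.random.Generator,
    config: SyntheticConfig,
    block_segs: dict[str, list[tuple[int, int]]],
    rate_out_per_kb: float,
    theta: float,
) -> list[GenomicInterval]:
    """Independent Bernoulli per bin; emitted as bin-aligned peaks.

    Per-bin probability is rate x bin width (capped at 1), times theta for bins
    whose start lies in a block; under theta = 1 the binned Fisher null holds
    exactly.
    """
    w = config.bin_size
    p_out = min(rate_out_per_kb * w / 1000.0, 1.0)
    p_in = min(p_out * theta, 1.0)
    out: list[GenomicInterval] = []
    for chrom, size in config.chrom_sizes.items():
        starts = np.arange(0, size, w)
        p = np.full(starts.size, p_out)
        for s, e in block_segs.get(chrom, []):
            p[(starts >= s - w + 1) & (starts < e)] = p_in
        hit = rng.random(starts.size) < p
        for st in starts[hit]:
            out.append(GenomicInterval(chrom, int(st), min(int(st) + w, size)))
    return out


def simulate_mark_dataset(
    rng: np.random.Generator, config: SyntheticConfig
) -> tuple[IntervalSet, IntervalSet]:
    """(block spans, peaks) without file output — the fast path for replicate studies."""
    blocks = _place_blocks(rng, config)
    segs = _block_segments(config, blocks)
    if config.peak_mode == "binwise":
        peaks = _sample_binwise_intervals(rng, config, segs, config.peak_rate_out,
                                          config.theta_peak)
    else:
        peaks = _sample_poisson_intervals(rng, config, segs, config.peak_rate_out,
                                          config.theta_peak, config.peak_width_range)
    return IntervalSet([b.span for b in blocks], normalize=False), IntervalSet(peaks)


def simulate_tf_stratum(
    rng: np.random.Generator,
    tf_specs: Sequence[TFSpec],
    n_in: int,
    n_out: int,
    p_out: float,
    mark: str = "H3K4me1",
    region_class: str = "distal",
) -> list[TFEnrichmentResult]:
    """Bin-level draw of one enrichment stratum: binomial site counts per TF.

    ``n_in``/``n_out`` are the marked background bins inside/outside LD blocks;
    each bin carries a site of a TF independently with probability p_out
    (theta x p_out inside blocks). Returns count-only results ready for
    ``fisher_fdr``.
    """
    results = []
    for spec in tf_specs:
        p_in = min(spec.theta * p_out, 1.0)
        a = int(rng.binomial(n_in, p_in))
        c = int(rng.binomial(n_out, p_out))
        results.append(
            TFEnrichmentResult(
                tf_name=spec.name,
                mark=mark,
                region_class=region_class,
                counts=np.array([[a, n_in - a], [c, n_out - c]], dtype=np.int64),
            )
        )
    return results


# ---------------------------------------------------------------- full bundle


def _plant_gene_slots(
    blocks: Sequence[LDBlock], n_needed: int, gene_width: int = 2_000
) -> tuple[list[GeneModel], LDBlock]:
    """Plus-strand genes inside blocks, promoter window fully in-block.

    The last block is kept gene-free (it hosts distal in-block anchors); raises
    if the remaining blocks cannot host ``n_needed`` genes.
    """
    slot = 5_000 + gene_width + 1_000 + 1_000  # promoter + body + downstream + gap
    genes: list[GeneModel] = []
    host_blocks = list(blocks[:-1]) if len(blocks) > 1 else list(blocks)
    free_block = blocks[-1]
    k = 0
    for b in host_blocks:
        cursor = b.span.start + 5_000
        while cursor + gene_width + 1_000 <= b.span.end and k < n_needed:
            genes.append(GeneModel(f"bgene{k:03d}", b.chrom, cursor, cursor + gene_width, "+"))
            cursor += slot
            k += 1
    if k < n_needed:
        raise ValueError(
            f"infeasible placement: only {k} of {n_needed} in-block gene slots available"
        )
    return genes, free_block


def _background_genes(
    rng: np.random.Generator, config: SyntheticConfig
) -> list[GeneModel]:
    lo_w, hi_w = config.gene_width_range
    genes: list[GeneModel] = []
    k = 0
    for chrom, size in config.chrom_sizes.items():
        zone_start = int(size * _BLOCK_ZONE_END) + _DESERT_MARGIN
        zone_end = int(size * _GENE_ZONE_END)
        cursor = zone_start + int(rng.integers(0, 5_000))
        while k < config.n_genes:
            width = int(rng.integers(lo_w, hi_w + 1))
            if cursor + width > zone_end:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{k:03d}", chrom, cursor, cursor + width, strand))
            cursor += width + int(rng.integers(2_000, 10_000))
            k += 1
    return genes


def _desert_positions(
    config: SyntheticConfig, chrom: str, n: int, width: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Anchor intervals inside the gene desert of one chromosome."""
    size = config.chrom_sizes[chrom]
    lo = int(size * _GENE_ZONE_END) + _DESERT_MARGIN
    hi = size - width - 1
    if lo >= hi or (hi - lo) < n * (width + 200):
        raise ValueError("infeasible placement: gene desert too small for distal anchors")
    starts = np.sort(rng.choice(np.arange(lo, hi - width, width + 200), size=n, replace=False))
    return [GenomicInterval(chrom, int(s), int(s) + width) for s in starts]


def _build_interactions(
    rng: np.random.Generator,
    config: SyntheticConfig,
    blocks: Sequence[LDBlock],
) -> tuple[list[ChIAInteraction], list[GeneModel], pd.DataFrame, dict[tuple, str]]:
    """Planted interactions + the in-block genes supporting them + truth table."""
    spec = config.interaction_spec
    assert spec is not None
    anchor_w = 2_000
    n_promoter_in_block = spec.n_promoter_promoter + spec.n_promoter_distal
    planted, free_block = _plant_gene_slots(blocks, n_promoter_in_block)
    chroms = list(config.chrom_sizes)
    desert_chrom = chroms[0]
    # partner promoters for PP pairs come from background-zone genes planted here
    partner_genes: list[GeneModel] = []
    partner_chrom = chroms[-1]
    size = config.chrom_sizes[partner_chrom]
    # fixed grid in the gene zone; overlap with background genes is harmless
    # (a promoter anchor stays a promoter anchor)
    cursor = int(size * _BLOCK_ZONE_END) + _DESERT_MARGIN
    grid = 9_000
    for k in range(spec.n_promoter_promoter):
        start = cursor + k * grid
        if start + 3_000 > int(size * _GENE_ZONE_END):
            raise ValueError("infeasible placement: no room for partner promoter genes")
        partner_genes.append(GeneModel(f"pgene{k:03d}", partner_chrom, start, start + 2_000, "+"))

    def promoter_anchor(g: GeneModel) -> GenomicInterval:
        # centered on the TSS: overlaps [TSS-5k, TSS+1k) and, for planted genes, the block
        return GenomicInterval(g.chrom, g.tss - anchor_w // 2, g.tss + anchor_w // 2)

    interactions: list[ChIAInteraction] = []
    rows = []
    n_dd = spec.n_distal_distal
    desert_anchors = _desert_positions(
        config, desert_chrom, spec.n_promoter_distal + n_dd, anchor_w, rng
    )
    # distal in-block anchors for DD pairs live in the gene-free block
    dd_cursor = free_block.span.start + 1_000
    idx = 0
    for k in range(spec.n_promoter_promoter):
        a = promoter_anchor(planted[idx]); idx += 1
        b = promoter_anchor(partner_genes[k])
        interactions.append(ChIAInteraction.make(a, b, f"ia{len(interactions):03d}"))
        rows.append(("promoter_promoter",))
    for k in range(spec.n_promoter_distal):
        a = promoter_anchor(planted[idx]); idx += 1
        b = desert_anchors[k]
        interactions.append(ChIAInteraction.make(a, b, f"ia{len(interactions):03d}"))
        rows.append(("promoter_distal",))
    for k in range(n_dd):
        a = GenomicInterval(free_block.chrom, dd_cursor, dd_cursor + anchor_w)
        dd_cursor += anchor_w + 500
        if dd_cursor > free_block.span.end:
            raise ValueError("infeasible placement: gene-free block too small for DD anchors")
        b = desert_anchors[spec.n_promoter_distal + k]
        interactions.append(ChIAInteraction.make(a, b, f"ia{len(interactions):03d}"))
        rows.append(("distal_distal",))

    # planted anchor histone categories over the unique anchors
    anchor_keys: list[tuple] = []
    seen = set()
    for it in interactions:
        for anchor in (it.anchor_a, it.anchor_b):
            key = (anchor.chrom, anchor.start, anchor.end)
            if key not in seen:
                seen.add(key)
                anchor_keys.append(key)
    categories: dict[tuple, str] = {}
    if spec.anchor_category_counts is not None:
        labels = [c for c, n in sorted(spec.anchor_category_counts.items()) for _ in range(n)]
        if len(labels) != len(anchor_keys):
            raise ValueError(
                f"{len(anchor_keys)} unique anchors but {len(labels)} category labels"
            )
        order = rng.permutation(len(labels))
        categories = {anchor_keys[i]: labels[order[i]] for i in range(len(labels))}

    truth_rows = []
    for it, (pair_class,) in zip(interactions, rows):
        ka = (it.anchor_a.chrom, it.anchor_a.start, it.anchor_a.end)
        kb = (it.anchor_b.chrom, it.anchor_b.start, it.anchor_b.end)
        truth_rows.append(
            dict(
                interaction_id=it.interaction_id,
                role="unique",
                pair_class=pair_class,
                anchor_a_category=categories.get(ka, ""),
                anchor_b_category=categories.get(kb, ""),
            )
        )

    # duplicates: same coordinates, swapped anchor order, fresh ids
    dup_sources = interactions[: spec.n_duplicates]
    records = list(interactions)
    for k, src in enumerate(dup_sources):
        # anchors deliberately swapped on disk; readers must re-canonicalize
        dup = ChIAInteraction(src.anchor_b, src.anchor_a, f"ia_dup{k:03d}")
        records.append(dup)
        truth_rows.append(
            dict(interaction_id=dup.interaction_id, role=f"duplicate_of:{src.interaction_id}",
                 pair_class="", anchor_a_category="", anchor_b_category="")
        )
    # decoys: both anchors in the desert of the last chromosome (never in blocks)
    decoy_anchors = _desert_positions(config, chroms[-1], 2 * spec.n_decoys, anchor_w, rng)
    for k in range(spec.n_decoys):
        d = ChIAInteraction.make(
            decoy_anchors[2 * k], decoy_anchors[2 * k + 1], f"decoy{k:03d}"
        )
        records.append(d)
        truth_rows.append(
            dict(interaction_id=d.interaction_id, role="decoy", pair_class="",
                 anchor_a_category="", anchor_b_category="")
        )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame(truth_rows).sort_values("interaction_id").reset_index(drop=True)
    return records, planted + partner_genes, truth, categories


def _enforce_anchor_categories(
    peaks: dict[tuple, list[GenomicInterval]],
    categories: dict[tuple, str],
    cell_type: str = "cd4_t",
) -> None:
    """Rewrite the cell type's peak lists so each anchor realizes its planted category."""
    anchors = [GenomicInterval(*key) for key in categories]
    for mark in ("h3k4me1", "h3k27ac"):
        kept = []
        for p in peaks[(cell_type, mark)]:
            if not any(p.overlaps(a) for a in anchors):
                kept.append(p)
        peaks[(cell_type, mark)] = kept
    for key, cat in sorted(categories.items()):
        chrom, start, end = key
        mid = (start + end) // 2
        if cat in ("both_marks", "me1_only"):
            peaks[(cell_type, "h3k4me1")].append(GenomicInterval(chrom, start, mid))
        if cat in ("both_marks", "ac_only"):
            peaks[(cell_type, "h3k27ac")].append(GenomicInterval(chrom, mid, end))


def _enforce_mark_flags(
    peaks: list[GenomicInterval],
    blocks: Sequence[LDBlock],
    flags: dict[str, bool],
) -> list[GenomicInterval]:
    """Drop peaks from planted-N blocks; guarantee >= 1 peak in planted-Y blocks."""
    out = list(peaks)
    for b in blocks:
        want = flags.get(b.block_id)
        if want is None:
            continue
        if not want:
            out = [p for p in out if not p.overlaps(b.span)]
        else:
            if not any(p.overlaps(b.span) for p in out):
                mid = (b.span.start + b.span.end) // 2
                w = min(500, b.span.width)
                out.append(GenomicInterval(b.chrom, mid, min(mid + w, b.span.end)))
    return out


def _gene_category(
    gene: GeneModel, categories: dict[tuple, str], promoter_window=(5000, 1000)
) -> str:
    """Planted histone category of the anchors touching a gene (body or promoter)."""
    priority = {"both_marks": 0, "ac_only": 1, "me1_only": 2, "neither": 3}
    best = "background"
    for (chrom, start, end), cat in categories.items():
        anchor = GenomicInterval(chrom, start, end)
        hit = anchor.overlaps(gene.body())
        if not hit:
            p = gene.promoter(*promoter_window)
            hit = p is not None and anchor.overlaps(p)
        if hit and (best == "background" or priority[cat] < priority[best]):
            best = cat
    return best


def _write_proxy_table(blocks: Sequence[LDBlock], path: Path) -> None:
    """Proxies at the span endpoints (r2 = 0.95) reconstruct each span exactly;
    one failing proxy per index SNP exercises the r2 filter."""
    rows = []
    for b in blocks:
        lo_1b, hi_1b = b.span.start + 1, b.span.end
        for snp in b.member_snps:
            index_pos = (lo_1b + hi_1b) // 2
            rows.append((snp, snp, b.chrom, index_pos, 1.0, 0))
            rows.append((snp, f"{snp}_p1", b.chrom, lo_1b, 0.95, abs(index_pos - lo_1b)))
            rows.append((snp, f"{snp}_p2", b.chrom, hi_1b, 0.95, abs(hi_1b - index_pos)))
            rows.append((snp, f"{snp}_fail", b.chrom, hi_1b + 50_000, 0.5,
                         abs(hi_1b + 50_000 - index_pos)))
    pd.DataFrame(
        rows, columns=["index_snp", "proxy_snp", "chrom", "position", "r2", "distance"]
    ).to_csv(path, sep="\t", index=False)


def generate(config: SyntheticConfig, outdir: str | Path) -> SyntheticBundle:
    """Write the full input bundle plus ground truth; same seed, same bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)

    blocks = _place_blocks(rng, config)
    segs = _block_segments(config, blocks)

    peaks: dict[tuple, list[GenomicInterval]] = {}
    for cell_type, mark in CELL_MARKS:
        if config.peak_mode == "binwise":
            ivs = _sample_binwise_intervals(rng, config, segs, config.peak_rate_out,
                                            config.theta_peak)
        else:
            ivs = _sample_poisson_intervals(rng, config, segs, config.peak_rate_out,
                                            config.theta_peak, config.peak_width_range)
        peaks[(cell_type, mark)] = ivs

    if config.planted_mark_flags:
        for key, flags in config.planted_mark_flags.items():
            peaks[key] = _enforce_mark_flags(peaks[key], blocks, flags)

    tfbs_sites: list[GenomicInterval] = []
    for spec in config.tf_specs:
        tfbs_sites.extend(
            _sample_poisson_intervals(rng, config, segs, spec.site_rate_per_kb,
                                      spec.theta, config.tf_site_width_range, name=spec.name)
        )

    genes = _background_genes(rng, config)
    interactions: list[ChIAInteraction] = []
    interaction_truth = pd.DataFrame(
        columns=["interaction_id", "role", "pair_class",
                 "anchor_a_category", "anchor_b_category"]
    )
    categories: dict[tuple, str] = {}
    if config.interaction_spec is not None:
        interactions, support_genes, interaction_truth, categories = _build_interactions(
            rng, config, blocks
        )
        genes = genes + support_genes
        if categories:
            _enforce_anchor_categories(peaks, categories, cell_type="cd4_t")

    # expression: planted category shifts the lognormal location by log(multiplier)
    fs = config.fpkm_spec
    gene_rows = []
    fpkm: dict[str, float] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        cat = _gene_category(g, categories) if categories else "background"
        mu = fs.log_mean + (np.log(fs.both_marks_multiplier) if cat == "both_marks" else 0.0)
        value = float(rng.lognormal(mean=mu, sigma=fs.log_sigma))
        fpkm[g.gene_id] = round(value, 4)
        gene_rows.append(dict(gene_id=g.gene_id, category=cat, fpkm=fpkm[g.gene_id]))
    gene_truth = pd.DataFrame(gene_rows)

    # realized per-block mark flags (after all planting)
    mark_flags: dict[tuple, dict[str, bool]] = {}
    for key, ivs in peaks.items():
        flags = {}
        for b in blocks:
            flags[b.block_id] = any(p.overlaps(b.span) for p in ivs)
        mark_flags[key] = flags

    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_chrom_sizes(config.chrom_sizes, _p("chrom.sizes"))
    write_blocks_bed(blocks, _p("blocks.bed"))
    _write_proxy_table(blocks, _p("proxies.tsv"))
    for cell_type, mark in CELL_MARKS:
        ivs = IntervalSet(peaks[(cell_type, mark)])
        write_bed(ivs, _p(f"{cell_type}_{mark}.bed"))
    write_bed(IntervalSet(tfbs_sites), _p("tfbs.bed"))
    write_gene_table(sorted(genes, key=lambda g: g.gene_id), _p("genes.tsv"))
    write_fpkm_table(fpkm, _p("fpkm.tsv"))
    write_bedpe(interactions, _p("interactions.bedpe"))
    snp_rows = []
    for b in blocks:
        mid = (b.span.start + b.span.end) // 2
        for snp in b.member_snps:
            snp_rows.append((snp, b.chrom, mid))
    pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "position"]).to_csv(
        _p("snps.tsv"), sep="\t", index=False
    )

    # ground truth + manifest
    pd.DataFrame(
        [
            dict(block_id=b.block_id, chrom=b.chrom, start=b.span.start, end=b.span.end,
                 snps=",".join(b.member_snps))
            for b in blocks
        ]
    ).to_csv(truth_dir / "blocks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            dict(cell_type=ct, mark=mk, block_id=bid, present=flag)
            for (ct, mk), flags in sorted(mark_flags.items())
            for bid, flag in flags.items()
        ]
    ).to_csv(truth_dir / "mark_flags.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            dict(tf_name=s.name, site_rate_per_kb=s.site_rate_per_kb, theta=s.theta,
                 direction="enriched" if s.theta > 1 else
                           ("depleted" if s.theta < 1 else "null"))
            for s in config.tf_specs
        ]
    ).to_csv(truth_dir / "tf_truth.tsv", sep="\t", index=False)
    interaction_truth.to_csv(truth_dir / "interactions.tsv", sep="\t", index=False)
    gene_truth.to_csv(truth_dir / "genes.tsv", sep="\t", index=False)

    manifest = dict(seed=config.seed, config=_config_echo(config))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = outdir / "manifest.json"

    truth = GroundTruth(
        blocks=blocks,
        mark_flags=mark_flags,
        tf_truth={s.name: s for s in config.tf_specs},
        interaction_truth=interaction_truth,
        gene_truth=gene_truth,
    )
    return SyntheticBundle(outdir=outdir, paths=paths, truth=truth)


def _config_echo(config: SyntheticConfig) -> dict:
    echo = asdict(config)
    echo["tf_specs"] = [asdict(s) for s in config.tf_specs]
    if config.interaction_spec is not None:
        echo["interaction_spec"] = asdict(config.interaction_spec)
    echo["fpkm_spec"] = asdict(config.fpkm_spec)
    if config.planted_mark_flags is not None:
        echo["planted_mark_flags"] = {
            f"{ct}/{mk}": flags for (ct, mk), flags in config.planted_mark_flags.items()
        }
    return echo


def table1_scenario(outdir: str | Path) -> SyntheticBundle:
    """The packaged 23-block risk-locus table with peaks realizing its Y/N matrix.

    Emits the real block spans, a proxy table that reconstructs them exactly,
    and synthetic peak BEDs per cell type with one peak mid-block for every Y
    and none for every N, so annotation reproduces the printed matrix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blocks, marks = load_table1_fixture()
    col_map = {
        ("neutrophil", "h3k4me1"): "neutrophil_h3k4me1",
        ("neutrophil", "h3k27ac"): "neutrophil_h3k27ac",
        ("cd4_t", "h3k4me1"): "cd4_h3k4me1",
        ("cd4_t", "h3k27ac"): "cd4_h3k27ac",
    }
    paths: dict[str, Path] = {}
    chrom_sizes: dict[str, int] = {}
    for b in blocks:
        chrom_sizes[b.chrom] = max(chrom_sizes.get(b.chrom, 0), b.span.end + 100_000)
    chrom_sizes = dict(sorted(chrom_sizes.items()))
    write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")
    paths["chrom.sizes"] = outdir / "chrom.sizes"
    write_blocks_bed(blocks, outdir / "blocks.bed")
    paths["blocks.bed"] = outdir / "blocks.bed"
    _write_proxy_table(blocks, outdir / "proxies.tsv")
    paths["proxies.tsv"] = outdir / "proxies.tsv"
    mark_flags: dict[tuple, dict[str, bool]] = {}
    for key, col in col_map.items():
        ivs = []
        flags = {}
        for b in blocks:
            present = bool(marks.loc[b.block_id, col])
            flags[b.block_id] = present
            if present:
                mid = (b.span.start + b.span.end) // 2
                w = min(500, b.span.width)
                ivs.append(GenomicInterval(b.chrom, mid, min(mid + w, b.span.end)))
        mark_flags[key] = flags
        name = f"{key[0]}_{key[1]}.bed"
        write_bed(IntervalSet(ivs), outdir / name)
        paths[name] = outdir / name
    truth = GroundTruth(
        blocks=blocks,
        mark_flags=mark_flags,
        tf_truth={},
        interaction_truth=pd.DataFrame(),
        gene_truth=pd.DataFrame(),
    )
    return SyntheticBundle(outdir=outdir, paths=paths, truth=truth)
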