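"""Long-range chromatin-interaction annotation within risk LD blocks.

Interactions arrive as anchor pairs (BEDPE). The stages mirror the analysis of
a ChIA-PET catalogue against risk loci: keep pairs with >= 1 anchor in a block,
collapse coordinate-identical pairs, classify each pair by whether its anchors
fall in promoter windows, label each distinct anchor region with its histone
category (both marks / H3K27ac only / H3K4me1 only / neither), and associate
genes and their expression with the anchor regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gene_models import DEFAULT_PROMOTER_WINDOW, GeneModel, promoter_windows
from .genomic_intervals import GenomicInterval, IntervalSet, intersect_any
from .ld_blocks import LDBlock

logger = logging.getLogger(__name__)

PAIR_CLASSES = ("promoter_promoter", "promoter_distal", "distal_distal")
HISTONE_CATEGORIES = ("both_marks", "ac_only", "me1_only", "neither")


@dataclass(frozen=True)
class ChIAInteraction:
    """One interaction: two anchor intervals in canonical (chrom, start) order."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    interaction_id: str = ""

    @staticmethod
    def make(
        anchor_a: GenomicInterval, anchor_b: GenomicInterval, interaction_id: str = ""
    ) -> "ChIAInteraction":
        """Construct with anchors ordered so (a,b) and (b,a) normalize identically."""
        ka = (anchor_a.chrom, anchor_a.start, anchor_a.end)
        kb = (anchor_b.chrom, anchor_b.start, anchor_b.end)
        if kb < ka:
            anchor_a, anchor_b = anchor_b, anchor_a
        return ChIAInteraction(anchor_a, anchor_b, interaction_id)

    def coords(self) -> tuple:
        return (
            self.anchor_a.chrom, self.anchor_a.start, self.anchor_a.end,
            self.anchor_b.chrom, self.anchor_b.start, self.anchor_b.end,
        )


@dataclass
class InteractionAnnotation:
    """Classification and gene context of one kept interaction."""

    interaction_id: str
    ld_block_ids: list[str] = field(default_factory=list)
    pair_class: str = ""
    anchor_categories: tuple[str, str] = ("", "")
    associated_genes: tuple[tuple[str, ...], tuple[str, ...]] = ((), ())


@dataclass(frozen=True)
class ExpressionConfig:
    """FPKM threshold above which a gene counts as highly expressed."""

    high_expression_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.high_expression_threshold <= 0:
            raise ValueError("high_expression_threshold must be > 0")


def read_bedpe(path: str | Path) -> list[ChIAInteraction]:
    """BEDPE (>= 6 columns); column 7, when present, is the interaction id."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"line {lineno}: BEDPE needs >= 6 columns")
            a = GenomicInterval(f[0], int(f[1]), int(f[2]))
            b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            name = f[6] if len(f) > 6 and f[6] != "." else f"interaction_{lineno}"
            out.append(ChIAInteraction.make(a, b, name))
    return out


def write_bedpe(interactions: Iterable[ChIAInteraction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for it in interactions:
            a, b = it.anchor_a, it.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{it.interaction_id}\n"
            )


def preflight_check(
    interactions: Sequence[ChIAInteraction], chrom_sizes: dict[str, int]
) -> list[str]:
    """Warn about anchors outside the stated chromosome bounds (e.g. wrong assembly)."""
    problems = []
    for it in interactions:
        for anchor in (it.anchor_a, it.anchor_b):
            size = chrom_sizes.get(anchor.chrom)
            if size is None:
                problems.append(f"{it.interaction_id}: unknown chromosome {anchor.chrom}")
            elif anchor.end > size:
                problems.append(
                    f"{it.interaction_id}: anchor {anchor} exceeds {anchor.chrom} size {size}"
                )
    if problems:
        warnings.warn(f"{len(problems)} anchors fall outside chromosome sizes", stacklevel=2)
    return problems


def filter_to_blocks(
    interactions: Sequence[ChIAInteraction], blocks: Sequence[LDBlock]
) -> tuple[list[ChIAInteraction], dict[str, list[str]]]:
    """Keep interactions with >= 1 anchor overlapping >= 1 block; record hit block ids."""
    block_set = IntervalSet(
        [GenomicInterval(b.chrom, b.span.start, b.span.end, name=b.block_id) for b in blocks]
    )
    trees = block_set.trees()
    kept, hits = [], {}
    for it in interactions:
        ids: list[str] = []
        for anchor in (it.anchor_a, it.anchor_b):
            tree = trees.get(anchor.chrom)
            if tree is not None:
                ids.extend(sorted(hit.data.name for hit in tree.overlap(anchor.start, anchor.end)))
        if ids:
            kept.append(it)
            hits[it.interaction_id] = sorted(set(ids))
    return kept, hits


def deduplicate(
    interactions: Sequence[ChIAInteraction],
) -> tuple[list[ChIAInteraction], dict[str, int]]:
    """Collapse coordinate-identical anchor pairs; returns per-kept-id source counts.

    Anchors are already canonically ordered, so swapped-order records collapse
    too. Idempotent and order-invariant up to which duplicate's id is kept
    (the lexicographically smallest id wins).
    """
    groups: dict[tuple, list[ChIAInteraction]] = {}
    for it in interactions:
        groups.setdefault(it.coords(), []).append(it)
    unique, provenance = [], {}
    for coords in sorted(groups):
        members = sorted(groups[coords], key=lambda it: it.interaction_id)
        keep = members[0]
        unique.append(keep)
        provenance[keep.interaction_id] = len(members)
    return unique, provenance


def _anchor_promoter_flags(
    anchors: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int],
) -> np.ndarray:
    windows = promoter_windows(genes, promoter_window)
    if len(windows) == 0:
        return np.zeros(len(anchors), dtype=bool)
    return intersect_any(IntervalSet(anchors, normalize=False), windows)


def classify_pair(
    interaction: ChIAInteraction,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> str:
    """promoter_promoter / promoter_distal / distal_distal from per-anchor promoter flags."""
    flags = _anchor_promoter_flags(
        [interaction.anchor_a, interaction.anchor_b], genes, promoter_window
    )
    n = int(flags.sum())
    return PAIR_CLASSES[2 - n]


def anchor_histone_category(
    anchor: GenomicInterval, me1_peaks: IntervalSet, ac_peaks: IntervalSet
) -> str:
    """both_marks / ac_only / me1_only / neither from any-overlap with each peak set."""
    probe = IntervalSet([anchor], normalize=False)
    has_me1 = bool(intersect_any(probe, me1_peaks)[0])
    has_ac = bool(intersect_any(probe, ac_peaks)[0])
    if has_me1 and has_ac:
        return "both_marks"
    if has_ac:
        return "ac_only"
    if has_me1:
        return "me1_only"
    return "neither"


def unique_anchor_regions(
    interactions: Sequence[ChIAInteraction],
) -> list[GenomicInterval]:
    """Distinct anchor regions across interactions; shared anchors counted once."""
    seen: dict[tuple, GenomicInterval] = {}
    for it in interactions:
        for anchor in (it.anchor_a, it.anchor_b):
            seen.setdefault((anchor.chrom, anchor.start, anchor.end), anchor)
    return [seen[k] for k in sorted(seen)]


def categorize_anchors(
    interactions: Sequence[ChIAInteraction],
    me1_peaks: IntervalSet,
    ac_peaks: IntervalSet,
) -> dict[tuple, str]:
    """Histone category per unique anchor region, keyed by (chrom, start, end)."""
    return {
        (a.chrom, a.start, a.end): anchor_histone_category(a, me1_peaks, ac_peaks)
        for a in unique_anchor_regions(interactions)
    }


def annotate_interactions(
    interactions: Sequence[ChIAInteraction],
    blocks: Sequence[LDBlock],
    genes: Sequence[GeneModel],
    me1_peaks: IntervalSet,
    ac_peaks: IntervalSet,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> tuple[list[ChIAInteraction], list[InteractionAnnotation], dict[str, int]]:
    """filter -> deduplicate -> classify + categorize, in one pass."""
    kept, hits = filter_to_blocks(interactions, blocks)
    unique, provenance = deduplicate(kept)
    cats = categorize_anchors(unique, me1_peaks, ac_peaks)
    annotations = []
    for it in unique:
        ann = InteractionAnnotation(
            interaction_id=it.interaction_id,
            ld_block_ids=hits.get(it.interaction_id, []),
            pair_class=classify_pair(it, genes, promoter_window),
            anchor_categories=(
                cats[(it.anchor_a.chrom, it.anchor_a.start, it.anchor_a.end)],
                cats[(it.anchor_b.chrom, it.anchor_b.start, it.anchor_b.end)],
            ),
        )
        annotations.append(ann)
    return unique, annotations, provenance


def genes_for_anchor(
    anchor: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> list[str]:
    """Genes whose body or promoter window shares >= 1 bp with the anchor."""
    out = []
    for g in genes:
        if anchor.overlaps(g.body()):
            out.append(g.gene_id)
            continue
        p = g.promoter(*promoter_window)
        if p is not None and anchor.overlaps(p):
            out.append(g.gene_id)
    return sorted(set(out))


def associate_genes_and_expression(
    interactions: Sequence[ChIAInteraction],
    genes: Sequence[GeneModel],
    fpkm_table: dict[str, float],
    config: ExpressionConfig = ExpressionConfig(),
    me1_peaks: IntervalSet | None = None,
    ac_peaks: IntervalSet | None = None,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> dict:
    """Per-histone-category gene sets, mean FPKM, and the high-expression subset.

    A gene is associated with an anchor region iff the anchor overlaps the gene
    body or its promoter window. Genes missing from the FPKM table are counted
    at 0 and logged (unsequenced small-RNA species behave this way).
    """
    if me1_peaks is None:
        me1_peaks = IntervalSet([])
    if ac_peaks is None:
        ac_peaks = IntervalSet([])
    cats = categorize_anchors(interactions, me1_peaks, ac_peaks)
    category_genes: dict[str, set[str]] = {c: set() for c in HISTONE_CATEGORIES}
    all_genes: set[str] = set()
    for anchor in unique_anchor_regions(interactions):
        gene_ids = genes_for_anchor(anchor, genes, promoter_window)
        category_genes[cats[(anchor.chrom, anchor.start, anchor.end)]].update(gene_ids)
        all_genes.update(gene_ids)
    missing = sorted(g for g in all_genes if g not in fpkm_table)
    if missing:
        logger.warning("%d associated genes missing from FPKM table; FPKM = 0", len(missing))

    def fpkm(g: str) -> float:
        return fpkm_table.get(g, 0.0)

    mean_fpkm = {
        c: (float(np.mean([fpkm(g) for g in sorted(gs)])) if gs else float("nan"))
        for c, gs in category_genes.items()
    }
    high = sorted(g for g in all_genes if fpkm(g) > config.high_expression_threshold)
    return {
        "category_genes": {c: sorted(gs) for c, gs in category_genes.items()},
        "mean_fpkm": mean_fpkm,
        "high_expression_genes": high,
        "all_genes": sorted(all_genes),
        "missing_from_fpkm": missing,
    }


def pair_class_counts(annotations: Sequence[InteractionAnnotation]) -> dict[str, int]:
    counts = {c: 0 for c in PAIR_CLASSES}
    for a in annotations:
        counts[a.pair_class] += 1
    return counts


def anchor_category_counts(cats: dict[tuple, str]) -> dict[str, int]:
    counts = {c: 0 for c in HISTONE_CATEGORIES}
    for c in cats.values():
        counts[c] += 1
    return counts


def annotations_to_frame(annotations: Sequence[InteractionAnnotation]) -> pd.DataFrame:
    rows = [
        dict(
            interaction_id=a.interaction_id,
            ld_block_ids=";".join(a.ld_block_ids),
            pair_class=a.pair_class,
            anchor_a_category=a.anchor_categories[0],
            anchor_b_category=a.anchor_categories[1],
        )
        for a in annotations
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("interaction_id").reset_index(drop=True)
    return df
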