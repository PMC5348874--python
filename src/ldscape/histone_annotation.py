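"""Presence and genome-wide enrichment of H3K4me1/H3K27ac marks in LD blocks.

H3K4me1 and H3K27ac are histone modifications whose co-occurrence marks active
enhancers. Each block is annotated Y/N per mark and cell type by any-overlap
(>= 1 bp) with the ChIP-Seq peak set, and mark enrichment inside blocks versus
the rest of the genome is tested with Fisher's exact test over fixed-width
genome bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genomic_intervals import GenomeBins, IntervalSet, intersect_any
from .ld_blocks import LDBlock
from .stats import FisherResult, fisher_test

CELL_TYPES = ("neutrophil", "cd4_t")


@dataclass(frozen=True)
class MarkAnnotation:
    """Per-(block, cell type) presence flags for the two enhancer marks."""

    block_id: str
    cell_type: str
    has_me1: bool
    has_ac: bool


@dataclass(frozen=True)
class MarkSummary:
    """Counts of blocks carrying each mark, both, or either, for one cell type."""

    cell_type: str
    n_blocks: int
    n_me1: int
    n_ac: int
    n_both: int
    n_either: int


def annotate_blocks(
    blocks: Sequence[LDBlock],
    me1_peaks: IntervalSet,
    ac_peaks: IntervalSet,
    cell_type: str,
) -> list[MarkAnnotation]:
    """Flag each block for >= 1 bp overlap with any H3K4me1 / H3K27ac peak."""
    if not blocks:
        raise ValueError("annotate_blocks requires at least one block")
    spans = IntervalSet([b.span for b in blocks], normalize=False)
    me1_flags = intersect_any(spans, me1_peaks)
    ac_flags = intersect_any(spans, ac_peaks)
    return [
        MarkAnnotation(b.block_id, cell_type, bool(m), bool(a))
        for b, m, a in zip(blocks, me1_flags, ac_flags)
    ]


def summarize_marks(annotations: Sequence[MarkAnnotation]) -> MarkSummary:
    """Tally blocks with me1, ac, both and either; n_either = n_me1 + n_ac - n_both."""
    ids = [a.block_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate block ids in annotations")
    cell_types = {a.cell_type for a in annotations}
    if len(cell_types) > 1:
        raise ValueError(f"annotations mix cell types: {sorted(cell_types)}")
    n_me1 = sum(a.has_me1 for a in annotations)
    n_ac = sum(a.has_ac for a in annotations)
    n_both = sum(a.has_me1 and a.has_ac for a in annotations)
    return MarkSummary(
        cell_type=cell_types.pop() if cell_types else "",
        n_blocks=len(annotations),
        n_me1=n_me1,
        n_ac=n_ac,
        n_both=n_both,
        n_either=n_me1 + n_ac - n_both,
    )


def annotation_matrix(
    blocks: Sequence[LDBlock],
    peak_sets: dict[tuple[str, str], IntervalSet],
) -> pd.DataFrame:
    """Y/N-style boolean matrix over blocks for all (cell_type, mark) peak sets.

    ``peak_sets`` maps (cell_type, mark) with mark in {"h3k4me1", "h3k27ac"} to
    the peak IntervalSet; columns are named ``{cell_type}_{mark}``.
    """
    spans = IntervalSet([b.span for b in blocks], normalize=False)
    data = {}
    for (cell_type, mark), peaks in peak_sets.items():
        data[f"{cell_type}_{mark}"] = intersect_any(spans, peaks)
    df = pd.DataFrame(data, index=pd.Index([b.block_id for b in blocks], name="block_id"))
    return df


def mark_enrichment_test(
    blocks: Sequence[LDBlock] | IntervalSet,
    peaks: IntervalSet,
    bins: GenomeBins,
) -> FisherResult:
    """Genome-binned Fisher test: are peak-bearing bins over-represented in blocks?

    Each bin is cross-classified (inside an LD block vs outside) x (overlaps a
    peak vs not); the 2x2 table goes to a two-sided Fisher's exact test. A zero
    margin (no peaks, or no in-block bins) yields a degenerate result with
    p = 1 by convention.
    """
    spans = blocks if isinstance(blocks, IntervalSet) else IntervalSet(
        [b.span for b in blocks], normalize=False
    )
    in_ld = bins.overlap_flags(spans)
    has_peak = bins.overlap_flags(peaks)
    table = [
        [int((in_ld & has_peak).sum()), int((in_ld & ~has_peak).sum())],
        [int((~in_ld & has_peak).sum()), int((~in_ld & ~has_peak).sum())],
    ]
    return fisher_test(table)


def summaries_to_frame(summaries: Iterable[MarkSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
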