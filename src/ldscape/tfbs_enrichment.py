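"""Per-TF enrichment of binding sites inside LD blocks, against a marked-genome background.

The counting unit is the fixed-width genome bin. For a given histone mark the
background is the set of bins overlapping that mark's peaks; within each
(mark, region class) stratum — region class is promoter vs distal, promoter
meaning the strand-aware [TSS-5 kb, TSS+1 kb) window of any gene — every TF's
sites are cross-classified (bin inside an LD block) x (bin carries >= 1 site)
and tested with two-sided Fisher's exact test. p-values are Benjamini-Hochberg
adjusted within the stratum, and significant TFs receive a signed normalized
rank score in [-1, 1] (enriched positive, depleted negative; the lowest FDR has
|score| = 1) for heatmap display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gene_models import DEFAULT_PROMOTER_WINDOW, GeneModel, promoter_windows
from .genomic_intervals import GenomeBins, GenomicInterval, IntervalSet
from .stats import bh_adjust, fisher_test

logger = logging.getLogger(__name__)

REGION_CLASSES = ("promoter", "distal")
MARKS = ("H3K4me1", "H3K27ac")


@dataclass(frozen=True)
class TFBSRecord:
    """One clustered binding-site interval for a named transcription factor."""

    tf_name: str
    site: GenomicInterval

    def __post_init__(self) -> None:
        if not self.tf_name:
            raise ValueError("tf_name must be non-empty")


@dataclass(frozen=True)
class EnrichmentConfig:
    """Bin width, FDR cutoff and promoter window (upstream, downstream of TSS)."""

    bin_size: int = 100
    fdr_cutoff: float = 0.05
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValueError("fdr_cutoff must be in (0, 1)")


@dataclass
class TFEnrichmentResult:
    """One TF x (mark, region class) contrast with its test statistics."""

    tf_name: str
    mark: str
    region_class: str
    counts: np.ndarray  # [[in-LD with sites, in-LD without], [out-LD with, out-LD without]]
    odds_ratio: float = math.nan
    p_value: float = math.nan
    fdr: float = math.nan
    direction: str = ""
    significant: bool = False
    degenerate: bool = False
    or_tied: bool = False  # odds ratio exactly 1; "enriched" by convention
    normalized_rank: float = math.nan
    haldane_corrected: bool = field(default=False, repr=False)


def read_tfbs_bed(
    path: str | Path, cell_type_filter: str | None = None
) -> list[TFBSRecord]:
    """BED with the TF name in column 4 (clustered-TFBS-track style).

    An optional fifth column lists cell types comma-separated; when
    ``cell_type_filter`` is given, only records whose list contains it are kept
    (convenience for inputs not pre-filtered to blood cells).
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: TFBS BED needs >= 4 columns (name = TF)")
            if cell_type_filter is not None and len(fields) > 4:
                cells = {c.strip() for c in fields[4].split(",")}
                if cell_type_filter not in cells:
                    continue
            site = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name=fields[3])
            records.append(TFBSRecord(tf_name=fields[3], site=site))
    return records


def classify_bins(
    bins: GenomeBins,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> np.ndarray:
    """Boolean per bin: True = promoter (overlaps any gene's TSS window), False = distal."""
    if not genes:
        return np.zeros(bins.n_bins, dtype=bool)
    return bins.overlap_flags(promoter_windows(genes, promoter_window))


def tf_enrichment_table(
    tf_flags: np.ndarray,
    marked_flags: np.ndarray,
    ld_flags: np.ndarray,
    class_flags: np.ndarray,
) -> np.ndarray:
    """2x2 counts restricted to marked bins of one region class.

    All vectors are boolean over the same GenomeBins; ``class_flags`` selects the
    stratum (promoter or distal bins). Rows: in-LD / out-LD; columns: bin
    carries >= 1 site of the TF / does not.
    """
    sel = marked_flags & class_flags
    in_ld = ld_flags[sel]
    tf = tf_flags[sel]
    return np.array(
        [
            [int((in_ld & tf).sum()), int((in_ld & ~tf).sum())],
            [int((~in_ld & tf).sum()), int((~in_ld & ~tf).sum())],
        ],
        dtype=np.int64,
    )


def fisher_fdr(
    results: Sequence[TFEnrichmentResult], fdr_cutoff: float = 0.05
) -> list[TFEnrichmentResult]:
    """Fisher p per TF, then Benjamini-Hochberg within the stratum.

    All results must belong to one (mark, region_class) stratum; significance is
    fdr <= cutoff. Degenerate tables (a zero margin) get p = 1 and are flagged.
    """
    if not results:
        return []
    strata = {(r.mark, r.region_class) for r in results}
    if len(strata) > 1:
        raise ValueError(f"fisher_fdr expects one stratum, got {sorted(strata)}")
    for r in results:
        fr = fisher_test(r.counts)
        r.odds_ratio = fr.odds_ratio
        r.p_value = fr.p_value
        r.direction = fr.direction
        r.degenerate = fr.degenerate
        r.haldane_corrected = fr.haldane_corrected
        r.or_tied = not fr.degenerate and fr.odds_ratio == 1.0
    fdrs = bh_adjust([r.p_value for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
        r.significant = bool(f <= fdr_cutoff) and not r.degenerate
    return list(results)


def normalized_rank_scores(
    results: Sequence[TFEnrichmentResult],
) -> list[TFEnrichmentResult]:
    """Signed display scores for the significant results of one stratum.

    Within each direction group, TFs are ranked by FDR — lowest FDR gets the
    highest rank r_max — and score = rank / r_max, negated for depleted, so
    enriched scores lie in (0, 1] and depleted in [-1, 0). Ties on FDR are
    broken by larger |log odds ratio|, then TF name.
    """
    for direction, sign in (("enriched", 1.0), ("depleted", -1.0)):
        group = [r for r in results if r.significant and r.direction == direction]
        if not group:
            continue
        group.sort(
            key=lambda r: (r.fdr, -abs(math.log(r.odds_ratio)) if r.odds_ratio > 0 else 0.0,
                           r.tf_name)
        )
        r_max = len(group)
        for i, r in enumerate(group):  # i = 0 is the lowest FDR -> rank r_max
            r.normalized_rank = sign * (r_max - i) / r_max
    return list(results)


def run_tfbs_enrichment(
    tfbs: Sequence[TFBSRecord],
    mark_peaks: dict[str, IntervalSet],
    ld_blocks: IntervalSet,
    bins: GenomeBins,
    genes: Sequence[GeneModel],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[TFEnrichmentResult]:
    """Full per-TF analysis across every (mark, region class) stratum.

    ``mark_peaks`` maps mark name (e.g. "H3K4me1") to its peak IntervalSet.
    """
    ld_flags = bins.overlap_flags(ld_blocks)
    promoter_flags = classify_bins(bins, genes, config.promoter_window)
    by_tf: dict[str, list[GenomicInterval]] = {}
    for rec in tfbs:
        by_tf.setdefault(rec.tf_name, []).append(rec.site)
    tf_flag_vecs = {
        tf: bins.overlap_flags(sites) for tf, sites in sorted(by_tf.items())
    }
    all_results: list[TFEnrichmentResult] = []
    for mark, peaks in mark_peaks.items():
        marked_flags = bins.overlap_flags(peaks)
        for region_class in REGION_CLASSES:
            class_flags = promoter_flags if region_class == "promoter" else ~promoter_flags
            if not (marked_flags & class_flags).any():
                logger.warning("no %s %s background bins; stratum skipped", mark, region_class)
                continue
            stratum = [
                TFEnrichmentResult(
                    tf_name=tf,
                    mark=mark,
                    region_class=region_class,
                    counts=tf_enrichment_table(vec, marked_flags, ld_flags, class_flags),
                )
                for tf, vec in tf_flag_vecs.items()
            ]
            fisher_fdr(stratum, config.fdr_cutoff)
            normalized_rank_scores(stratum)
            all_results.extend(stratum)
    return all_results


def results_to_frame(results: Iterable[TFEnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        a, b, c, d = r.counts.ravel()
        rows.append(
            dict(
                tf_name=r.tf_name, mark=r.mark, region_class=r.region_class,
                in_ld_with_sites=a, in_ld_without=b, out_ld_with_sites=c, out_ld_without=d,
                odds_ratio=r.odds_ratio, p_value=r.p_value, fdr=r.fdr,
                direction=r.direction, significant=r.significant,
                degenerate=r.degenerate, normalized_rank=r.normalized_rank,
            )
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["mark", "region_class", "fdr", "tf_name"]).reset_index(drop=True)
    return df


def score_matrix(results: Iterable[TFEnrichmentResult]) -> pd.DataFrame:
    """TFs x (mark, region class) matrix of normalized-rank scores (NaN = not significant)."""
    df = results_to_frame(results)
    if df.empty:
        return pd.DataFrame()
    return df.pivot_table(
        index="tf_name",
        columns=["mark", "region_class"],
        values="normalized_rank",
        dropna=False,
    ).sort_index()
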