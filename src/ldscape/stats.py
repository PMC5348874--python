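"""Fisher's exact test and Benjamini-Hochberg helpers shared by the enrichment modules.

The 2x2 layout everywhere is::

    [[in-region & feature,  in-region & no feature],
     [outside  & feature,   outside  & no feature]]

so an odds ratio above 1 means the feature is over-represented inside the
region of interest relative to the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class FisherResult:
    """One 2x2 enrichment contrast: odds ratio, two-sided p, direction."""

    table: np.ndarray
    odds_ratio: float
    p_value: float
    direction: str  # "enriched" or "depleted"
    degenerate: bool = False  # a zero margin: test uninformative, p = 1 by convention
    haldane_corrected: bool = False  # +0.5 applied to the OR because of a zero cell


def _odds_ratio(table: np.ndarray) -> tuple[float, bool]:
    """Sample odds ratio; Haldane-Anscombe +0.5 applied only when a cell is zero."""
    a, b, c, d = table.ravel().astype(float)
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    return (a * d) / (b * c), corrected


def fisher_test(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    A zero margin (no feature anywhere, or an empty row) makes the test
    uninformative; the result is flagged degenerate with p = 1.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    degenerate = bool((table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any())
    if degenerate:
        odds_ratio, corrected = _odds_ratio(table)
        return FisherResult(table, odds_ratio, 1.0, "enriched", True, corrected)
    _, p = sps.fisher_exact(table, alternative="two-sided")
    odds_ratio, corrected = _odds_ratio(table)
    # ties (OR exactly 1) count as enriched, flagged by the caller if needed
    direction = "depleted" if odds_ratio < 1.0 else "enriched"
    return FisherResult(table, odds_ratio, float(p), direction, False, corrected)


def fisher_two_sided_oracle(table) -> float:
    """Independent tail-sum oracle for the two-sided Fisher p-value.

    Enumerates every table with the observed margins and sums hypergeometric
    probabilities not exceeding the observed one (with the customary 1+1e-7
    relative tolerance for floating-point ties). Used to cross-check the
    production path, never to replace it.
    """
    a, b, c, d = np.asarray(table, dtype=np.int64).ravel()
    n = a + b + c + d
    r1, c1 = a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    observed = sps.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return fdr
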