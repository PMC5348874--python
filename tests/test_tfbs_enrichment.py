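"""Promoter/distal bin classification, per-TF contingency tables, BH, and rank scores."""

import math

import numpy as np
import pytest

from ldscape.gene_models import GeneModel
from ldscape.genomic_intervals import GenomicInterval, IntervalSet, make_bins
from ldscape.tfbs_enrichment import (
    TFBSRecord,
    TFEnrichmentResult,
    classify_bins,
    fisher_fdr,
    normalized_rank_scores,
    run_tfbs_enrichment,
    tf_enrichment_table,
)


def result(tf, counts, mark="H3K4me1", region_class="promoter"):
    return TFEnrichmentResult(tf, mark, region_class, np.asarray(counts, dtype=np.int64))


class TestClassifyBins:
    def test_plus_strand_window_boundaries(self):
        bins = make_bins({"c": 20_000}, 100)
        genes = [GeneModel("g", "c", 10_000, 12_000, "+")]  # TSS 10,000
        flags = classify_bins(bins, genes)
        # window [5,000, 11,000): bin [4,900,5,000) distal, [5,000,5,100) promoter
        assert not flags[49] and flags[50] and flags[109] and not flags[110]

    def test_minus_strand_window_mirrors(self):
        bins = make_bins({"c": 20_000}, 100)
        genes = [GeneModel("g", "c", 8_000, 10_000, "-")]  # TSS 10,000
        flags = classify_bins(bins, genes)
        # window [9,000, 15,000): bin [9,000,9,100) promoter, [8,900,9,000) distal
        assert flags[90] and not flags[89] and flags[149] and not flags[150]

    def test_no_genes_all_distal(self):
        bins = make_bins({"c": 1_000}, 100)
        assert not classify_bins(bins, []).any()


class TestContingencyTable:
    def test_hand_counted_toy_genome(self):
        # 10 marked bins: 4 in-LD (3 with sites), 6 out-LD (1 with a site)
        marked = np.ones(10, dtype=bool)
        ld = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        tf = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        table = tf_enrichment_table(tf, marked, ld, np.ones(10, dtype=bool))
        np.testing.assert_array_equal(table, [[3, 1], [1, 5]])

    def test_tf_without_sites(self):
        marked = np.ones(8, dtype=bool)
        ld = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        table = tf_enrichment_table(np.zeros(8, dtype=bool), marked, ld,
                                    np.ones(8, dtype=bool))
        np.testing.assert_array_equal(table, [[0, 3], [0, 5]])

    def test_counts_conserve_background_size(self):
        rng = np.random.default_rng(3)
        n = 500
        marked = rng.random(n) < 0.4
        ld = rng.random(n) < 0.2
        cls = rng.random(n) < 0.5
        tf = rng.random(n) < 0.3
        table = tf_enrichment_table(tf, marked, ld, cls)
        assert table.sum() == int((marked & cls).sum())


class TestFisherFdr:
    def test_degenerate_background_flagged(self):
        r = fisher_fdr([result("t", [[0, 0], [2, 3]])])[0]
        assert r.degenerate and r.p_value == 1.0 and not r.significant

    def test_mixed_strata_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            fisher_fdr([result("a", [[1, 1], [1, 1]]),
                        result("b", [[1, 1], [1, 1]], mark="H3K27ac")])

    def test_null_table_never_significant(self):
        r = fisher_fdr([result("t", [[5, 5], [50, 50]])])[0]
        assert r.p_value == 1.0 and not r.significant

    def test_fdr_ordering_follows_bh(self):
        results = [
            result("strong", [[60, 40], [20, 80]]),
            result("weak", [[55, 45], [45, 55]]),
            result("null", [[50, 50], [50, 50]]),
        ]
        out = fisher_fdr(results)
        by_name = {r.tf_name: r for r in out}
        assert by_name["strong"].fdr <= by_name["weak"].fdr <= by_name["null"].fdr


class TestNormalizedRankScores:
    def _sig(self, tf, fdr, direction, odds):
        r = result(tf, [[1, 1], [1, 1]])
        r.fdr, r.direction, r.significant, r.odds_ratio = fdr, direction, True, odds
        return r

    def test_single_enriched_tf_scores_one(self):
        out = normalized_rank_scores([self._sig("a", 0.01, "enriched", 2.0)])
        assert out[0].normalized_rank == 1.0

    def test_enriched_rank_fractions(self):
        rs = [
            self._sig("a", 0.001, "enriched", 3.0),
            self._sig("b", 0.01, "enriched", 2.0),
            self._sig("c", 0.04, "enriched", 1.5),
        ]
        normalized_rank_scores(rs)
        scores = {r.tf_name: r.normalized_rank for r in rs}
        assert scores == {"a": 1.0, "b": pytest.approx(2 / 3), "c": pytest.approx(1 / 3)}

    def test_depleted_scores_are_negated(self):
        rs = [
            self._sig("a", 0.002, "depleted", 0.3),
            self._sig("b", 0.03, "depleted", 0.5),
        ]
        normalized_rank_scores(rs)
        scores = {r.tf_name: r.normalized_rank for r in rs}
        assert scores == {"a": -1.0, "b": pytest.approx(-0.5)}

    def test_extreme_score_is_always_unit(self):
        rs = [self._sig(f"t{i}", 0.01 * (i + 1), "enriched", 2.0) for i in range(7)]
        rs += [self._sig(f"d{i}", 0.02 * (i + 1), "depleted", 0.4) for i in range(3)]
        normalized_rank_scores(rs)
        enr = [r.normalized_rank for r in rs if r.direction == "enriched"]
        dep = [r.normalized_rank for r in rs if r.direction == "depleted"]
        assert max(enr) == 1.0 and min(dep) == -1.0
        assert all(0 < s <= 1 for s in enr) and all(-1 <= s < 0 for s in dep)

    def test_insignificant_results_keep_nan_scores(self):
        r = result("t", [[1, 1], [1, 1]])
        r.significant = False
        normalized_rank_scores([r])
        assert math.isnan(r.normalized_rank)


class TestRunTFBSEnrichment:
    def test_full_run_counts_conservation(self):
        """Every stratum's tables sum to that stratum's marked-bin count."""
        rng = np.random.default_rng(5)
        sizes = {"c": 100_000}
        bins = make_bins(sizes, 100)
        blocks = IntervalSet([GenomicInterval("c", 0, 20_000)])
        peaks = IntervalSet(
            [GenomicInterval("c", int(s), int(s) + 300)
             for s in rng.integers(0, 99_000, 120)]
        )
        genes = [GeneModel("g1", "c", 30_000, 40_000, "+"),
                 GeneModel("g2", "c", 10_000, 15_000, "-")]
        tfbs = [
            TFBSRecord("TFA", GenomicInterval("c", int(s), int(s) + 150))
            for s in rng.integers(0, 99_000, 80)
        ]
        results = run_tfbs_enrichment(tfbs, {"H3K4me1": peaks}, blocks, bins, genes)
        marked = bins.overlap_flags(peaks)
        promoter = classify_bins(bins, genes)
        for r in results:
            expected = int((marked & (promoter if r.region_class == "promoter" else ~promoter)).sum())
            assert r.counts.sum() == expected
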