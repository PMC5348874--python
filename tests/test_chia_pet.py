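"""Interaction filtering, deduplication, pair classification, and gene association."""

import numpy as np
import pytest

from ldscape.chia_pet import (
    ChIAInteraction,
    ExpressionConfig,
    anchor_category_counts,
    anchor_histone_category,
    annotate_interactions,
    associate_genes_and_expression,
    categorize_anchors,
    classify_pair,
    deduplicate,
    filter_to_blocks,
    pair_class_counts,
    read_bedpe,
)
from ldscape.gene_models import GeneModel, read_fpkm_table, read_gene_table
from ldscape.genomic_intervals import GenomicInterval, IntervalSet, read_bed
from ldscape.ld_blocks import LDBlock, blocks_from_proxy_table


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def block(bid, chrom, start, end):
    return LDBlock(bid, chrom, GenomicInterval(chrom, start, end), [bid])


class TestFilterAndDeduplicate:
    def test_one_in_block_anchor_suffices(self):
        blocks = [block("b1", "c", 1_000, 5_000)]
        inter = ChIAInteraction.make(iv("c", 2_000, 3_000), iv("c", 2_000_000, 2_001_000), "i1")
        kept, hits = filter_to_blocks([inter], blocks)
        assert len(kept) == 1 and hits["i1"] == ["b1"]

    def test_no_anchor_in_block_is_dropped(self):
        blocks = [block("b1", "c", 1_000, 5_000)]
        inter = ChIAInteraction.make(iv("c", 10_000, 11_000), iv("c", 20_000, 21_000), "i1")
        kept, _ = filter_to_blocks([inter], blocks)
        assert kept == []

    def test_swapped_anchor_order_collapses(self):
        a, b = iv("c", 100, 200), iv("c", 500, 600)
        unique, prov = deduplicate(
            [ChIAInteraction.make(a, b, "x"), ChIAInteraction.make(b, a, "y")]
        )
        assert len(unique) == 1 and prov[unique[0].interaction_id] == 2

    def test_deduplicate_is_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(0)
        pool = [
            ChIAInteraction.make(iv("c", s, s + 100), iv("c", s + 1_000, s + 1_100), f"i{k}")
            for k, s in enumerate(rng.integers(0, 10_000, 20))
        ]
        records = pool + pool[:5]  # five duplicates
        unique1, _ = deduplicate(records)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        unique2, _ = deduplicate(shuffled)
        assert [u.coords() for u in unique1] == [u.coords() for u in unique2]
        again, _ = deduplicate(unique1)
        assert [u.coords() for u in again] == [u.coords() for u in unique1]

    def test_distinct_input_passes_through(self):
        records = [
            ChIAInteraction.make(iv("c", 0, 10), iv("c", 50, 60), "a"),
            ChIAInteraction.make(iv("c", 100, 110), iv("c", 150, 160), "b"),
        ]
        unique, prov = deduplicate(records)
        assert len(unique) == 2 and all(v == 1 for v in prov.values())


class TestClassifyPair:
    genes = [GeneModel("g1", "c", 10_000, 12_000, "+"), GeneModel("g2", "c", 50_000, 52_000, "+")]

    def test_both_promoter_anchors(self):
        inter = ChIAInteraction.make(iv("c", 9_000, 9_500), iv("c", 49_000, 49_500), "i")
        assert classify_pair(inter, self.genes) == "promoter_promoter"

    def test_promoter_and_desert_anchor(self):
        inter = ChIAInteraction.make(iv("c", 9_000, 9_500), iv("c", 200_000, 200_500), "i")
        assert classify_pair(inter, self.genes) == "promoter_distal"

    def test_zero_width_window_makes_everything_distal(self):
        inter = ChIAInteraction.make(iv("c", 9_000, 9_500), iv("c", 49_000, 49_500), "i")
        assert classify_pair(inter, self.genes, promoter_window=(0, 0)) == "distal_distal"


class TestAnchorCategories:
    me1 = IntervalSet([iv("c", 100, 200), iv("c", 1_000, 1_200)])
    ac = IntervalSet([iv("c", 150, 250), iv("c", 5_000, 5_200)])

    @pytest.mark.parametrize(
        "anchor,expected",
        [
            ((120, 180), "both_marks"),
            ((1_050, 1_100), "me1_only"),
            ((5_050, 5_100), "ac_only"),
            ((9_000, 9_100), "neither"),
        ],
    )
    def test_category_from_overlap_flags(self, anchor, expected):
        assert anchor_histone_category(iv("c", *anchor), self.me1, self.ac) == expected

    def test_shared_anchors_counted_once(self):
        shared = iv("c", 120, 180)
        inters = [
            ChIAInteraction.make(shared, iv("c", 9_000, 9_100), "i1"),
            ChIAInteraction.make(shared, iv("c", 5_050, 5_100), "i2"),
        ]
        cats = categorize_anchors(inters, self.me1, self.ac)
        assert len(cats) == 3  # 4 anchor slots, one shared region
        counts = anchor_category_counts(cats)
        assert counts == {"both_marks": 1, "ac_only": 1, "me1_only": 0, "neither": 1}


class TestPlantedRecovery:
    def test_bundle_round_trip_recovers_planted_counts(self, bundle):
        """48 in-block records with 6 duplicates and 20/21/1 planted classes come back exactly."""
        d = bundle.outdir
        blocks = blocks_from_proxy_table(d / "proxies.tsv")
        interactions = read_bedpe(d / "interactions.bedpe")
        genes = read_gene_table(d / "genes.tsv")
        me1 = read_bed(d / "cd4_t_h3k4me1.bed")
        ac = read_bed(d / "cd4_t_h3k27ac.bed")
        unique, annotations, provenance = annotate_interactions(
            interactions, blocks, genes, me1, ac
        )
        assert sum(provenance.values()) == 48
        assert len(unique) == 42
        assert pair_class_counts(annotations) == {
            "promoter_promoter": 20, "promoter_distal": 21, "distal_distal": 1,
        }
        cats = categorize_anchors(unique, me1, ac)
        assert anchor_category_counts(cats) == {
            "both_marks": 66, "ac_only": 2, "me1_only": 11, "neither": 5,
        }

    def test_pair_classes_match_planted_labels_per_interaction(self, bundle):
        truth = bundle.truth.interaction_truth
        truth = truth[truth.role == "unique"].set_index("interaction_id")
        d = bundle.outdir
        blocks = blocks_from_proxy_table(d / "proxies.tsv")
        genes = read_gene_table(d / "genes.tsv")
        unique, annotations, _ = annotate_interactions(
            read_bedpe(d / "interactions.bedpe"), blocks, genes,
            read_bed(d / "cd4_t_h3k4me1.bed"), read_bed(d / "cd4_t_h3k27ac.bed"),
        )
        for ann in annotations:
            assert ann.pair_class == truth.loc[ann.interaction_id, "pair_class"]

    def test_class_counts_sum_to_unique_interactions(self, bundle):
        d = bundle.outdir
        blocks = blocks_from_proxy_table(d / "proxies.tsv")
        genes = read_gene_table(d / "genes.tsv")
        unique, annotations, _ = annotate_interactions(
            read_bedpe(d / "interactions.bedpe"), blocks, genes,
            IntervalSet([]), IntervalSet([]),
        )
        assert sum(pair_class_counts(annotations).values()) == len(unique)
        cats = categorize_anchors(unique, IntervalSet([]), IntervalSet([]))
        assert sum(anchor_category_counts(cats).values()) == len(cats)


class TestGeneAssociation:
    genes = [GeneModel("body_gene", "c", 10_000, 20_000, "+"),
             GeneModel("far_gene", "c", 500_000, 510_000, "+")]

    def test_anchor_inside_gene_body_associates(self):
        inter = ChIAInteraction.make(iv("c", 12_000, 13_000), iv("c", 700_000, 701_000), "i")
        out = associate_genes_and_expression([inter], self.genes, {"body_gene": 10.0})
        assert out["all_genes"] == ["body_gene"]

    def test_high_expression_threshold(self):
        inter = ChIAInteraction.make(iv("c", 12_000, 13_000), iv("c", 505_000, 506_000), "i")
        out = associate_genes_and_expression(
            [inter], self.genes, {"body_gene": 150.0, "far_gene": 99.0},
            ExpressionConfig(high_expression_threshold=100.0),
        )
        assert out["high_expression_genes"] == ["body_gene"]

    def test_missing_fpkm_counts_as_zero(self):
        inter = ChIAInteraction.make(iv("c", 12_000, 13_000), iv("c", 700_000, 701_000), "i")
        out = associate_genes_and_expression([inter], self.genes, {})
        assert out["missing_from_fpkm"] == ["body_gene"]
        assert out["mean_fpkm"]["neither"] == 0.0

    def test_both_marks_genes_express_higher_in_bundle(self, bundle):
        """The planted 4x lognormal shift shows up in the per-category means."""
        d = bundle.outdir
        genes = read_gene_table(d / "genes.tsv")
        fpkm = read_fpkm_table(d / "fpkm.tsv")
        unique, _, _ = annotate_interactions(
            read_bedpe(d / "interactions.bedpe"),
            blocks_from_proxy_table(d / "proxies.tsv"),
            genes,
            read_bed(d / "cd4_t_h3k4me1.bed"),
            read_bed(d / "cd4_t_h3k27ac.bed"),
        )
        out = associate_genes_and_expression(
            unique, genes, fpkm,
            me1_peaks=read_bed(d / "cd4_t_h3k4me1.bed"),
            ac_peaks=read_bed(d / "cd4_t_h3k27ac.bed"),
        )
        assert out["mean_fpkm"]["both_marks"] > out["mean_fpkm"]["neither"]
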