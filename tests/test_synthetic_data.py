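"""Generator contracts: determinism, round-trips, planted structure, rate calibration."""

import numpy as np
import pytest

from conftest import tree_digest
from ldscape.chia_pet import read_bedpe
from ldscape.gene_models import read_fpkm_table, read_gene_table
from ldscape.genomic_intervals import read_bed, read_chrom_sizes
from ldscape.ld_blocks import blocks_from_proxy_table
from ldscape.synthetic_data import (
    InteractionSpec,
    SyntheticConfig,
    TFSpec,
    _block_segments,
    _place_blocks,
    _sample_poisson_intervals,
    generate,
    table1_scenario,
)


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate(SyntheticConfig(seed=5), d1)
        generate(SyntheticConfig(seed=5), d2)
        assert tree_digest(d1) == tree_digest(d2)

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate(SyntheticConfig(seed=5), d1)
        generate(SyntheticConfig(seed=6), d2)
        assert tree_digest(d1) != tree_digest(d2)


class TestRoundTrips:
    def test_proxy_table_reconstructs_planted_spans_exactly(self, bundle):
        recon = blocks_from_proxy_table(bundle.outdir / "proxies.tsv")
        planted = {(b.chrom, b.span.start, b.span.end, tuple(b.member_snps))
                   for b in bundle.truth.blocks}
        rebuilt = {(b.chrom, b.span.start, b.span.end, tuple(b.member_snps))
                   for b in recon}
        assert planted == rebuilt

    def test_every_emitted_file_parses_fully(self, bundle):
        d = bundle.outdir
        sizes = read_chrom_sizes(d / "chrom.sizes")
        assert sizes == {"chrS1": 2_000_000, "chrS2": 1_000_000}
        for name in ("neutrophil_h3k4me1", "neutrophil_h3k27ac",
                     "cd4_t_h3k4me1", "cd4_t_h3k27ac", "tfbs"):
            ivs = read_bed(d / f"{name}.bed")
            assert len(ivs) > 0 and ivs.n_duplicates_dropped == 0
        genes = read_gene_table(d / "genes.tsv")
        fpkm = read_fpkm_table(d / "fpkm.tsv")
        assert {g.gene_id for g in genes} == set(fpkm)
        spec = InteractionSpec()
        n_records = spec.n_unique + spec.n_duplicates + spec.n_decoys
        assert len(read_bedpe(d / "interactions.bedpe")) == n_records

    def test_realized_mark_flags_match_files(self, bundle):
        d = bundle.outdir
        for (cell, mark), flags in bundle.truth.mark_flags.items():
            peaks = read_bed(d / f"{cell}_{mark}.bed")
            for b in bundle.truth.blocks:
                hit = any(p.overlaps(b.span) for p in peaks)
                assert hit == flags[b.block_id], (cell, mark, b.block_id)


class TestPlanting:
    def test_planted_mark_flags_enforced(self, tmp_path):
        cfg = SyntheticConfig(seed=2, interaction_spec=None)
        base = generate(cfg, tmp_path / "probe")
        ids = [b.block_id for b in base.truth.blocks]
        wanted = {bid: (i % 2 == 0) for i, bid in enumerate(ids)}
        cfg2 = SyntheticConfig(
            seed=2, interaction_spec=None,
            planted_mark_flags={("neutrophil", "h3k4me1"): wanted},
        )
        b = generate(cfg2, tmp_path / "planted")
        assert b.truth.mark_flags[("neutrophil", "h3k4me1")] == wanted

    def test_infeasible_block_layout_raises(self, tmp_path):
        cfg = SyntheticConfig(seed=0, n_blocks=100, block_width_range=(90_000, 99_000))
        with pytest.raises(ValueError, match="infeasible"):
            generate(cfg, tmp_path / "x")

    def test_inconsistent_anchor_categories_rejected(self):
        with pytest.raises(ValueError, match="category counts"):
            InteractionSpec(anchor_category_counts={"both_marks": 10, "ac_only": 0,
                                                    "me1_only": 0, "neither": 0})


class TestRateCalibration:
    def test_null_tf_in_out_rate_ratio_near_unity(self):
        """theta = 1 site placement shows no systematic in-block rate excess."""
        config = SyntheticConfig(seed=0)
        within_band = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            blocks = _place_blocks(rng, config)
            segs = _block_segments(config, blocks)
            sites = _sample_poisson_intervals(
                rng, config, segs, rate_out_per_kb=1.0, theta=1.0, width_range=(100, 300)
            )
            block_bp = sum(b.span.width for b in blocks)
            total_bp = sum(config.chrom_sizes.values())
            spans = [(b.chrom, b.span.start, b.span.end) for b in blocks]
            n_in = sum(
                1 for s in sites
                if any(c == s.chrom and lo <= s.start < hi for c, lo, hi in spans)
            )
            n_out = len(sites) - n_in
            rate_in = n_in / (block_bp / 1000)
            rate_out = n_out / ((total_bp - block_bp) / 1000)
            if 0.8 <= rate_in / rate_out <= 1.25:
                within_band += 1
        assert within_band >= 0.9 * n_seeds

    def test_enriched_tf_rate_ratio_tracks_theta(self):
        config = SyntheticConfig(seed=0)
        rng = np.random.default_rng(123)
        blocks = _place_blocks(rng, config)
        segs = _block_segments(config, blocks)
        sites = _sample_poisson_intervals(
            rng, config, segs, rate_out_per_kb=1.0, theta=5.0, width_range=(100, 300)
        )
        spans = [(b.chrom, b.span.start, b.span.end) for b in blocks]
        block_bp = sum(b.span.width for b in blocks)
        total_bp = sum(config.chrom_sizes.values())
        n_in = sum(
            1 for s in sites
            if any(c == s.chrom and lo <= s.start < hi for c, lo, hi in spans)
        )
        ratio = (n_in / (block_bp / 1000)) / ((len(sites) - n_in) / ((total_bp - block_bp) / 1000))
        assert 3.5 < ratio < 6.5


class TestTable1Scenario:
    def test_summary_counts(self, table1_bundle):
        # covered in depth by the histone tests; here: the bundle itself
        blocks = blocks_from_proxy_table(table1_bundle.outdir / "proxies.tsv")
        assert len(blocks) == 23
        assert sum(len(b.member_snps) for b in blocks) == 30

    def test_unmarked_block_has_no_peaks_in_any_set(self, table1_bundle):
        d = table1_bundle.outdir
        target = next(b for b in table1_bundle.truth.blocks
                      if "rs34132030" in b.member_snps)
        for cell in ("neutrophil", "cd4_t"):
            for mark in ("h3k4me1", "h3k27ac"):
                peaks = read_bed(d / f"{cell}_{mark}.bed")
                assert not any(p.overlaps(target.span) for p in peaks)

    def test_tf_specs_recorded_in_truth(self, bundle):
        truth = bundle.truth.tf_truth
        assert truth["TF_ENR1"].theta == 5.0 and truth["TF_NULL1"].theta == 1.0
        assert isinstance(truth["TF_DEP1"], TFSpec) and truth["TF_DEP1"].theta < 1
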