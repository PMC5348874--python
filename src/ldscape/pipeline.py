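"""End-to-end orchestration: LD blocks -> marks -> TFBS -> interactions -> SNP windows.

Stages run off a single config (YAML on disk or a PipelineConfig in memory).
Stages whose inputs are not configured are skipped and recorded as such, so a
bundle carrying only proxy tables and peak BEDs still produces the mark
report. All tables are written sorted on explicit keys; re-running on the
same inputs reproduces the bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chia_pet import (
    ExpressionConfig,
    anchor_category_counts,
    annotate_interactions,
    annotations_to_frame,
    associate_genes_and_expression,
    categorize_anchors,
    pair_class_counts,
    preflight_check,
    read_bedpe,
)
from .gene_models import read_fpkm_table, read_gene_table
from .genomic_intervals import make_bins, read_bed, read_chrom_sizes
from .histone_annotation import annotate_blocks, mark_enrichment_test, summarize_marks
from .ld_blocks import LDConfig, blocks_from_proxy_table, write_blocks_bed
from .snp_windows import WindowConfig, read_snp_table, union_gene_list
from .tfbs_enrichment import (
    EnrichmentConfig,
    read_tfbs_bed,
    results_to_frame,
    run_tfbs_enrichment,
    score_matrix,
)
from .genomic_intervals import IntervalSet

logger = logging.getLogger(__name__)

STAGES = ("ld_blocks", "histone_annotation", "tfbs_enrichment", "chia_pet", "snp_windows")

_MARK_LABEL = {"h3k4me1": "H3K4me1", "h3k27ac": "H3K27ac"}


@dataclass
class PipelineConfig:
    """Input paths plus stage parameters; any input left None skips its stage."""

    output_dir: Path
    chrom_sizes: Path | None = None
    proxies: Path | None = None
    peaks: dict = field(default_factory=dict)  # {cell_type: {mark: path}}
    tfbs: Path | None = None
    genes: Path | None = None
    interactions: Path | None = None
    fpkm: Path | None = None
    snps: Path | None = None
    coordinate_dialects: dict = field(default_factory=dict)  # {input name: dialect}
    ld: LDConfig = field(default_factory=LDConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})

        def _path(key):
            v = inputs.get(key)
            return (base / v) if v else None

        peaks = {
            cell: {mark: base / p for mark, p in marks.items()}
            for cell, marks in (inputs.get("peaks") or {}).items()
        }
        params = raw.get("params", {})
        enr = dict(params.get("enrichment", {}))
        if "promoter_window" in enr:
            enr["promoter_window"] = tuple(enr["promoter_window"])
        return PipelineConfig(
            output_dir=base / raw.get("output_dir", "out"),
            chrom_sizes=_path("chrom_sizes"),
            proxies=_path("proxies"),
            peaks=peaks,
            tfbs=_path("tfbs"),
            genes=_path("genes"),
            interactions=_path("interactions"),
            fpkm=_path("fpkm"),
            snps=_path("snps"),
            coordinate_dialects=raw.get("coordinate_dialects", {}),
            ld=LDConfig(**params.get("ld", {})),
            enrichment=EnrichmentConfig(**enr),
            window=WindowConfig(**params.get("window", {})),
            expression=ExpressionConfig(**params.get("expression", {})),
            seed=int(raw.get("seed", 0)),
        )

    def input_paths(self) -> dict[str, Path]:
        paths = {}
        for key in ("chrom_sizes", "proxies", "tfbs", "genes", "interactions", "fpkm", "snps"):
            p = getattr(self, key)
            if p is not None:
                paths[key] = Path(p)
        for cell, marks in self.peaks.items():
            for mark, p in marks.items():
                paths[f"peaks/{cell}/{mark}"] = Path(p)
        return paths


def validate(config: PipelineConfig) -> dict[str, list[str]]:
    """File-existence, dialect and chromosome-name diagnostics; runs no stage."""
    errors, warnings_ = [], []
    paths = config.input_paths()
    for name, p in paths.items():
        if not p.exists():
            errors.append(f"missing input {name}: {p}")
    for name, dialect in config.coordinate_dialects.items():
        p = paths.get(name)
        if p is None or not p.exists():
            continue
        if dialect == "table1":
            with open(p) as fh:
                for lineno, line in enumerate(fh, start=1):
                    fields = line.rstrip("\n").split("\t")
                    if len(fields) >= 3 and fields[1].lstrip("-").isdigit():
                        if int(fields[1]) < 1:
                            errors.append(
                                f"{name} line {lineno}: start {fields[1]} invalid for a "
                                "1-based inclusive (table1) file"
                            )
        elif dialect != "bed0":
            errors.append(f"{name}: unknown coordinate dialect {dialect!r}")
    # chromosome-name overlap across the interval-bearing inputs
    chrom_sets: dict[str, set[str]] = {}
    if config.chrom_sizes is not None and Path(config.chrom_sizes).exists():
        chrom_sets["chrom_sizes"] = set(read_chrom_sizes(config.chrom_sizes))
    for cell, marks in config.peaks.items():
        for mark, p in marks.items():
            if Path(p).exists():
                chrom_sets[f"peaks/{cell}/{mark}"] = read_bed(p).chromosomes()
    if config.proxies is not None and Path(config.proxies).exists():
        chrom_sets["proxies"] = set(
            pd.read_csv(config.proxies, sep="\t")["chrom"].astype(str)
        )
    names = sorted(chrom_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if chrom_sets[a] and chrom_sets[b] and not (chrom_sets[a] & chrom_sets[b]):
                warnings_.append(
                    f"{a} and {b} share no chromosome names "
                    f"({sorted(chrom_sets[a])[:3]}... vs {sorted(chrom_sets[b])[:3]}...)"
                )
    return {"errors": errors, "warnings": warnings_}


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the report dict (also written as JSON).

    On stage failure, partial outputs are kept and a STATE file names the
    failed stage before the exception propagates.
    """
    diagnostics = validate(config)
    if diagnostics["errors"]:
        raise FileNotFoundError("; ".join(diagnostics["errors"]))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "validation_warnings": diagnostics["warnings"],
        "input_hashes": {
            name: _file_sha256(p) for name, p in sorted(config.input_paths().items())
        },
        "stages": {},
    }
    state_path = out / "STATE"
    current_stage = ""
    try:
        chrom_sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None

        current_stage = "ld_blocks"
        blocks = None
        if config.proxies is not None:
            blocks = blocks_from_proxy_table(config.proxies, config.ld)
            write_blocks_bed(blocks, out / "ld_blocks.bed")
            report["stages"]["ld_blocks"] = {
                "n_blocks": len(blocks),
                "n_snps": sum(len(b.member_snps) for b in blocks),
            }
        else:
            report["stages"]["ld_blocks"] = "skipped"

        current_stage = "histone_annotation"
        peak_sets: dict[tuple[str, str], IntervalSet] = {}
        for cell, marks in sorted(config.peaks.items()):
            for mark, p in sorted(marks.items()):
                peak_sets[(cell, mark)] = read_bed(p)
        if blocks is not None and peak_sets:
            ann_rows, summaries, enrich_rows = [], [], []
            cells = sorted({c for c, _ in peak_sets})
            for cell in cells:
                me1 = peak_sets.get((cell, "h3k4me1"), IntervalSet([]))
                ac = peak_sets.get((cell, "h3k27ac"), IntervalSet([]))
                anns = annotate_blocks(blocks, me1, ac, cell)
                s = summarize_marks(anns)
                summaries.append(s.__dict__)
                for a in anns:
                    ann_rows.append(a.__dict__)
            pd.DataFrame(ann_rows).sort_values(["cell_type", "block_id"]).to_csv(
                out / "mark_annotation.tsv", sep="\t", index=False
            )
            pd.DataFrame(summaries).sort_values("cell_type").to_csv(
                out / "mark_summary.tsv", sep="\t", index=False
            )
            if chrom_sizes is not None:
                bins = make_bins(chrom_sizes, config.enrichment.bin_size)
                for (cell, mark), peaks in sorted(peak_sets.items()):
                    fr = mark_enrichment_test(blocks, peaks, bins)
                    enrich_rows.append(
                        dict(cell_type=cell, mark=mark, odds_ratio=fr.odds_ratio,
                             p_value=fr.p_value, direction=fr.direction,
                             degenerate=fr.degenerate,
                             haldane_corrected=fr.haldane_corrected)
                    )
                pd.DataFrame(enrich_rows).sort_values(["cell_type", "mark"]).to_csv(
                    out / "mark_enrichment.tsv", sep="\t", index=False
                )
            report["stages"]["histone_annotation"] = {
                "summaries": {s["cell_type"]: s for s in summaries}
            }
        else:
            report["stages"]["histone_annotation"] = "skipped"

        current_stage = "tfbs_enrichment"
        if (
            blocks is not None and config.tfbs is not None and config.genes is not None
            and chrom_sizes is not None and peak_sets
        ):
            tfbs = read_tfbs_bed(config.tfbs)
            genes = read_gene_table(config.genes)
            bins = make_bins(chrom_sizes, config.enrichment.bin_size)
            block_set = IntervalSet([b.span for b in blocks])
            stage_report = {}
            for cell in sorted({c for c, _ in peak_sets}):
                mark_peaks = {
                    _MARK_LABEL[mark]: peak_sets[(cell, mark)]
                    for (c, mark) in peak_sets
                    if c == cell and mark in _MARK_LABEL
                }
                results = run_tfbs_enrichment(
                    tfbs, mark_peaks, block_set, bins, genes, config.enrichment
                )
                df = results_to_frame(results)
                df.to_csv(out / f"tfbs_enrichment_{cell}.tsv", sep="\t", index=False)
                sm = score_matrix(results)
                sm.to_csv(out / f"tfbs_scores_{cell}.tsv", sep="\t")
                stage_report[cell] = {
                    "n_significant": int(df["significant"].sum()) if not df.empty else 0,
                    "n_tests": int(len(df)),
                }
            report["stages"]["tfbs_enrichment"] = stage_report
        else:
            report["stages"]["tfbs_enrichment"] = "skipped"

        current_stage = "chia_pet"
        if blocks is not None and config.interactions is not None and config.genes is not None:
            interactions = read_bedpe(config.interactions)
            if chrom_sizes is not None:
                preflight_check(interactions, chrom_sizes)
            genes = read_gene_table(config.genes)
            me1 = peak_sets.get(("cd4_t", "h3k4me1"), IntervalSet([]))
            ac = peak_sets.get(("cd4_t", "h3k27ac"), IntervalSet([]))
            window = config.enrichment.promoter_window
            unique, annotations, provenance = annotate_interactions(
                interactions, blocks, genes, me1, ac, window
            )
            df = annotations_to_frame(annotations)
            df["n_source_records"] = df["interaction_id"].map(provenance)
            df.to_csv(out / "chia_annotations.tsv", sep="\t", index=False)
            cats = categorize_anchors(unique, me1, ac)
            summary = {
                "n_input": len(interactions),
                "n_in_blocks": int(sum(provenance.values())),
                "n_unique": len(unique),
                "pair_classes": pair_class_counts(annotations),
                "anchor_categories": anchor_category_counts(cats),
            }
            if config.fpkm is not None:
                fpkm = read_fpkm_table(config.fpkm)
                assoc = associate_genes_and_expression(
                    unique, genes, fpkm, config.expression, me1, ac, window
                )
                pd.DataFrame(
                    [
                        dict(category=c, gene_id=g)
                        for c, gs in sorted(assoc["category_genes"].items())
                        for g in gs
                    ]
                ).to_csv(out / "chia_genes.tsv", sep="\t", index=False)
                summary["n_associated_genes"] = len(assoc["all_genes"])
                summary["mean_fpkm"] = assoc["mean_fpkm"]
                summary["high_expression_genes"] = assoc["high_expression_genes"]
            report["stages"]["chia_pet"] = summary
            with open(out / "chia_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
        else:
            report["stages"]["chia_pet"] = "skipped"

        current_stage = "snp_windows"
        if config.snps is not None and config.genes is not None:
            snps = read_snp_table(config.snps)
            genes = read_gene_table(config.genes)
            df = union_gene_list(snps, genes, config.window, chrom_sizes)
            df.to_csv(out / "snp_window_genes.tsv", sep="\t", index=False)
            report["stages"]["snp_windows"] = {"n_genes": int(len(df))}
        else:
            report["stages"]["snp_windows"] = "skipped"
    except Exception:
        state_path.write_text(f"FAILED at stage: {current_stage}\n")
        raise
    if state_path.exists():
        state_path.unlink()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
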