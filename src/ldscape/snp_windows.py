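"""Genes within a flanking window of each risk SNP, as input for pathway tools.

The default window spans 200 kb on either side of the SNP; a gene belongs to a
SNP iff its body overlaps the window. The union list carries, per gene, every
contributing SNP, and is exported as a TSV suitable for pasting into external
pathway-enrichment services (the enrichment itself is out of scope here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .gene_models import GeneModel

SNP_COLUMNS = ["snp_id", "chrom", "position"]


@dataclass(frozen=True)
class SNPLocus:
    """A risk SNP at a 0-based position."""

    snp_id: str
    chrom: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")


@dataclass(frozen=True)
class WindowConfig:
    """Flank size in bp on each side of the SNP (default 200 kb)."""

    flank: int = 200_000

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError(f"flank must be > 0, got {self.flank}")


def genes_in_window(
    snp: SNPLocus,
    genes: Sequence[GeneModel],
    config: WindowConfig = WindowConfig(),
    chrom_sizes: dict[str, int] | None = None,
) -> set[str]:
    """Gene ids whose body overlaps [position - flank, position + flank].

    The window is clipped at 0 and, when sizes are given, at the chromosome
    end; an unknown chromosome yields an empty set with a warning.
    """
    if chrom_sizes is not None and snp.chrom not in chrom_sizes:
        warnings.warn(f"SNP {snp.snp_id}: unknown chromosome {snp.chrom}", stacklevel=2)
        return set()
    lo = max(snp.position - config.flank, 0)
    hi = snp.position + config.flank + 1  # inclusive endpoint, half-open interval
    if chrom_sizes is not None:
        hi = min(hi, chrom_sizes[snp.chrom])
    return {
        g.gene_id
        for g in genes
        if g.chrom == snp.chrom and g.start < hi and lo < g.end
    }


def union_gene_list(
    snps: Sequence[SNPLocus],
    genes: Sequence[GeneModel],
    config: WindowConfig = WindowConfig(),
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Deduplicated union over SNP windows; per gene, the contributing SNPs.

    Returns a DataFrame with columns gene_id and contributing_snps
    (comma-separated), sorted by gene_id.
    """
    contributors: dict[str, set[str]] = {}
    for snp in snps:
        for gene_id in genes_in_window(snp, genes, config, chrom_sizes):
            contributors.setdefault(gene_id, set()).add(snp.snp_id)
    rows = [
        {"gene_id": g, "contributing_snps": ",".join(sorted(s))}
        for g, s in sorted(contributors.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "contributing_snps"])


def read_snp_table(path: str | Path) -> list[SNPLocus]:
    """TSV with columns snp_id, chrom, position (0-based)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    return [
        SNPLocus(str(r.snp_id), str(r.chrom), int(r.position))
        for r in df.itertuples(index=False)
    ]
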