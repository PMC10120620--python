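"""Gene models as a tabular container.

A gene-model table is a pandas DataFrame with columns
``gene_id, chrom, strand, tss, length`` (TSS in 0-based coordinates, length
in bp). Promoters are symmetric windows around the TSS, shared by the
enhancer-landscape and target-wiring stages so that "promoter" and
"non-promoter" are complementary by construction.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "length"]

__all__ = ["GENE_COLUMNS", "read_gene_models", "write_gene_models",
           "promoters_of"]


def read_gene_models(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene model table missing columns: {missing}")
    return genes[GENE_COLUMNS].copy()


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def promoters_of(genes: pd.DataFrame, window: int = 2000) -> IntervalSet:
    """Promoter intervals TSS +/- window, clipped at 0, one per gene."""
    if window <= 0:
        raise ValueError("promoter window must be positive")
    ivs = []
    for row in genes.itertuples(index=False):
        start = max(0, int(row.tss) - window)
        ivs.append(
            GenomicInterval(row.chrom, start, int(row.tss) + window,
                            name=str(row.gene_id))
        )
    return IntervalSet(ivs, label="promoters")
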