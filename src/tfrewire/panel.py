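"""Tissue-panel analyses of the four master TFs.

Three views of lineage enrichment across a pan-tissue panel: (i) k-means
clustering of tissues by their mean 4-TF expression profile, (ii) ranking
tissues by the average pairwise Pearson correlation of the four TFs across
samples (the core-regulatory-circuitry signature: co-regulated factors
correlate within the tissue that depends on them), and (iii)
immunohistochemistry co-positivity: how many of the four factors stain
positive per sample at a positivity-rate threshold.

Expression is expected on a log scale (log2(TPM + 1) by convention here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cobinding import TFS

DEFAULT_POSITIVITY_THRESHOLD = 0.1

__all__ = [
    "cluster_tissues",
    "rank_by_correlation",
    "co_positivity",
]


def _tf_columns(df: pd.DataFrame, tf_columns: Sequence[str] | None) -> list[str]:
    cols = list(tf_columns) if tf_columns is not None else [
        c for c in TFS if c in df.columns
    ]
    if len(cols) != 4:
        raise ValueError(f"expected exactly 4 TF columns, got {cols}")
    return cols


def cluster_tissues(
    expr: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    tissue_column: str = "tissue",
    tf_columns: Sequence[str] | None = None,
    n_restarts: int = 20,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means clustering of tissues on z-scored mean 4-TF profiles.

    Profiles are per-tissue means of each TF column, z-scored per TF across
    tissues (constant TFs are set to zero with a warning). Runs
    ``n_restarts`` k-means initializations and keeps the best inertia;
    deterministic given ``seed``. Returns (tissue -> cluster id, per-cluster
    mean profile on the z scale).
    """
    cols = _tf_columns(expr, tf_columns)
    profiles = expr.groupby(tissue_column)[cols].mean()
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of tissues ({len(profiles)})")
    z = profiles.to_numpy(dtype=float)
    mu = z.mean(axis=0)
    sd = z.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("constant TF expression across tissues; z-score set to 0")
        sd = np.where(degenerate, 1.0, sd)
    z = (z - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    assignment = pd.Series(labels, index=profiles.index, name="cluster")
    centers = pd.DataFrame(km.cluster_centers_, columns=cols)
    centers.index.name = "cluster"
    return assignment, centers


def rank_by_correlation(
    expr: pd.DataFrame,
    tissue_column: str = "tissue",
    tf_columns: Sequence[str] | None = None,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Rank tissues by the mean pairwise Pearson correlation of the 4 TFs.

    For each tissue, Pearson r is computed across its samples for all 6 TF
    pairs; the tissue score is the mean of the defined pairs (a pair is
    undefined, and flagged, when either TF has zero variance in the tissue).
    Tissues are ranked by score descending; ties share the order of their
    (alphabetical) names and are flagged. Tissues with fewer than
    ``min_samples`` samples are excluded.
    """
    cols = _tf_columns(expr, tf_columns)
    rows = []
    for tissue, sub in expr.groupby(tissue_column):
        if len(sub) < min_samples:
            continue
        vals = sub[cols].to_numpy(dtype=float)
        rs = []
        undefined = 0
        for a, b in combinations(range(4), 2):
            xa, xb = vals[:, a], vals[:, b]
            if xa.std() == 0 or xb.std() == 0:
                undefined += 1
                continue
            rs.append(float(np.corrcoef(xa, xb)[0, 1]))
        mean_r = float(np.mean(rs)) if rs else float("nan")
        rows.append((tissue, mean_r, len(sub), undefined))
    out = pd.DataFrame(
        rows, columns=["tissue", "mean_pairwise_r", "n_samples",
                       "n_undefined_pairs"]
    )
    out = out.sort_values(
        ["mean_pairwise_r", "tissue"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["tied"] = out["mean_pairwise_r"].duplicated(keep=False)
    return out


def co_positivity(
    tab: pd.DataFrame,
    threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
    histotype_column: str = "histotype",
    tf_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Distribution of the number of TFs staining positive per sample.

    A TF is positive in a sample iff its positivity rate is >= threshold
    (inclusive). Returns per histotype the fraction of samples with k = 0..4
    positive TFs plus the fraction co-staining all four; fractions per
    histotype sum to 1 over the k bins.
    """
    cols = _tf_columns(tab, tf_columns)
    rates = tab[cols].to_numpy(dtype=float)
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("positivity rates must lie in [0, 1]")
    n_pos = (rates >= threshold).sum(axis=1)
    rows = []
    for histotype, idx in tab.groupby(histotype_column).groups.items():
        counts = n_pos[tab.index.get_indexer(idx)]
        n = len(counts)
        fracs = [float(np.mean(counts == k)) for k in range(5)]
        rows.append((histotype, n, *fracs, fracs[4]))
    return pd.DataFrame(
        rows,
        columns=["histotype", "n_samples", "frac_0", "frac_1", "frac_2",
                 "frac_3", "frac_4", "frac_all_four"],
    )
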