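"""Spike-in-anchored normalization and high-confidence DEG calling for
TF-knockdown RNA-seq.

Counts are converted to transcripts-per-million (TPM), then normalized by
cyclic pairwise loess on the log2(TPM + pseudocount) scale. The loess curves
are fitted ONLY on anchor rows — the ERCC spike-ins, which were added to
each sample at a fixed per-cell amount — and the fitted correction is
applied to every row. Anchoring on spike-ins lets a genuine global
transcriptional shift survive normalization (the spike-ins certify it is
biological), while a distortion that also affects spike-ins (library depth /
composition artifacts) is removed. This is the distinction that makes
knockdown-induced global expression shifts measurable at all.

Differential calling is deliberately an effect-size threshold rule, not a
dispersion model: a gene is a high-confidence target of a TF in a context
when |log2FC| >= 0.5 in BOTH cell lines of that context with concordant
sign, each log2FC taken against the two pooled control conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

CONTROL_CONDITIONS = ("control_1", "control_2")
KNOCKDOWN_CONDITIONS = ("siMECOM", "siPAX8", "siSOX17", "siWT1")
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_SPAN = 0.6
DEFAULT_THRESHOLD = 0.5

__all__ = [
    "CountMatrix",
    "DegTable",
    "tpm",
    "loess_normalize",
    "log2fc",
    "call_high_confidence",
]


@dataclass
class CountMatrix:
    """Gene-level counts with gene and sample metadata.

    ``counts``: genes x samples nonnegative values. ``gene_meta`` is indexed
    like counts rows with columns ``length`` (bp) and ``is_spikein``;
    ``sample_meta`` is indexed like counts columns with columns
    ``cell_line``, ``context``, ``condition``, ``replicate``.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_meta.index):
            raise ValueError("gene_meta index must match counts rows")
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match counts columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def spikein_mask(self) -> np.ndarray:
        return self.gene_meta["is_spikein"].to_numpy(dtype=bool)

    def write(self, counts_path: str | Path, genes_path: str | Path,
              samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.gene_meta.to_csv(genes_path, sep="\t", index_label="gene_id")
        self.sample_meta.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, counts_path: str | Path, genes_path: str | Path,
             samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        gene_meta = pd.read_csv(genes_path, sep="\t", index_col="gene_id")
        sample_meta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(counts, gene_meta, sample_meta)


@dataclass
class DegTable:
    """Per-gene knockdown effects and high-confidence flags.

    ``per_cell_line``: rows (gene_id, tf, cell_line, context, log2fc);
    ``per_context``: rows (gene_id, tf, context, log2fc_mean, high_confidence,
    direction) where direction is 'up'/'down' after knockdown.
    """

    per_cell_line: pd.DataFrame
    per_context: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD

    def high_confidence(self, tf: Optional[str] = None,
                        context: Optional[str] = None) -> pd.DataFrame:
        out = self.per_context[self.per_context["high_confidence"]]
        if tf is not None:
            out = out[out["tf"] == tf]
        if context is not None:
            out = out[out["context"] == context]
        return out.copy()


def tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: per sample, length-normalized rates scaled
    so each column sums to 1e6 (all-zero columns stay zero, with a warning)."""
    lengths = counts.gene_meta["length"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.counts.to_numpy(dtype=float) / (lengths[:, None] / 1e3)
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn("all-zero sample column(s); TPM left as zeros")
        colsum = np.where(zero, 1.0, colsum)
    out = rate / colsum[None, :] * 1e6
    return pd.DataFrame(out, index=counts.counts.index,
                        columns=counts.counts.columns)


def _fitted_m(
    log_mat: np.ndarray,
    i: int,
    j: int,
    anchor: np.ndarray,
    span: float,
) -> np.ndarray:
    """Loess curve of M = log-ratio vs A = log-mean for samples (i, j),
    fitted on anchor rows only and evaluated at every row's A."""
    a_all = 0.5 * (log_mat[:, i] + log_mat[:, j])
    m_all = log_mat[:, i] - log_mat[:, j]
    a_anchor = a_all[anchor]
    m_anchor = m_all[anchor]
    if np.ptp(a_anchor) == 0:
        return np.full_like(a_all, float(np.median(m_anchor)))
    fit = lowess(m_anchor, a_anchor, frac=span, it=0, return_sorted=True)
    return np.interp(a_all, fit[:, 0], fit[:, 1])


def loess_normalize(
    tpm_mat: pd.DataFrame,
    spikein_mask: Optional[np.ndarray] = None,
    anchor: Literal["spikeins_only", "all_genes"] = "spikeins_only",
    span: float = DEFAULT_SPAN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_passes: int = 3,
    tol: float = 0.01,
    min_anchor_rows: int = 20,
) -> pd.DataFrame:
    """Cyclic pairwise loess normalization anchored on spike-ins.

    Works on log2(TPM + pseudocount). For every sample pair, a degree-1
    loess curve of M (log-ratio) against A (log-mean) is fitted on the
    anchor rows only and half the fitted M is subtracted from one sample and
    added to the other — for ALL rows. Passes over all pairs repeat until
    the largest |median anchor M| across pairs drops below ``tol`` or
    ``max_passes`` passes have run. Returns the matrix back on the TPM scale
    (clipped at 0 where the correction pushes a zero-TPM row negative).
    """
    x = tpm_mat.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples to normalize")
    if anchor == "spikeins_only":
        if spikein_mask is None:
            raise ValueError("spikein_mask required for anchor='spikeins_only'")
        anchor_rows = np.asarray(spikein_mask, dtype=bool)
        nonzero_anchor = anchor_rows & (x.sum(axis=1) > 0)
        if int(nonzero_anchor.sum()) < min_anchor_rows:
            raise ValueError(
                f"spike-in anchoring needs >= {min_anchor_rows} spike-in rows "
                f"with nonzero counts, got {int(nonzero_anchor.sum())}"
            )
        anchor_rows = nonzero_anchor
    elif anchor == "all_genes":
        anchor_rows = np.ones(n_genes, dtype=bool)
    else:
        raise ValueError(f"unknown anchor mode {anchor!r}")

    log_mat = np.log2(x + pseudocount)
    pairs = [(i, j) for i in range(n_samples) for j in range(i + 1, n_samples)]
    for _ in range(max_passes):
        worst = 0.0
        for i, j in pairs:
            m_anchor = log_mat[anchor_rows, i] - log_mat[anchor_rows, j]
            worst = max(worst, abs(float(np.median(m_anchor))))
        if worst < tol:
            break
        # one pass: every sample moves by the average of its fitted pairwise
        # log-ratios (1/n per pair, applied after the full sweep), so a
        # constant distortion is removed in a single pass; for two samples
        # this is exactly a half-M shift on each side
        delta = np.zeros_like(log_mat)
        for i, j in pairs:
            fitted = _fitted_m(log_mat, i, j, anchor_rows, span)
            delta[:, i] += fitted / n_samples
            delta[:, j] -= fitted / n_samples
        log_mat -= delta
    out = np.clip(np.exp2(log_mat) - pseudocount, 0.0, None)
    return pd.DataFrame(out, index=tpm_mat.index, columns=tpm_mat.columns)


def log2fc(
    norm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    tf_condition: str,
    control_conditions: Sequence[str] = CONTROL_CONDITIONS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene, per-cell-line log2 fold-change of a knockdown vs pooled
    controls.

    log2FC = mean over knockdown replicates of log2(TPM + pc) minus the mean
    over the POOLED replicates of both control conditions. Returns a
    DataFrame genes x cell lines.
    """
    missing = [c for c in (tf_condition, *control_conditions)
               if c not in set(sample_meta["condition"])]
    if missing:
        raise ValueError(f"conditions absent from sample metadata: {missing}")
    logx = np.log2(norm.to_numpy(dtype=float) + pseudocount)
    out: dict[str, np.ndarray] = {}
    for cell_line, meta in sample_meta.groupby("cell_line", sort=True):
        kd_cols = meta.index[meta["condition"] == tf_condition]
        ctrl_cols = meta.index[meta["condition"].isin(control_conditions)]
        if len(kd_cols) == 0 or len(ctrl_cols) == 0:
            continue
        kd_idx = [norm.columns.get_loc(c) for c in kd_cols]
        ctrl_idx = [norm.columns.get_loc(c) for c in ctrl_cols]
        out[cell_line] = logx[:, kd_idx].mean(axis=1) - logx[:, ctrl_idx].mean(axis=1)
    return pd.DataFrame(out, index=norm.index)


def call_high_confidence(
    fc_by_cell_line: pd.DataFrame,
    cell_line_context: dict[str, str],
    tf: str,
    threshold: float = DEFAULT_THRESHOLD,
    allow_single_line: bool = False,
) -> DegTable:
    """Apply the high-confidence threshold rule per context.

    A gene is a high-confidence target in a context iff |log2FC| >=
    threshold (inclusive) in BOTH of the context's cell lines AND the sign
    agrees. Direction is taken from the sign of the mean log2FC. Contexts
    with a single cell line are rejected unless ``allow_single_line``.
    """
    ctx_lines: dict[str, list[str]] = {}
    for line in fc_by_cell_line.columns:
        if line not in cell_line_context:
            raise ValueError(f"no context given for cell line {line!r}")
        ctx_lines.setdefault(cell_line_context[line], []).append(line)

    per_cell_rows = []
    for line in fc_by_cell_line.columns:
        for gene, v in fc_by_cell_line[line].items():
            per_cell_rows.append(
                (gene, tf, line, cell_line_context[line], float(v))
            )
    per_cell = pd.DataFrame(
        per_cell_rows,
        columns=["gene_id", "tf", "cell_line", "context", "log2fc"],
    )

    ctx_rows = []
    for context, lines in sorted(ctx_lines.items()):
        if len(lines) < 2 and not allow_single_line:
            raise ValueError(
                f"context {context!r} has a single cell line; pass "
                "allow_single_line=True to call on one line"
            )
        sub = fc_by_cell_line[lines].to_numpy(dtype=float)
        passes = np.all(np.abs(sub) >= threshold, axis=1)
        signs = np.sign(sub)
        concordant = np.all(signs == signs[:, [0]], axis=1) & np.all(
            signs != 0, axis=1
        )
        hc = passes & concordant if len(lines) > 1 else passes & (signs[:, 0] != 0)
        mean_fc = sub.mean(axis=1)
        for g, gene in enumerate(fc_by_cell_line.index):
            ctx_rows.append(
                (
                    gene, tf, context, float(mean_fc[g]), bool(hc[g]),
                    "up" if mean_fc[g] > 0 else "down",
                )
            )
    per_context = pd.DataFrame(
        ctx_rows,
        columns=["gene_id", "tf", "context", "log2fc_mean",
                 "high_confidence", "direction"],
    )
    return DegTable(per_cell_line=per_cell, per_context=per_context,
                    threshold=threshold)
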