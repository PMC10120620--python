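"""TAD-aware TF target classification and core-regulatory-circuit inference.

Every high-confidence differentially expressed gene (DEG) after a TF
knockdown is classified, per TF and context, into exactly one of three
modes:

* **direct** — a peak of that TF overlaps the gene's promoter;
* **putative** — the TF binds a non-promoter region inside the same TAD as
  the gene's TSS (and not its promoter);
* **indirect** — the TF has no peak anywhere inside the gene's TAD.

Precedence is direct > putative > indirect, so the classes partition the
DEG set. A gene's TAD is the (smallest) domain containing its TSS; genes
whose TSS lies in no TAD can still be direct via promoter overlap and are
otherwise indirect.

The core regulatory circuit is the signed directed graph among the master
TFs themselves: regulator -> target with sign "activates" when the target
drops after regulator knockdown and "represses" when it rises, kept only
when the effect passes the high-confidence rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cobinding import TFS
from .expression import DegTable
from .genes import promoters_of
from .intervals import GenomicInterval, IntervalSet
from .tads import TadMap

logger = logging.getLogger(__name__)

MODES = ("direct", "putative", "indirect")

__all__ = ["MODES", "TargetCall", "CircuitGraph", "classify_targets",
           "rewiring_summary", "build_circuit"]


@dataclass(frozen=True)
class TargetCall:
    """One (TF, gene, context) target classification."""

    tf: str
    gene: str
    context: str
    mode: str            # direct | putative | indirect
    sign: str            # up | down (post-knockdown direction)
    evidence: str = "none"   # supporting peak id(s) or "none"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sign not in ("up", "down"):
            raise ValueError(f"unknown sign {self.sign!r}")


@dataclass
class CircuitGraph:
    """Signed directed regulation graph among the master TFs.

    ``edges`` rows: (regulator, target, context, sign, log2fc_mean) with
    sign in {activates, represses}. Self-edges (autoregulation) are allowed.
    """

    nodes: tuple[str, ...]
    edges: pd.DataFrame

    def edge_set(self, context: Optional[str] = None) -> set[tuple[str, str, str]]:
        e = self.edges
        if context is not None:
            e = e[e["context"] == context]
        return {(r.regulator, r.target, r.sign) for r in e.itertuples(index=False)}

    def to_dot(self) -> str:
        lines = ["digraph circuit {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for r in self.edges.sort_values(
            ["context", "regulator", "target"]
        ).itertuples(index=False):
            style = "normal" if r.sign == "activates" else "tee"
            lines.append(
                f'  "{r.regulator}" -> "{r.target}" '
                f'[arrowhead={style}, label="{r.context}"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"


def _peak_label(peak: GenomicInterval) -> str:
    return peak.name or f"{peak.chrom}:{peak.start}-{peak.end}"


def classify_targets(
    deg: DegTable,
    peaks: Mapping[str, IntervalSet],
    genes: pd.DataFrame,
    tads: TadMap,
    context: str,
    promoter_window: int = 2000,
    promoters: Optional[IntervalSet] = None,
) -> list[TargetCall]:
    """Classify every high-confidence DEG of every TF in one context.

    ``peaks`` maps TF name -> that TF's peak set in this context. The
    promoter set defaults to TSS +/- promoter_window from the shared gene
    models, so "promoter" and "non-promoter" are complementary. Genes absent
    from the gene models are skipped with a logged warning. Output order is
    (tf, gene) sorted; the result is invariant to peak and TAD input order.
    """
    gene_rows = {str(r.gene_id): r for r in genes.itertuples(index=False)}
    if promoters is None:
        promoters = promoters_of(genes, promoter_window)
    promoter_by_gene = {iv.name: iv for iv in promoters}

    calls: list[TargetCall] = []
    hc = deg.per_context[
        (deg.per_context["high_confidence"])
        & (deg.per_context["context"] == context)
    ]
    for tf, sub in hc.groupby("tf", sort=True):
        tf_peaks = peaks.get(tf)
        if tf_peaks is None:
            raise ValueError(f"no peak set supplied for TF {tf!r}")
        for row in sub.sort_values("gene_id").itertuples(index=False):
            gene_id = str(row.gene_id)
            grow = gene_rows.get(gene_id)
            if grow is None:
                logger.warning("gene %s missing from gene models; skipped",
                               gene_id)
                continue
            sign = row.direction
            prom = promoter_by_gene.get(gene_id)
            if prom is None:
                prom = GenomicInterval(
                    grow.chrom, max(0, int(grow.tss) - promoter_window),
                    int(grow.tss) + promoter_window, name=gene_id,
                )
            prom_set = IntervalSet([prom])
            prom_hits = prom_set.overlap_pair_indices(tf_peaks)
            if prom_hits:
                ev = ",".join(
                    sorted(_peak_label(tf_peaks[j]) for _, j in prom_hits)
                )
                calls.append(TargetCall(tf, gene_id, context, "direct",
                                        sign, ev))
                continue
            tad = tads.containing(grow.chrom, int(grow.tss))
            mode = "indirect"
            ev = "none"
            if tad is not None:
                tad_set = IntervalSet([tad])
                tad_hits = tad_set.overlap_pair_indices(tf_peaks)
                if tad_hits:
                    mode = "putative"
                    ev = ",".join(
                        sorted(_peak_label(tf_peaks[j]) for _, j in tad_hits)
                    )
            calls.append(TargetCall(tf, gene_id, context, mode, sign, ev))
    return calls


def calls_to_frame(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.tf, c.gene, c.context, c.mode, c.sign, c.evidence) for c in calls],
        columns=["tf", "gene", "context", "mode", "sign", "evidence"],
    )


def rewiring_summary(
    calls_a: Sequence[TargetCall],
    calls_b: Sequence[TargetCall],
) -> pd.DataFrame:
    """Per-TF transition table between two contexts.

    Rows per TF: counts of target genes exclusive to context A, exclusive to
    B, and shared; for shared genes a mode-transition count per
    (mode_in_A, mode_in_B) pair. Returned long-form with a ``category``
    column in {exclusive_a, exclusive_b, shared, transition}; transition rows
    carry mode_a/mode_b.
    """
    a_by = {(c.tf, c.gene): c for c in calls_a}
    b_by = {(c.tf, c.gene): c for c in calls_b}
    tfs = sorted({c.tf for c in calls_a} | {c.tf for c in calls_b})
    rows = []
    for tf in tfs:
        a_genes = {g for (t, g) in a_by if t == tf}
        b_genes = {g for (t, g) in b_by if t == tf}
        shared = a_genes & b_genes
        rows.append((tf, "exclusive_a", None, None, len(a_genes - b_genes)))
        rows.append((tf, "exclusive_b", None, None, len(b_genes - a_genes)))
        rows.append((tf, "shared", None, None, len(shared)))
        trans: dict[tuple[str, str], int] = {}
        for g in shared:
            key = (a_by[(tf, g)].mode, b_by[(tf, g)].mode)
            trans[key] = trans.get(key, 0) + 1
        for (ma, mb) in sorted(trans):
            rows.append((tf, "transition", ma, mb, trans[(ma, mb)]))
    return pd.DataFrame(
        rows, columns=["tf", "category", "mode_a", "mode_b", "count"]
    )


def build_circuit(
    deg_by_tf: Mapping[str, DegTable],
    tf_genes: Mapping[str, str] | None = None,
    nodes: Sequence[str] = TFS,
) -> CircuitGraph:
    """Infer the signed core-regulatory circuit among the master TFs.

    ``deg_by_tf`` maps each regulator to the DegTable of its knockdown;
    ``tf_genes`` maps TF name -> gene id of the TF's own gene (identity by
    default). An edge regulator -> target exists per context iff the target
    gene passes the high-confidence rule under the regulator's knockdown;
    sign is "activates" when the target goes down and "represses" when up.
    """
    if tf_genes is None:
        tf_genes = {tf: tf for tf in nodes}
    rows = []
    for regulator in nodes:
        deg = deg_by_tf.get(regulator)
        if deg is None:
            continue
        hc = deg.per_context[deg.per_context["high_confidence"]]
        for target in nodes:
            gene_id = tf_genes[target]
            sub = hc[hc["gene_id"] == gene_id]
            for r in sub.itertuples(index=False):
                sign = "activates" if r.direction == "down" else "represses"
                rows.append((regulator, target, r.context, sign,
                             float(r.log2fc_mean)))
    edges = pd.DataFrame(
        rows,
        columns=["regulator", "target", "context", "sign", "log2fc_mean"],
    )
    return CircuitGraph(nodes=tuple(nodes), edges=edges)


def write_calls(calls: Sequence[TargetCall], path: str | Path) -> Path:
    path = Path(path)
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
    return path


def read_calls(path: str | Path) -> list[TargetCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        TargetCall(str(r.tf), str(r.gene), str(r.context), str(r.mode),
                   str(r.sign), str(r.evidence))
        for r in df.itertuples(index=False)
    ]
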