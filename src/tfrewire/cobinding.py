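"""Multi-TF co-occupancy, context comparison, and the permutation
enrichment test for TF binding at context-specific enhancers.

Co-binding is quantified on two complementary views: per merged union region
(how many of the four TFs touch each region) and per TF peak (what fraction
of a factor's own peaks are co-bound by at least one other factor). Both are
reported because cistrome studies quote both kinds of number.

The permutation test asks whether enhancers are bound by the master TFs more
often than expected by chance. The null relocates each enhancer uniformly at
random within its own chromosome, preserving its length, with placements
independent (relocated enhancers may overlap); the TF cistrome — the
quantity under test — is held fixed. The empirical p-value uses the add-one
estimator p = (1 + #{null >= observed}) / (N + 1), so p is never zero and
its floor with the default N = 9,999 permutations is 1e-4. The test is
one-sided for enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .enhancers import ChromatinStateMap
from .intervals import GenomeLayout, GenomicInterval, IntervalSet, SignalTrack

TFS = ("MECOM", "PAX8", "SOX17", "WT1")

STATE_PRECEDENCE = (
    "promoter",
    "super_enhancer",
    "typical_enhancer",
    "super_methylated",
    "typical_methylated",
)

__all__ = [
    "TFS",
    "STATE_PRECEDENCE",
    "CobindingTable",
    "ContextComparison",
    "PermutationResult",
    "count_cobinding",
    "annotate_state",
    "compare_contexts",
    "enhancer_binding_permutation",
    "signal_matrix",
]


@dataclass
class CobindingTable:
    """Union-region TF membership with chromatin-state annotation.

    ``table`` has one row per merged union region with boolean membership
    columns per TF, ``n_tfs_bound``, and ``state``; ``per_tf_cobound_fraction``
    is the per-peak view: for each TF, the fraction of its peaks overlapped by
    at least one other TF's peak.
    """

    table: pd.DataFrame
    regions: IntervalSet
    per_tf_cobound_fraction: dict[str, float]
    context: str = ""

    def n_bound_counts(self) -> pd.Series:
        """Number of union regions bound by k TFs, k = 0..n_tfs."""
        n_tfs = len(self.per_tf_cobound_fraction)
        return (
            self.table["n_tfs_bound"]
            .value_counts()
            .reindex(range(0, n_tfs + 1), fill_value=0)
            .sort_index()
        )


@dataclass
class ContextComparison:
    """Common vs context-specific peak classification for one TF.

    ``common_regions`` is the number of merged union regions formed by the
    reciprocally overlapping peaks of the two contexts (one count, not one
    per side); ``specific_a``/``specific_b`` count peaks private to each
    context. ``fraction_common = common / (common + specific_a + specific_b)``.
    """

    tf: str
    context_a: str
    context_b: str
    specific_a: int
    specific_b: int
    common_regions: int
    common_peaks_a: int
    common_peaks_b: int
    specific_a_peaks: IntervalSet
    specific_b_peaks: IntervalSet
    common_merged: IntervalSet

    @property
    def fraction_common(self) -> float:
        denom = self.common_regions + self.specific_a + self.specific_b
        return self.common_regions / denom if denom else 0.0


@dataclass
class PermutationResult:
    """One-sided permutation enrichment result."""

    observed_statistic: float
    null_draws: np.ndarray
    n_permutations: int
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def p_empirical(self) -> float:
        n_ge = int(np.sum(self.null_draws >= self.observed_statistic))
        return (1 + n_ge) / (self.n_permutations + 1)


def annotate_state(region: GenomicInterval, state_map: ChromatinStateMap) -> str:
    """Assign exactly one chromatin-state label to a region.

    Precedence promoter > super_enhancer > typical_enhancer >
    super_methylated > typical_methylated > none; membership is >= 1 bp
    overlap with the class's intervals.
    """
    q = IntervalSet([region])
    classes = state_map.classes()
    for label in STATE_PRECEDENCE:
        if q.overlap_pair_indices(classes[label]):
            return label
    return "none"


def _annotate_many(regions: IntervalSet, state_map: ChromatinStateMap) -> list[str]:
    labels = ["none"] * len(regions)
    undecided = np.ones(len(regions), dtype=bool)
    classes = state_map.classes()
    for label in STATE_PRECEDENCE:
        hits = regions.overlaps_any(classes[label])
        take = hits & undecided
        for i in np.nonzero(take)[0]:
            labels[i] = label
        undecided &= ~hits
    return labels


def count_cobinding(
    peaksets: Mapping[str, IntervalSet],
    state_map: Optional[ChromatinStateMap] = None,
    context: str = "",
) -> CobindingTable:
    """Build the union-region co-binding table for the given TF peak sets.

    Union regions are the merge (gap 0) of all peaks pooled across TFs; a TF
    is bound at a region when at least one of its peaks overlaps it. Also
    computes, per TF, the fraction of its own peaks co-bound by >= 1 other
    TF (overlapping any other factor's peak).
    """
    nonempty = {tf: ps for tf, ps in peaksets.items() if len(ps) > 0}
    if not nonempty:
        raise ValueError("need at least one nonempty peak set")
    pooled = IntervalSet(
        [iv for ps in peaksets.values() for iv in ps], label="union"
    )
    union = pooled.merge(0)
    data: dict[str, object] = {
        "chrom": [iv.chrom for iv in union],
        "start": [iv.start for iv in union],
        "end": [iv.end for iv in union],
    }
    membership = {}
    for tf, ps in peaksets.items():
        membership[tf] = union.overlaps_any(ps)
        data[tf] = membership[tf]
    n_bound = np.sum(np.column_stack(list(membership.values())), axis=1)
    data["n_tfs_bound"] = n_bound.astype(int)
    if state_map is not None:
        data["state"] = _annotate_many(union, state_map)
    else:
        data["state"] = ["none"] * len(union)
    table = pd.DataFrame(data)

    per_tf: dict[str, float] = {}
    for tf, ps in peaksets.items():
        if len(ps) == 0:
            per_tf[tf] = float("nan")
            continue
        others = {t: q for t, q in peaksets.items() if t != tf}
        cobound = np.zeros(len(ps), dtype=bool)
        for q in others.values():
            cobound |= ps.overlaps_any(q)
        per_tf[tf] = float(np.mean(cobound))
    return CobindingTable(table=table, regions=union,
                          per_tf_cobound_fraction=per_tf, context=context)


def compare_contexts(
    peaks_a: IntervalSet,
    peaks_b: IntervalSet,
    tf: str = "",
    context_a: str = "A",
    context_b: str = "B",
) -> ContextComparison:
    """Classify one TF's peaks as common or specific between two contexts.

    A peak is common when it overlaps (>= 1 bp) any peak of the other
    context; common regions are the merged union of all reciprocally
    overlapping peaks from both sides, so a common binding event is counted
    once. Symmetric: swapping contexts swaps the specific counts and leaves
    the common count unchanged.
    """
    a_common = peaks_a.overlaps_any(peaks_b)
    b_common = peaks_b.overlaps_any(peaks_a)
    common_pool = [peaks_a[i] for i in np.nonzero(a_common)[0]]
    common_pool += [peaks_b[i] for i in np.nonzero(b_common)[0]]
    common_merged = IntervalSet(common_pool).merge(0)
    return ContextComparison(
        tf=tf,
        context_a=context_a,
        context_b=context_b,
        specific_a=int(np.sum(~a_common)),
        specific_b=int(np.sum(~b_common)),
        common_regions=len(common_merged),
        common_peaks_a=int(np.sum(a_common)),
        common_peaks_b=int(np.sum(b_common)),
        specific_a_peaks=IntervalSet(
            [peaks_a[i] for i in np.nonzero(~a_common)[0]],
            label=f"{tf}_{context_a}_specific",
        ),
        specific_b_peaks=IntervalSet(
            [peaks_b[i] for i in np.nonzero(~b_common)[0]],
            label=f"{tf}_{context_b}_specific",
        ),
        common_merged=common_merged.with_label(f"{tf}_common"),
    )


def _merged_arrays(peaks: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) of the merged peak footprint."""
    merged = peaks.merge(0)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        out.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in merged:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, rows in by.items():
        arr = np.asarray(rows, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def _overlap_flags_vs_merged(
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    merged_by_chrom: Sequence[Optional[tuple[np.ndarray, np.ndarray]]],
) -> np.ndarray:
    """Vectorized any-overlap of query intervals against merged,
    non-overlapping target intervals (per chromosome index)."""
    flags = np.zeros(len(starts), dtype=bool)
    for ci, merged in enumerate(merged_by_chrom):
        if merged is None:
            continue
        m_starts, m_ends = merged
        sel = chrom_idx == ci
        if not np.any(sel):
            continue
        q_start = starts[sel]
        q_end = ends[sel]
        # merged intervals are disjoint and sorted, so ends are sorted too
        idx = np.searchsorted(m_starts, q_end, side="left")
        hit = (idx > 0) & (m_ends[np.maximum(idx - 1, 0)] > q_start)
        flags[sel] = hit
    return flags


def enhancer_binding_permutation(
    enhancers: IntervalSet,
    peaksets: Mapping[str, IntervalSet],
    genome: GenomeLayout,
    n_permutations: int = 9_999,
    seed: int = 0,
) -> tuple[PermutationResult, pd.DataFrame]:
    """Permutation test for TF binding enrichment at enhancers.

    Observed statistic: fraction of enhancers overlapping at least one TF
    peak (any factor). Null: each enhancer is relocated uniformly at random
    within its own chromosome, length preserved, placements independent.
    Also returns the bound-by-k distribution (k = 0..n_tfs): the fraction of
    enhancers overlapped by peaks of exactly k distinct TFs.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(enhancers) == 0:
        raise ValueError("no enhancers supplied")
    chrom_names = list(genome.chrom_names)
    chrom_pos = {c: i for i, c in enumerate(chrom_names)}
    e_chrom = np.array([chrom_pos[iv.chrom] for iv in enhancers], dtype=np.int64)
    e_start = np.array([iv.start for iv in enhancers], dtype=np.int64)
    e_len = np.array([len(iv) for iv in enhancers], dtype=np.int64)
    chrom_lens = np.array([genome.length_of(c) for c in chrom_names],
                          dtype=np.int64)
    max_start = chrom_lens[e_chrom] - e_len
    if np.any(max_start < 0):
        raise ValueError("enhancer longer than its chromosome")

    pooled = IntervalSet([iv for ps in peaksets.values() for iv in ps])
    merged_union = _merged_arrays(pooled) if len(pooled) else {}
    union_by_chrom = [merged_union.get(c) for c in chrom_names]

    observed_flags = _overlap_flags_vs_merged(
        e_chrom, e_start, e_start + e_len, union_by_chrom
    )
    observed = float(np.mean(observed_flags))

    # bound-by-k distribution on the observed enhancers
    k_counts = np.zeros(len(enhancers), dtype=np.int64)
    for tf, ps in peaksets.items():
        m = _merged_arrays(ps) if len(ps) else {}
        by = [m.get(c) for c in chrom_names]
        k_counts += _overlap_flags_vs_merged(
            e_chrom, e_start, e_start + e_len, by
        ).astype(np.int64)
    n_tfs = len(peaksets)
    k_frac = pd.DataFrame(
        {
            "k": np.arange(n_tfs + 1),
            "n_enhancers": [int(np.sum(k_counts == k)) for k in range(n_tfs + 1)],
        }
    )
    k_frac["fraction"] = k_frac["n_enhancers"] / len(enhancers)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=float)
    for p in range(n_permutations):
        new_start = rng.integers(0, max_start + 1)
        flags = _overlap_flags_vs_merged(
            e_chrom, new_start, new_start + e_len, union_by_chrom
        )
        null[p] = float(np.mean(flags))
    result = PermutationResult(
        observed_statistic=observed,
        null_draws=null,
        n_permutations=n_permutations,
        seed=seed,
        metadata={
            "null": "uniform length-preserving relocation within chromosome, "
                    "independent placements; one-sided enrichment",
            "rng": "numpy PCG64 (default_rng)",
        },
    )
    return result, k_frac


def signal_matrix(
    track: SignalTrack,
    centers: IntervalSet,
    window: int,
    bin_size: int,
    library_size: float = 1e6,
    genome: Optional[GenomeLayout] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region binned signal profile, CPM-scaled.

    Rows follow the order of ``centers`` (midpoint-anchored windows of
    ``window`` bp split into ``window / bin_size`` bins); each cell is the
    mean track value in the bin times 1e6 / library_size. Windows running off
    a chromosome edge are zero-padded and flagged in the returned boolean
    vector.
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin size")
    n_bins = window // bin_size
    scale = 1e6 / library_size
    mat = np.zeros((len(centers), n_bins), dtype=float)
    clipped = np.zeros(len(centers), dtype=bool)
    for i, iv in enumerate(centers):
        mid = iv.midpoint()
        left = mid - window // 2
        chrom_len = genome.length_of(iv.chrom) if genome is not None else None
        for b in range(n_bins):
            a = left + b * bin_size
            z = a + bin_size
            if a < 0 or (chrom_len is not None and z > chrom_len):
                clipped[i] = True
                lo = max(a, 0)
                hi = min(z, chrom_len) if chrom_len is not None else z
                if hi <= lo:
                    continue
                mat[i, b] = track.mean_over(iv.chrom, lo, hi) * (hi - lo) / bin_size
            else:
                mat[i, b] = track.mean_over(iv.chrom, a, z)
    mat *= scale
    return mat, clipped
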