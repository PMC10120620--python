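"""Super-enhancer calling and chromatin-state maps.

Enhancer peaks (H3K27ac) are stitched into regions when they fall within a
stitch distance of each other (12,500 bp by default, the classic choice),
optionally excluding peaks that sit wholly inside a TSS window. Stitched
regions are ranked by total constituent signal and split into "super" and
"typical" classes at the hockey-stick cutpoint: with both the rank axis and
the signal axis rescaled to [0, 1], the cutpoint is the first rank position
at which the slope of the ascending rank-vs-signal curve exceeds 1 (the point
where a 45-degree tangent touches the curve). The identical stitch-and-cut
procedure applied to H3K27me3 peak signal yields "super-methylated" and
"typical methylated" regions; that construction is an analytic choice of this
package and is flagged as such in output metadata.

A :class:`ChromatinStateMap` bundles the five annotation classes for one
cellular context (e.g. FTSEC or HGSC): promoters, typical enhancers,
super-enhancers, typical-methylated, super-methylated. Classes are stored
unmodified; precedence between them is applied only when a query region is
annotated (see :mod:`tfrewire.cobinding`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genes import promoters_of
from .intervals import GenomicInterval, IntervalSet
from .tads import TadMap

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION = 2_500
DEFAULT_PROMOTER_WINDOW = 2_000

__all__ = [
    "StitchedRegion",
    "ChromatinStateMap",
    "stitch",
    "call_super",
    "build_state_map",
    "assign_regions_to_genes",
    "loop_anchor_overlap",
]


@dataclass
class StitchedRegion:
    """A stitched enhancer region with its constituent peaks."""

    interval: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    total_signal: float
    rank: int = 0          # 1 = highest total signal
    is_super: bool = False

    def __post_init__(self) -> None:
        for c in self.constituents:
            if (c.chrom != self.interval.chrom
                    or c.start < self.interval.start
                    or c.end > self.interval.end):
                raise ValueError("constituent outside stitched region")


@dataclass
class ChromatinStateMap:
    """Five chromatin annotation classes for one cellular context."""

    promoters: IntervalSet
    typical_enhancers: IntervalSet
    super_enhancers: IntervalSet
    typical_methylated: IntervalSet
    super_methylated: IntervalSet
    context: str = ""
    metadata: dict = field(default_factory=dict)

    def classes(self) -> dict[str, IntervalSet]:
        return {
            "promoter": self.promoters,
            "super_enhancer": self.super_enhancers,
            "typical_enhancer": self.typical_enhancers,
            "super_methylated": self.super_methylated,
            "typical_methylated": self.typical_methylated,
        }


def stitch(
    peaks: IntervalSet,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: Optional[tuple[pd.DataFrame, int]] = None,
) -> list[StitchedRegion]:
    """Stitch signal peaks into regions.

    Peaks separated by at most ``stitch_distance`` bases are fused into one
    region whose total signal is the sum of its constituents' signals. When
    ``tss_exclusion=(gene_models, window)`` is given, peaks lying WHOLLY
    inside a TSS +/- window promoter interval are dropped before stitching
    (the ROSE convention, so promoter signal does not nucleate
    super-enhancers). Constituents of the output partition the surviving
    input peaks exactly.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    kept = list(peaks)
    if tss_exclusion is not None:
        genes, window = tss_exclusion
        tss_windows = promoters_of(genes, window)
        survivors = []
        kept_set = IntervalSet(kept)
        contained = np.zeros(len(kept_set), dtype=bool)
        for i, j in kept_set.overlap_pair_indices(tss_windows):
            p, w = kept_set[i], tss_windows[j]
            if w.start <= p.start and p.end <= w.end:
                contained[i] = True
        survivors = [kept_set[i] for i in range(len(kept_set)) if not contained[i]]
        kept = survivors
    kept.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    regions: list[StitchedRegion] = []
    group: list[GenomicInterval] = []

    def _flush() -> None:
        if not group:
            return
        chrom = group[0].chrom
        start = min(p.start for p in group)
        end = max(p.end for p in group)
        total = float(sum(p.signal or 0.0 for p in group))
        regions.append(
            StitchedRegion(
                GenomicInterval(chrom, start, end, signal=total),
                tuple(group), total,
            )
        )

    cur_end: Optional[int] = None
    for p in kept:
        if group and p.chrom == group[0].chrom and p.start - cur_end <= stitch_distance:
            group.append(p)
            cur_end = max(cur_end, p.end)
        else:
            _flush()
            group = [p]
            cur_end = p.end
        cur_end = max(cur_end, p.end)
    _flush()
    return regions


def super_cutpoint_index(signals: Sequence[float]) -> int:
    """Index (into the ascending-sorted signal vector) of the hockey-stick
    cutpoint: regions at positions strictly greater than the returned index
    are super.

    Both axes are min-max rescaled to [0, 1]; the cutpoint is the lower
    endpoint of the first rank segment whose forward-difference slope exceeds
    1. The strict inequality breaks ties toward fewer supers: an exactly
    linear rescaled curve (slope identically 1) yields no supers, signalled
    by returning ``len(signals) - 1``.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 2:
        return n - 1
    span = s[-1] - s[0]
    if span == 0:
        return n - 1
    y = (s - s[0]) / span
    x = np.arange(n, dtype=float) / (n - 1)
    slopes = np.diff(y) / np.diff(x)
    above = np.nonzero(slopes > 1.0)[0]
    if len(above) == 0:
        return n - 1
    return int(above[0])


def call_super(regions: Sequence[StitchedRegion]) -> list[StitchedRegion]:
    """Rank stitched regions by total signal and flag super-enhancers.

    Returns the same regions with ``rank`` (1 = highest signal; ties broken
    by genomic position for determinism) and ``is_super`` set. Scale
    invariant: multiplying every signal by a positive constant leaves the
    flags unchanged. All-zero signal yields zero supers with a warning.
    """
    regions = list(regions)
    if len(regions) < 2:
        raise ValueError("need >= 2 stitched regions to call supers")
    signals = np.array([r.total_signal for r in regions], dtype=float)
    if np.all(signals == 0):
        warnings.warn("all stitched regions have zero signal; no supers called")
    # descending rank with positional tie-break
    order = sorted(
        range(len(regions)),
        key=lambda i: (-signals[i], regions[i].interval.chrom,
                       regions[i].interval.start),
    )
    for rank, i in enumerate(order, start=1):
        regions[i].rank = rank
    cut = super_cutpoint_index(signals)
    n = len(regions)
    n_super = n - 1 - cut
    for r in regions:
        r.is_super = r.rank <= n_super
    return regions


def build_state_map(
    h3k27ac: IntervalSet,
    h3k27me3: IntervalSet,
    genes: pd.DataFrame,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion_window: int = DEFAULT_TSS_EXCLUSION,
    context: str = "",
) -> ChromatinStateMap:
    """Build the five-class chromatin-state map for one context.

    Promoters are TSS +/- ``promoter_window``. H3K27ac peaks are stitched
    (with TSS exclusion) and split into super/typical enhancers at the
    hockey-stick cutpoint; H3K27me3 peaks get the identical treatment to
    yield super/typical methylated classes. Each class is merged internally;
    overlaps BETWEEN classes are left intact and resolved by precedence at
    annotation time.
    """
    if genes is None or len(genes) == 0:
        raise ValueError("gene models are required to build a state map")

    def _split(peaks: IntervalSet) -> tuple[IntervalSet, IntervalSet]:
        if len(peaks) == 0:
            return IntervalSet(), IntervalSet()
        regions = stitch(peaks, stitch_distance,
                         tss_exclusion=(genes, tss_exclusion_window))
        if len(regions) < 2:
            typ = IntervalSet([r.interval for r in regions]).merge(0)
            return typ, IntervalSet()
        regions = call_super(regions)
        sup = IntervalSet([r.interval for r in regions if r.is_super]).merge(0)
        typ = IntervalSet([r.interval for r in regions if not r.is_super]).merge(0)
        return typ, sup

    typ_enh, sup_enh = _split(h3k27ac)
    typ_me, sup_me = _split(h3k27me3)
    return ChromatinStateMap(
        promoters=promoters_of(genes, promoter_window).merge(0),
        typical_enhancers=typ_enh.with_label("typical_enhancer"),
        super_enhancers=sup_enh.with_label("super_enhancer"),
        typical_methylated=typ_me.with_label("typical_methylated"),
        super_methylated=sup_me.with_label("super_methylated"),
        context=context,
        metadata={
            "promoter_window": promoter_window,
            "stitch_distance": stitch_distance,
            "tss_exclusion_window": tss_exclusion_window,
            "super_methylated_construction":
                "stitch+hockey-stick applied to H3K27me3 signal "
                "(analytic choice; upstream literature names the class "
                "without defining its construction)",
        },
    )


def assign_regions_to_genes(
    regions: Sequence[StitchedRegion],
    genes: pd.DataFrame,
    tads: TadMap,
) -> pd.DataFrame:
    """Assign stitched regions to genes, TAD-aware.

    A region is assigned to every gene whose TSS lies in the same TAD as the
    region's midpoint. Regions whose midpoint falls outside any TAD (or
    inside a TAD containing no TSS) fall back to the nearest TSS on the same
    chromosome. Returns a DataFrame (region_index, gene_id, mechanism) where
    mechanism is ``tad`` or ``nearest``.
    """
    gene_tad = np.array(
        [
            -1 if (idx := tads.tad_index_of(row.chrom, int(row.tss))) is None
            else idx
            for row in genes.itertuples(index=False)
        ],
        dtype=np.int64,
    )
    rows: list[tuple[int, str, str]] = []
    for ri, region in enumerate(regions):
        mid = region.interval.midpoint()
        chrom = region.interval.chrom
        tad_idx = tads.tad_index_of(chrom, mid)
        assigned = False
        if tad_idx is not None:
            for gi in np.nonzero(gene_tad == tad_idx)[0]:
                if genes.iloc[gi]["chrom"] == chrom:
                    rows.append((ri, str(genes.iloc[gi]["gene_id"]), "tad"))
                    assigned = True
        if not assigned:
            same = genes[genes["chrom"] == chrom]
            if len(same):
                dist = (same["tss"].to_numpy(dtype=np.int64) - mid)
                gi = int(np.argmin(np.abs(dist)))
                rows.append((ri, str(same.iloc[gi]["gene_id"]), "nearest"))
    return pd.DataFrame(rows, columns=["region_index", "gene_id", "mechanism"])


def loop_anchor_overlap(
    loops: Sequence[tuple[GenomicInterval, GenomicInterval]],
    regions: Sequence[StitchedRegion],
    slop: int = 0,
) -> tuple[np.ndarray, float]:
    """Count Hi-C loops anchored at each stitched region's constituents.

    A loop is anchored at a region when either of its anchors, widened by
    ``slop`` bp on each side, overlaps (>= 1 bp) any constituent peak of the
    region. Returns per-region anchored-loop counts and the fraction of
    super-enhancer regions with at least one anchored loop (fraction over all
    regions when none is flagged super).
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    counts = np.zeros(len(regions), dtype=np.int64)
    consts = []
    for ri, region in enumerate(regions):
        for c in region.constituents:
            consts.append((ri, c))
    const_set = IntervalSet([c for _, c in consts])
    owner = [consts[i][0] for i in range(len(consts))]
    # IntervalSet sorts; rebuild owner map against sorted order
    sorted_consts = sorted(
        range(len(consts)),
        key=lambda i: (consts[i][1].chrom, consts[i][1].start, consts[i][1].end),
    )
    owner = [consts[i][0] for i in sorted_consts]

    for a, b in loops:
        hit_regions: set[int] = set()
        for anchor in (a, b):
            start = max(0, anchor.start - slop)
            q = IntervalSet([GenomicInterval(anchor.chrom, start,
                                             anchor.end + slop)])
            for _, j in q.overlap_pair_indices(const_set):
                hit_regions.add(owner[j])
        for ri in hit_regions:
            counts[ri] += 1
    supers = [i for i, r in enumerate(regions) if r.is_super]
    pool = supers if supers else list(range(len(regions)))
    frac = float(np.mean([counts[i] > 0 for i in pool])) if pool else 0.0
    return counts, frac
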