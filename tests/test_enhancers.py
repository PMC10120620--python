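"""Stitching, hockey-stick super-enhancer calling, chromatin-state maps,
TAD-aware region-gene assignment, and loop anchoring."""

import numpy as np
import pandas as pd
import pytest

from tfrewire.enhancers import (
    assign_regions_to_genes,
    build_state_map,
    call_super,
    loop_anchor_overlap,
    stitch,
    super_cutpoint_index,
)
from tfrewire.intervals import GenomicInterval, IntervalSet
from tfrewire.simulate import CONTEXTS
from tfrewire.tads import TadMap

from conftest import random_interval_set


def _peaks(spec):
    return IntervalSet(
        [GenomicInterval("chr1", a, b, signal=s) for a, b, s in spec]
    )


def brute_cutpoint(signals):
    """Exhaustive tangent search: smallest ascending index whose rescaled
    forward slope exceeds 1 (45-degree tangent); n-1 when none does."""
    s = sorted(signals)
    n = len(s)
    span = s[-1] - s[0]
    if n < 2 or span == 0:
        return n - 1
    for i in range(n - 1):
        slope = ((s[i + 1] - s[i]) / span) * (n - 1)
        if slope > 1.0:
            return i
    return n - 1


class TestStitch:
    def test_two_peaks_within_distance_form_one_region(self):
        regions = stitch(_peaks([(0, 1000, 1.0), (5000, 6000, 2.0)]),
                         stitch_distance=12_500)
        assert len(regions) == 1
        assert len(regions[0].constituents) == 2
        assert regions[0].total_signal == pytest.approx(3.0)
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 6000)

    def test_distance_zero_keeps_merged_peaks(self):
        regions = stitch(_peaks([(0, 1000, 1.0), (5000, 6000, 2.0)]),
                         stitch_distance=0)
        assert len(regions) == 2

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            stitch(_peaks([(0, 10, 1.0)]), stitch_distance=-1)

    def test_tss_exclusion_drops_contained_peaks_only(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "strand": ["+"],
             "tss": [10_000], "length": [1000]}
        )
        peaks = _peaks([(9_000, 9_500, 1.0),      # wholly inside TSS window
                        (11_800, 12_700, 2.0),    # straddles the edge: kept
                        (50_000, 50_500, 3.0)])
        regions = stitch(peaks, 500, tss_exclusion=(genes, 2_500))
        consts = [c for r in regions for c in r.constituents]
        assert {(c.start, c.end) for c in consts} == {(11_800, 12_700),
                                                      (50_000, 50_500)}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_constituents_partition_input(self, small_layout, seed):
        rng = np.random.default_rng(seed)
        peaks = random_interval_set(rng, 150, small_layout, with_signal=True)
        distance = int(rng.integers(0, 3000))
        regions = stitch(peaks, distance)
        consts = sorted(
            (c.chrom, c.start, c.end)
            for r in regions for c in r.constituents
        )
        assert consts == sorted((p.chrom, p.start, p.end) for p in peaks)
        for r in regions:
            assert r.total_signal == pytest.approx(
                sum(c.signal for c in r.constituents)
            )


class TestCallSuper:
    def _regions(self, signals):
        return stitch(
            _peaks([(i * 10_000, i * 10_000 + 100, s)
                    for i, s in enumerate(signals)]),
            stitch_distance=0,
        )

    def test_single_outlier_is_the_only_super(self):
        regions = call_super(self._regions([1, 1, 1, 1, 100]))
        supers = [r.total_signal for r in regions if r.is_super]
        assert supers == [100]

    def test_perfectly_linear_signals_yield_zero_supers(self):
        regions = call_super(self._regions(list(range(1, 21))))
        assert not any(r.is_super for r in regions)

    def test_all_zero_signals_warn_and_yield_zero_supers(self):
        with pytest.warns(UserWarning):
            regions = call_super(self._regions([0, 0, 0]))
        assert not any(r.is_super for r in regions)

    @pytest.mark.parametrize("seed", list(range(10)))
    def test_cutpoint_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        signals = np.exp(rng.normal(0, 1, size=n))
        signals[rng.random(n) < 0.1] *= 50  # hockey-stick upper arm
        assert super_cutpoint_index(signals) == brute_cutpoint(signals)

    @pytest.mark.parametrize("mult", [0.01, 3.7, 1e6])
    def test_scale_invariance(self, mult):
        rng = np.random.default_rng(42)
        signals = np.exp(rng.normal(0, 1, size=80))
        signals[:8] *= 100
        base = call_super(self._regions(list(signals)))
        scaled = call_super(self._regions(list(signals * mult)))
        assert [r.is_super for r in base] == [r.is_super for r in scaled]

    def test_raising_a_supers_signal_never_demotes_it(self):
        rng = np.random.default_rng(11)
        signals = list(np.exp(rng.normal(0, 0.5, size=50))) + [60.0, 80.0]
        regions = call_super(self._regions(signals))
        super_idx = [i for i, r in enumerate(regions) if r.is_super]
        for i in super_idx:
            bumped = list(signals)
            bumped[i] *= 5
            again = call_super(self._regions(bumped))
            assert again[i].is_super

    def test_planted_super_count_recovered(self, default_dataset):
        ds = default_dataset
        for ctx in CONTEXTS:
            regions = call_super(
                stitch(ds.h3k27ac[ctx], 2_000,
                       tss_exclusion=(ds.genes, 2_500))
            )
            called = IntervalSet([r.interval for r in regions if r.is_super])
            planted = ds.truth.planted_superenhancers[ctx]
            assert len(called) == len(planted)
            assert planted.overlaps_any(called).all()


class TestStateMap:
    def _genes(self):
        return pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "strand": ["+"],
             "tss": [10_000], "length": [1000]}
        )

    def test_promoter_window_arithmetic(self):
        sm = build_state_map(
            _peaks([(50_000, 50_500, 1.0), (70_000, 70_500, 5.0)]),
            IntervalSet([]), self._genes(), promoter_window=2_000,
        )
        assert [(iv.start, iv.end) for iv in sm.promoters] == [(8_000, 12_000)]

    def test_no_methylation_peaks_give_empty_classes(self):
        sm = build_state_map(
            _peaks([(50_000, 50_500, 1.0), (70_000, 70_500, 5.0)]),
            IntervalSet([]), self._genes(),
        )
        assert len(sm.typical_methylated) == 0
        assert len(sm.super_methylated) == 0

    def test_missing_gene_models_rejected(self):
        with pytest.raises(ValueError):
            build_state_map(_peaks([(0, 10, 1.0)]), IntervalSet([]),
                            pd.DataFrame())

    def test_planted_state_assignments(self, default_dataset):
        from tfrewire.cobinding import annotate_state

        ds = default_dataset
        for ctx in CONTEXTS:
            sm = build_state_map(
                ds.h3k27ac[ctx], ds.h3k27me3[ctx], ds.genes,
                stitch_distance=2_000, context=ctx,
            )
            for se in ds.truth.planted_superenhancers[ctx]:
                assert annotate_state(se, sm) == "super_enhancer"
            for sme in ds.truth.planted_supermethylated[ctx]:
                assert annotate_state(sme, sm) == "super_methylated"


class TestAssignRegionsToGenes:
    def _setup(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
             "strand": ["+", "+"], "tss": [5_000, 60_000],
             "length": [1000, 1000]}
        )
        tads = TadMap([GenomicInterval("chr1", 0, 20_000),
                       GenomicInterval("chr1", 50_000, 90_000)])
        return genes, tads

    def test_same_tad_assignment(self):
        genes, tads = self._setup()
        regions = stitch(_peaks([(8_000, 8_500, 1.0)]), 0)
        table = assign_regions_to_genes(regions, genes, tads)
        assert table.iloc[0]["gene_id"] == "g1"
        assert table.iloc[0]["mechanism"] == "tad"

    def test_region_outside_tads_falls_back_to_nearest_tss(self):
        genes, tads = self._setup()
        regions = stitch(_peaks([(30_000, 30_500, 1.0)]), 0)  # in TAD gap
        table = assign_regions_to_genes(regions, genes, tads)
        assert list(table["mechanism"]) == ["nearest"]
        assert table.iloc[0]["gene_id"] == "g1"  # 22 kb vs 29.5 kb away

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_scan(self, small_layout, seed):
        rng = np.random.default_rng(seed)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(30)],
            "chrom": rng.choice(small_layout.chrom_names, size=30),
            "strand": ["+"] * 30,
            "tss": rng.integers(0, 70_000, size=30),
            "length": [1000] * 30,
        })
        tad_ivs = []
        for chrom in small_layout.chrom_names:
            bounds = np.sort(rng.choice(
                np.arange(0, small_layout.length_of(chrom), 1000), 5,
                replace=False,
            ))
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b - a > 2000:
                    tad_ivs.append(GenomicInterval(chrom, int(a), int(b)))
        tads = TadMap(tad_ivs)
        peaks = random_interval_set(rng, 40, small_layout, with_signal=True)
        regions = stitch(peaks, 1000)
        table = assign_regions_to_genes(regions, genes, tads)
        got = set(map(tuple, table[["region_index", "gene_id"]].values))

        expected = set()
        for ri, region in enumerate(regions):
            mid = region.interval.midpoint()
            t = tads.containing(region.interval.chrom, mid)
            hits = []
            if t is not None:
                for g in genes.itertuples(index=False):
                    gt = tads.containing(g.chrom, int(g.tss))
                    if gt is not None and gt == t and g.chrom == region.interval.chrom:
                        hits.append(g.gene_id)
            if not hits:
                same = genes[genes["chrom"] == region.interval.chrom]
                if len(same):
                    d = (same["tss"] - mid).abs()
                    hits = [same.loc[d.idxmin(), "gene_id"]]
            expected |= {(ri, g) for g in hits}
        assert got == expected


class TestLoopAnchorOverlap:
    def test_anchor_inside_constituent_counts(self):
        regions = call_super(
            stitch(_peaks([(0, 1000, 1.0), (20_000, 21_000, 50.0),
                           (40_000, 41_000, 1.0)]), 0)
        )
        loops = [(GenomicInterval("chr1", 20_100, 20_200),
                  GenomicInterval("chr1", 90_000, 90_100))]
        counts, frac = loop_anchor_overlap(loops, regions, slop=0)
        assert counts.sum() == 1
        assert frac == 1.0  # the single super-enhancer is anchored

    def test_zero_loops(self):
        regions = stitch(_peaks([(0, 1000, 1.0), (30_000, 31_000, 2.0)]), 0)
        counts, frac = loop_anchor_overlap([], regions)
        assert counts.sum() == 0 and frac == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_counts_match_all_pairs_scan(self, small_layout, seed):
        rng = np.random.default_rng(seed)
        peaks = random_interval_set(rng, 60, small_layout, with_signal=True)
        regions = stitch(peaks, 2_000)
        loops = []
        for _ in range(40):
            a = random_interval_set(rng, 1, small_layout)[0]
            b = random_interval_set(rng, 1, small_layout)[0]
            loops.append((a, b))
        slop = int(rng.integers(0, 500))
        counts, _ = loop_anchor_overlap(loops, regions, slop=slop)
        for ri, region in enumerate(regions):
            expected = 0
            for a, b in loops:
                hit = False
                for anchor in (a, b):
                    widened = GenomicInterval(
                        anchor.chrom, max(0, anchor.start - slop),
                        anchor.end + slop,
                    )
                    for c in region.constituents:
                        if widened.overlap_bp(c) >= 1:
                            hit = True
                if hit:
                    expected += 1
            assert counts[ri] == expected
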