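"""Co-binding tables, state annotation precedence, context comparison,
the permutation enrichment test, and signal-profile matrices."""

import numpy as np
import pandas as pd
import pytest

from tfrewire.cobinding import (
    TFS,
    annotate_state,
    compare_contexts,
    count_cobinding,
    enhancer_binding_permutation,
    signal_matrix,
)
from tfrewire.enhancers import ChromatinStateMap
from tfrewire.intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
)

from conftest import random_interval_set


def _one(chrom, start, end):
    return IntervalSet([GenomicInterval(chrom, start, end)])


def _state_map(small_layout, rng=None):
    if rng is None:
        return ChromatinStateMap(
            promoters=IntervalSet([]), typical_enhancers=IntervalSet([]),
            super_enhancers=IntervalSet([]),
            typical_methylated=IntervalSet([]),
            super_methylated=IntervalSet([]),
        )
    return ChromatinStateMap(
        promoters=random_interval_set(rng, 20, small_layout),
        typical_enhancers=random_interval_set(rng, 20, small_layout),
        super_enhancers=random_interval_set(rng, 20, small_layout),
        typical_methylated=random_interval_set(rng, 20, small_layout),
        super_methylated=random_interval_set(rng, 20, small_layout),
    )


class TestCountCobinding:
    def test_identical_single_peak_sets_share_one_region(self):
        sets = {tf: _one("chr1", 100, 200) for tf in TFS}
        table = count_cobinding(sets)
        assert len(table.regions) == 1
        assert table.table["n_tfs_bound"].tolist() == [4]
        assert all(v == 1.0 for v in table.per_tf_cobound_fraction.values())

    def test_disjoint_peaks_stay_separate(self):
        sets = {tf: _one("chr1", 1000 * i, 1000 * i + 100)
                for i, tf in enumerate(TFS)}
        table = count_cobinding(sets)
        assert len(table.regions) == 4
        assert table.table["n_tfs_bound"].tolist() == [1, 1, 1, 1]
        assert all(v == 0.0 for v in table.per_tf_cobound_fraction.values())

    def test_all_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            count_cobinding({tf: IntervalSet([]) for tf in TFS})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_membership_matches_brute_force(self, small_layout, seed):
        rng = np.random.default_rng(seed)
        sets = {tf: random_interval_set(rng, 200, small_layout)
                for tf in TFS}
        table = count_cobinding(sets)
        for _, row in table.table.iterrows():
            region = GenomicInterval(row["chrom"], row["start"], row["end"])
            for tf in TFS:
                expected = any(region.overlap_bp(p) >= 1 for p in sets[tf])
                assert bool(row[tf]) == expected
        # partition invariant
        counts = table.n_bound_counts()
        assert counts.sum() == len(table.regions)
        assert counts.index.tolist() == [0, 1, 2, 3, 4]

    def test_per_tf_cobound_fraction_matches_brute_force(self, small_layout):
        rng = np.random.default_rng(5)
        sets = {tf: random_interval_set(rng, 80, small_layout) for tf in TFS}
        table = count_cobinding(sets)
        for tf in TFS:
            n = 0
            for p in sets[tf]:
                others = (q for t in TFS if t != tf for q in sets[t])
                if any(p.overlap_bp(q) >= 1 for q in others):
                    n += 1
            assert table.per_tf_cobound_fraction[tf] == pytest.approx(
                n / len(sets[tf])
            )


class TestAnnotateState:
    def test_promoter_beats_super_enhancer(self, small_layout):
        sm = ChromatinStateMap(
            promoters=_one("chr1", 0, 1000),
            typical_enhancers=IntervalSet([]),
            super_enhancers=_one("chr1", 500, 2000),
            typical_methylated=IntervalSet([]),
            super_methylated=IntervalSet([]),
        )
        assert annotate_state(GenomicInterval("chr1", 600, 900), sm) == \
            "promoter"

    def test_nothing_overlapping_is_none(self, small_layout):
        sm = _state_map(small_layout)
        assert annotate_state(GenomicInterval("chr1", 0, 10), sm) == "none"

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_nested_if_brute_force(self, small_layout, seed):
        rng = np.random.default_rng(seed)
        sm = _state_map(small_layout, rng)
        classes = sm.classes()
        for _ in range(100):
            region = random_interval_set(rng, 1, small_layout)[0]
            got = annotate_state(region, sm)
            expected = "none"
            for label in ("promoter", "super_enhancer", "typical_enhancer",
                          "super_methylated", "typical_methylated"):
                if any(region.overlap_bp(iv) >= 1 for iv in classes[label]):
                    expected = label
                    break
            assert got == expected


class TestCompareContexts:
    def test_identical_sets_all_common(self, small_layout):
        rng = np.random.default_rng(1)
        a = random_interval_set(rng, 50, small_layout)
        comp = compare_contexts(a, a)
        assert comp.fraction_common == 1.0
        assert comp.specific_a == comp.specific_b == 0

    def test_disjoint_sets_no_common(self):
        a = _one("chr1", 0, 100)
        b = _one("chr1", 500, 600)
        comp = compare_contexts(a, b)
        assert comp.fraction_common == 0.0
        assert comp.common_regions == 0

    def test_symmetry_under_swap(self, small_layout):
        rng = np.random.default_rng(2)
        a = random_interval_set(rng, 120, small_layout)
        b = random_interval_set(rng, 80, small_layout)
        fwd = compare_contexts(a, b)
        rev = compare_contexts(b, a)
        assert fwd.specific_a == rev.specific_b
        assert fwd.specific_b == rev.specific_a
        assert fwd.common_regions == rev.common_regions

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_classification_matches_brute_force(self, small_layout, seed):
        rng = np.random.default_rng(seed)
        a = random_interval_set(rng, 100, small_layout)
        b = random_interval_set(rng, 100, small_layout)
        comp = compare_contexts(a, b)
        a_common = [any(p.overlap_bp(q) >= 1 for q in b) for p in a]
        b_common = [any(q.overlap_bp(p) >= 1 for p in a) for q in b]
        assert comp.specific_a == a_common.count(False)
        assert comp.specific_b == b_common.count(False)
        assert comp.common_peaks_a == a_common.count(True)
        pool = [p for p, c in zip(a, a_common) if c] + \
               [q for q, c in zip(b, b_common) if c]
        assert comp.common_regions == len(IntervalSet(pool).merge(0))


class TestPermutation:
    def test_zero_tf_peaks_give_p_one(self, small_layout):
        enh = _one("chr1", 0, 500)
        result, k = enhancer_binding_permutation(
            enh, {tf: IntervalSet([]) for tf in TFS}, small_layout,
            n_permutations=99, seed=0,
        )
        assert result.observed_statistic == 0.0
        assert result.p_empirical == 1.0
        assert k.loc[k["k"] == 0, "fraction"].iloc[0] == 1.0

    def test_p_floor_and_determinism(self, small_layout):
        rng = np.random.default_rng(3)
        peaks = {tf: random_interval_set(rng, 40, small_layout)
                 for tf in TFS}
        enh = peaks["PAX8"]
        r1, _ = enhancer_binding_permutation(enh, peaks, small_layout,
                                             n_permutations=99, seed=5)
        r2, _ = enhancer_binding_permutation(enh, peaks, small_layout,
                                             n_permutations=99, seed=5)
        assert np.array_equal(r1.null_draws, r2.null_draws)
        assert r1.p_empirical >= 1 / 100
        assert r1.observed_statistic == 1.0

    def test_enhancer_longer_than_chromosome_rejected(self):
        layout = GenomeLayout.from_lengths({"chr2": 50})
        enh = IntervalSet([GenomicInterval("chr2", 0, 100)])
        peaks = {"PAX8": IntervalSet([GenomicInterval("chr2", 0, 10)])}
        with pytest.raises(ValueError):
            enhancer_binding_permutation(enh, peaks, layout,
                                         n_permutations=9, seed=0)

    def test_empirical_p_near_exact_enumeration(self):
        """1-chromosome, 1 kb genome with one enhancer: the chance a random
        placement overlaps the single peak is exactly enumerable."""
        layout = GenomeLayout.from_lengths({"chr1": 1000})
        peak = IntervalSet([GenomicInterval("chr1", 400, 500)])
        enh = IntervalSet([GenomicInterval("chr1", 420, 470)])  # length 50
        # placements 0..950; overlap iff start in [351, 499] -> 149 of 951
        exact = 149 / 951
        n = 4000
        result, _ = enhancer_binding_permutation(
            enh, {"PAX8": peak}, layout, n_permutations=n, seed=1,
        )
        hit_rate = float(np.mean(result.null_draws >= 1.0))
        sd = np.sqrt(exact * (1 - exact) / n)
        assert abs(hit_rate - exact) <= 3 * sd


class TestSignalMatrix:
    def _flat_track(self, value=2.0):
        return SignalTrack({
            "chr1": (np.array([0]), np.array([100_000]), np.array([value]))
        })

    def test_flat_track_fills_all_bins(self):
        centers = _one("chr1", 50_000, 50_001)
        mat, clipped = signal_matrix(self._flat_track(2.0), centers,
                                     window=3000, bin_size=100,
                                     library_size=1e6)
        assert mat.shape == (1, 30)
        assert np.allclose(mat, 2.0)
        assert not clipped.any()

    def test_delta_peak_hits_middle_bin_only(self):
        track = SignalTrack({
            "chr1": (np.array([50_000]), np.array([50_100]), np.array([5.0]))
        })
        centers = _one("chr1", 50_000, 50_001)
        mat, _ = signal_matrix(track, centers, window=3000, bin_size=100,
                               library_size=1e6)
        assert mat[0, 15] == pytest.approx(5.0)
        assert np.count_nonzero(mat) == 1

    def test_cpm_scaling(self):
        centers = _one("chr1", 50_000, 50_001)
        mat, _ = signal_matrix(self._flat_track(2.0), centers, window=1000,
                               bin_size=100, library_size=2e6)
        assert np.allclose(mat, 1.0)

    def test_window_off_edge_pads_zero_and_flags(self, small_layout):
        centers = _one("chr1", 0, 100)
        mat, clipped = signal_matrix(self._flat_track(1.0), centers,
                                     window=3000, bin_size=100,
                                     library_size=1e6, genome=small_layout)
        assert clipped[0]
        assert mat[0, 0] == 0.0       # fully off-chromosome bin
        assert mat[0, -1] == 1.0

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError):
            signal_matrix(self._flat_track(), _one("chr1", 0, 10), 1000, 300)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_per_bin_summation(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 99_000, 10), 300,
                                    replace=False))
        ends = starts + rng.integers(1, 10, size=300)
        vals = rng.uniform(0, 5, size=300)
        track = SignalTrack({"chr1": (starts, ends, vals)})
        centers = IntervalSet([
            GenomicInterval("chr1", int(p), int(p) + 1)
            for p in rng.integers(2_000, 95_000, size=25)
        ])
        window, bin_size = 2000, 50
        mat, _ = signal_matrix(track, centers, window, bin_size,
                               library_size=1e6)
        for i, iv in enumerate(centers):
            left = iv.midpoint() - window // 2
            for b in range(window // bin_size):
                a, z = left + b * bin_size, left + (b + 1) * bin_size
                acc = 0.0
                for s, e, v in zip(starts, ends, vals):
                    acc += max(0, min(e, z) - max(s, a)) * v
                assert mat[i, b] == pytest.approx(acc / bin_size)
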