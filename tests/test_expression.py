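"""TPM, spike-in-anchored cyclic loess, log2 fold-changes, and the
two-cell-line high-confidence threshold rule."""

import numpy as np
import pandas as pd
import pytest

from tfrewire.expression import (
    CountMatrix,
    call_high_confidence,
    loess_normalize,
    log2fc,
    tpm,
)


def _count_matrix(counts, lengths, is_spikein, conditions=None,
                  cell_line="L1", context="FTSEC"):
    genes = [f"g{i}" for i in range(len(lengths))]
    samples = list(counts.keys())
    cm = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    gene_meta = pd.DataFrame(
        {"length": lengths, "is_spikein": is_spikein},
        index=cm.index,
    )
    conditions = conditions or ["control_1"] * len(samples)
    sample_meta = pd.DataFrame(
        {"cell_line": cell_line, "context": context,
         "condition": conditions, "replicate": range(1, len(samples) + 1)},
        index=pd.Index(samples, name="sample_id"),
    )
    return CountMatrix(cm, gene_meta, sample_meta)


class TestTpm:
    def test_two_gene_arithmetic(self):
        cm = _count_matrix({"s1": [10, 90]}, [1000, 1000], [False, False])
        t = tpm(cm)
        assert t["s1"].tolist() == [100_000.0, 900_000.0]

    def test_single_gene_gets_everything(self):
        cm = _count_matrix({"s1": [7]}, [500], [False])
        assert tpm(cm)["s1"].iloc[0] == pytest.approx(1e6)

    def test_length_normalization(self):
        # same counts, 2x length -> half the rate -> 1/3 vs 2/3 of the mass
        cm = _count_matrix({"s1": [10, 10]}, [2000, 1000], [False, False])
        t = tpm(cm)["s1"]
        assert t.iloc[0] == pytest.approx(1e6 / 3)

    def test_all_zero_sample_warns_and_stays_zero(self):
        cm = _count_matrix({"s1": [0, 0]}, [1000, 1000], [False, False])
        with pytest.warns(UserWarning):
            t = tpm(cm)
        assert (t["s1"] == 0).all()

    def test_zero_length_rejected(self):
        cm = _count_matrix({"s1": [1, 1]}, [1000, 1000], [False, False])
        cm.gene_meta.loc["g0", "length"] = 0
        with pytest.raises(ValueError):
            tpm(cm)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_columns_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = {f"s{i}": rng.integers(0, 1000, size=50) for i in range(4)}
        counts["s0"][0] += 1  # ensure nonzero column
        cm = _count_matrix(counts, rng.integers(200, 5000, size=50),
                           [False] * 50)
        t = tpm(cm)
        assert np.allclose(t.sum(axis=0), 1e6, rtol=1e-9)


def _tpm_frame(rng, n_genes=150, n_spike=40, n_samples=4):
    vals = np.exp2(rng.uniform(5, 14, size=(n_genes + n_spike, 1)))
    mat = np.tile(vals, (1, n_samples))
    idx = [f"g{i}" for i in range(n_genes)] + [f"spike{i}" for i in range(n_spike)]
    frame = pd.DataFrame(mat, index=idx,
                         columns=[f"s{i}" for i in range(n_samples)])
    mask = np.array([False] * n_genes + [True] * n_spike)
    return frame, mask


class TestLoessNormalize:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(0)
        frame, mask = _tpm_frame(rng)
        out = loess_normalize(frame, spikein_mask=mask)
        assert np.allclose(out.to_numpy(), frame.to_numpy(), atol=1e-6)

    def test_gene_only_shift_is_preserved(self):
        """A 2x shift on genes with untouched spike-ins is biology: the
        anchor certifies it and normalization must keep it."""
        rng = np.random.default_rng(1)
        frame, mask = _tpm_frame(rng)
        shifted = frame.copy()
        shifted.loc[~mask, "s0"] *= 2.0
        out = loess_normalize(shifted, spikein_mask=mask)
        logm = np.log2(out.to_numpy() + 1)
        gene_m = np.median(logm[~mask, 0] - logm[~mask, 1])
        spike_m = np.median(logm[mask, 0] - logm[mask, 1])
        assert gene_m == pytest.approx(1.0, abs=0.05)
        assert abs(spike_m) < 0.05

    def test_global_distortion_including_spikeins_is_removed(self):
        rng = np.random.default_rng(2)
        frame, mask = _tpm_frame(rng)
        distorted = frame.copy()
        distorted["s0"] *= 2.0  # all rows: a depth artifact
        out = loess_normalize(distorted, spikein_mask=mask)
        logm = np.log2(out.to_numpy() + 1)
        m = logm[:, 0] - logm[:, 1]
        assert abs(np.median(m)) < 0.05

    def test_two_sample_swap_symmetry(self):
        rng = np.random.default_rng(3)
        frame, mask = _tpm_frame(rng, n_samples=2)
        frame["s0"] *= 1.7
        out = loess_normalize(frame, spikein_mask=mask)
        swapped = loess_normalize(frame[["s1", "s0"]], spikein_mask=mask)
        assert np.allclose(out["s0"], swapped["s0"], rtol=1e-6)
        assert np.allclose(out["s1"], swapped["s1"], rtol=1e-6)

    def test_too_few_spikeins_rejected(self):
        rng = np.random.default_rng(4)
        frame, mask = _tpm_frame(rng, n_spike=5)
        with pytest.raises(ValueError, match="spike-in"):
            loess_normalize(frame, spikein_mask=mask)

    def test_all_genes_anchor_mode(self):
        rng = np.random.default_rng(5)
        frame, _ = _tpm_frame(rng)
        distorted = frame.copy()
        distorted["s0"] *= 2.0
        out = loess_normalize(distorted, anchor="all_genes")
        logm = np.log2(out.to_numpy() + 1)
        assert abs(np.median(logm[:, 0] - logm[:, 1])) < 0.05


class TestLog2fc:
    def _norm(self, kd_factor):
        rng = np.random.default_rng(6)
        base = np.exp2(rng.uniform(6, 14, size=100))
        cols = {"c1": base, "c2": base, "k1": base * kd_factor,
                "k2": base * kd_factor}
        frame = pd.DataFrame(cols, index=[f"g{i}" for i in range(100)])
        meta = pd.DataFrame(
            {"cell_line": "L1", "context": "FTSEC",
             "condition": ["control_1", "control_2", "siPAX8", "siPAX8"],
             "replicate": [1, 1, 1, 2]},
            index=frame.columns,
        )
        return frame, meta

    def test_knockdown_equal_to_controls_gives_zero(self):
        frame, meta = self._norm(1.0)
        fc = log2fc(frame, meta, "siPAX8")
        assert np.allclose(fc["L1"], 0.0, atol=1e-12)

    def test_doubling_gives_one_up_to_pseudocount(self):
        frame, meta = self._norm(2.0)
        fc = log2fc(frame, meta, "siPAX8")
        assert np.allclose(fc["L1"], 1.0, atol=0.02)
        exact = np.log2(frame["k1"] + 1) - np.log2(frame["c1"] + 1)
        assert np.allclose(fc["L1"], exact, atol=1e-9)

    def test_missing_condition_rejected(self):
        frame, meta = self._norm(1.0)
        with pytest.raises(ValueError):
            log2fc(frame, meta, "siWT1")


class TestHighConfidenceRule:
    CONTEXT = {"L1": "FTSEC", "L2": "FTSEC"}

    def _table(self, rows):
        genes = [f"g{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=genes, columns=["L1", "L2"])

    def test_hand_enumerated_truth_table(self):
        """12 hand-built rows covering boundaries, discordance, and
        one-sided passes; expected flags enumerated by hand."""
        rows = [
            (-0.6, -0.7),   # both pass, down
            (0.6, 0.7),     # both pass, up
            (-0.5, -0.5),   # boundary: inclusive
            (0.5, 0.5),     # boundary: inclusive, up
            (-0.6, 0.6),    # discordant signs
            (0.6, -0.6),    # discordant signs
            (-0.49, -0.9),  # one line below threshold
            (-0.9, -0.49),  # other line below threshold
            (0.0, 0.0),     # null
            (0.49, 0.49),   # both just below
            (-3.0, -0.51),  # strong + weak pass
            (0.51, 2.0),    # weak + strong pass
        ]
        expected_flag = [True, True, True, True, False, False, False,
                         False, False, False, True, True]
        expected_dir = ["down", "up", "down", "up", None, None, None, None,
                        None, None, "down", "up"]
        deg = call_high_confidence(self._table(rows), self.CONTEXT, "PAX8")
        got = deg.per_context.set_index("gene_id")
        for i, (flag, direction) in enumerate(zip(expected_flag,
                                                  expected_dir)):
            row = got.loc[f"g{i}"]
            assert bool(row["high_confidence"]) == flag, f"row {i}"
            if flag:
                assert row["direction"] == direction, f"row {i}"

    def test_direction_from_mean_sign(self):
        deg = call_high_confidence(self._table([(-0.8, -0.9)]),
                                   self.CONTEXT, "WT1")
        row = deg.per_context.iloc[0]
        assert row["direction"] == "down"
        assert row["log2fc_mean"] == pytest.approx(-0.85)

    def test_single_cell_line_needs_override(self):
        table = pd.DataFrame({"L1": [-0.8]}, index=["g0"])
        with pytest.raises(ValueError):
            call_high_confidence(table, {"L1": "FTSEC"}, "PAX8")
        deg = call_high_confidence(table, {"L1": "FTSEC"}, "PAX8",
                                   allow_single_line=True)
        assert bool(deg.per_context.iloc[0]["high_confidence"])

    def test_threshold_parameter_respected(self):
        deg = call_high_confidence(self._table([(-0.4, -0.4)]),
                                   self.CONTEXT, "PAX8", threshold=0.3)
        assert bool(deg.per_context.iloc[0]["high_confidence"])


class TestPlantedRecovery:
    def test_noise_free_planted_effects_recovered(self, default_dataset):
        """At zero noise the spike-in pipeline returns the planted log2FC
        up to pseudocount-scale error (< 0.03 at the simulated depths)."""
        from tfrewire.simulate import CELL_LINES
        from tfrewire.cobinding import TFS

        ds = default_dataset
        norm = {
            line: (loess_normalize(tpm(cm), spikein_mask=cm.spikein_mask), cm)
            for line, cm in ds.counts.items()
        }
        truth = ds.truth.planted_targets
        for tf in TFS:
            fc = pd.DataFrame({
                line: log2fc(nm, cm.sample_meta, f"si{tf}")[line]
                for line, (nm, cm) in norm.items()
            })
            sub = truth[truth["tf"] == tf]
            for r in sub.itertuples(index=False):
                rec = fc.loc[r.gene, list(CELL_LINES[r.context])].mean()
                assert rec == pytest.approx(r.expected_log2fc, abs=0.03)
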