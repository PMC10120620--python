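"""Planted-truth recovery experiments on the synthetic study.

Each function simulates data with :mod:`tfrewire.simulate`, runs the
relevant pipeline stages, and measures agreement with the planted truth.
They are the package's validation battery: the test suite asserts on their
outputs and the acceptance script reports them.

Problem sizes: single-dataset experiments run on the default mini-genome
(2 x 1 Mb, 200 genes, 500 candidate sites); multi-seed sweeps use a reduced
genome (2 x 0.6 Mb, 100 genes, 250 sites, duplicate rather than quadruplicate
libraries) so a 50-seed sweep stays near a minute on one core.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cobinding import (
    TFS,
    compare_contexts,
    count_cobinding,
    enhancer_binding_permutation,
)
from .enhancers import call_super, stitch
from .expression import (
    DegTable,
    call_high_confidence,
    loess_normalize,
    log2fc,
    tpm,
)
from .intervals import GenomeLayout, GenomicInterval, IntervalSet
from .simulate import (
    CELL_LINES,
    CONTEXTS,
    SimulationConfig,
    SyntheticDataset,
    simulate_all,
)
from .wiring import build_circuit, classify_targets

# sweep-scale study: reduced genome, duplicate libraries
def sweep_config(seed: int, noise_sd: float = 0.1) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, chrom_length=600_000, n_genes=100, n_tads=12,
        peaks_per_tf=250, noise_sd=noise_sd, n_samples_per_condition=2,
    )


def deg_tables_for(ds: SyntheticDataset,
                   threshold: float = 0.5) -> dict[str, DegTable]:
    """Spike-in-anchored normalization + high-confidence calling, per TF."""
    norm = {}
    for line, cm in ds.counts.items():
        norm[line] = (
            loess_normalize(tpm(cm), spikein_mask=cm.spikein_mask), cm
        )
    line_ctx = {line: ctx for ctx in CELL_LINES for line in CELL_LINES[ctx]}
    tables = {}
    for tf in TFS:
        cols = {}
        for line, (nm, cm) in norm.items():
            fc = log2fc(nm, cm.sample_meta, f"si{tf}")
            cols[line] = fc.loc[~cm.spikein_mask, line]
        tables[tf] = call_high_confidence(
            pd.DataFrame(cols), line_ctx, tf, threshold=threshold
        )
    return tables


def _combined(tables: dict[str, DegTable]) -> DegTable:
    return DegTable(
        per_cell_line=pd.concat(
            [t.per_cell_line for t in tables.values()], ignore_index=True
        ),
        per_context=pd.concat(
            [t.per_context for t in tables.values()], ignore_index=True
        ),
    )


def mode_recovery(config: SimulationConfig) -> dict[str, float]:
    """Fraction of planted targets whose mode AND sign the pipeline
    recovers, plus sign-only recovery and unplanted extra calls."""
    ds = simulate_all(config)
    combined = _combined(deg_tables_for(ds))
    truth = ds.truth.planted_targets
    n_ok = n_sign = n_total = 0
    extras = 0
    for ctx in CONTEXTS:
        calls = classify_targets(
            combined, ds.tf_peaks[ctx], ds.genes, ds.tads, context=ctx,
            promoter_window=config.promoter_window,
        )
        call_map = {(c.tf, c.gene): (c.mode, c.sign) for c in calls}
        sub = truth[truth["context"] == ctx]
        for r in sub.itertuples(index=False):
            n_total += 1
            got = call_map.get((r.tf, r.gene))
            if got is None:
                continue
            if got[1] == r.sign:
                n_sign += 1
            if got == (r.mode, r.sign):
                n_ok += 1
        extras += len(call_map) - len(sub)
    return {
        "mode_and_sign_pct": 100.0 * n_ok / n_total,
        "sign_pct": 100.0 * n_sign / n_total,
        "n_planted": n_total,
        "n_extra_calls": extras,
    }


def noisy_mode_recovery(n_seeds: int = 50, base_seed: int = 100,
                        noise_sd: float = 0.1) -> dict[str, float]:
    """Mode+sign recovery pooled over seeded noisy sweep datasets."""
    oks = []
    for s in range(n_seeds):
        r = mode_recovery(sweep_config(base_seed + s, noise_sd=noise_sd))
        oks.append((r["mode_and_sign_pct"], r["n_planted"]))
    total = sum(n for _, n in oks)
    hits = sum(pct / 100.0 * n for pct, n in oks)
    return {"mode_and_sign_pct": 100.0 * hits / total,
            "n_planted": total, "n_seeds": n_seeds}


def log2fc_recovery(n_seeds: int = 5, base_seed: int = 200,
                    noise_sd: float = 0.1,
                    global_shift: float = 1.0) -> dict[str, float]:
    """Planted-effect recovery through TPM + spike-in loess.

    Uses the default-size study with a planted 2-fold spike-in-certified
    global shift; reports the fraction of planted targets whose recovered
    per-context log2FC lies within +/-0.1 of the planted value.
    """
    errs = []
    for s in range(n_seeds):
        config = SimulationConfig(seed=base_seed + s, noise_sd=noise_sd,
                                  global_shift=global_shift)
        ds = simulate_all(config)
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
            for r in truth[truth["tf"] == tf].itertuples(index=False):
                rec = fc.loc[r.gene, list(CELL_LINES[r.context])].mean()
                errs.append(rec - r.expected_log2fc)
    errs = np.abs(np.asarray(errs))
    return {
        "within_0p1_pct": 100.0 * float(np.mean(errs <= 0.1)),
        "median_abs_error": float(np.median(errs)),
        "max_abs_error": float(np.max(errs)),
        "n_targets": int(errs.size),
    }


def distortion_removal(seed: int = 7) -> dict[str, float]:
    """Residual global log-ratio after removing a 2-fold library-depth
    distortion that also scales the spike-ins (so it is an artifact)."""
    config = SimulationConfig(seed=seed, noise_sd=0.1)
    ds = simulate_all(config)
    line, cm = next(iter(ds.counts.items()))
    t = tpm(cm)
    distorted = t.copy()
    distorted.iloc[:, 0] *= 2.0  # depth artifact: every row of one library
    norm = loess_normalize(distorted, spikein_mask=cm.spikein_mask)
    logm = np.log2(norm.to_numpy() + 1.0)
    m = logm[:, 0] - logm[:, 1:].mean(axis=1)
    return {"abs_median_logratio": float(abs(np.median(m))), "n_rows": len(m)}


def superenhancer_recovery(config: Optional[SimulationConfig] = None,
                           stitch_distance: int = 2_000,
                           tss_exclusion: int = 2_500) -> dict[str, dict]:
    """Planted vs called super-enhancer counts per context."""
    config = config or SimulationConfig()
    ds = simulate_all(config)
    out = {}
    for ctx in CONTEXTS:
        regions = call_super(
            stitch(ds.h3k27ac[ctx], stitch_distance,
                   tss_exclusion=(ds.genes, tss_exclusion))
        )
        called = IntervalSet(
            [r.interval for r in regions if r.is_super]
        )
        planted = ds.truth.planted_superenhancers[ctx]
        matched = int(np.sum(planted.overlaps_any(called)))
        out[ctx] = {
            "planted": len(planted),
            "called": int(sum(r.is_super for r in regions)),
            "planted_matched": matched,
        }
    return out


def permutation_planted(seed: int = 7,
                        n_permutations: int = 9_999) -> dict[str, float]:
    """Enrichment p when the tested enhancers ARE TF-bound sites.

    Every enhancer overlaps a peak, the genome is sparse, so the observed
    fraction (1.0) beats all permutations and p hits its floor
    1/(n_permutations + 1)."""
    ds = simulate_all(SimulationConfig(seed=seed))
    ctx = "FTSEC"
    enhancers = IntervalSet(list(ds.tf_peaks[ctx]["PAX8"])[:200])
    result, k_frac = enhancer_binding_permutation(
        enhancers, ds.tf_peaks[ctx], ds.layout,
        n_permutations=n_permutations, seed=seed,
    )
    return {
        "p_empirical": result.p_empirical,
        "observed": result.observed_statistic,
        "n_permutations": n_permutations,
        "bound_by_4_fraction": float(
            k_frac.loc[k_frac["k"] == 4, "fraction"].iloc[0]
        ),
    }


def permutation_calibration(n_sims: int = 200, seed: int = 7,
                            n_permutations: int = 499,
                            n_enhancers: int = 300) -> dict[str, float]:
    """Uniformity of the empirical p-value under the null.

    TF peak sets are held fixed; in each simulation the enhancers
    themselves are drawn uniformly (the null), the permutation test runs,
    and the 200 p-values are compared to Uniform(0,1) by a KS test.
    """
    layout = GenomeLayout.from_lengths(
        {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    rng = np.random.default_rng([seed, 5])
    peaksets = {}
    for tf in TFS:
        ivs = []
        for _ in range(150):
            chrom = f"chr{1 + int(rng.integers(2))}"
            s = int(rng.integers(0, 999_400))
            ivs.append(GenomicInterval(chrom, s, s + 600))
        peaksets[tf] = IntervalSet(ivs)
    pvals = []
    for sim in range(n_sims):
        r2 = np.random.default_rng([seed, 7, sim])
        enh = []
        for _ in range(n_enhancers):
            chrom = f"chr{1 + int(r2.integers(2))}"
            length = int(r2.integers(300, 1200))
            s = int(r2.integers(0, 1_000_000 - length))
            enh.append(GenomicInterval(chrom, s, s + length))
        result, _ = enhancer_binding_permutation(
            IntervalSet(enh), peaksets, layout,
            n_permutations=n_permutations, seed=seed + sim,
        )
        pvals.append(result.p_empirical)
    ks = stats.kstest(np.asarray(pvals), "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
            "mean_p": float(np.mean(pvals)), "n_sims": n_sims}


def context_overlap(config: Optional[SimulationConfig] = None) -> dict:
    """Common-vs-specific peak fractions between the two contexts."""
    config = config or SimulationConfig()
    ds = simulate_all(config)
    fracs = {}
    for tf in TFS:
        comp = compare_contexts(
            ds.tf_peaks["FTSEC"][tf], ds.tf_peaks["HGSC"][tf], tf=tf,
            context_a="FTSEC", context_b="HGSC",
        )
        fracs[tf] = comp.fraction_common
    return {
        "fraction_common_pct": {tf: 100.0 * v for tf, v in fracs.items()},
        "mean_fraction_common_pct": 100.0 * float(np.mean(list(fracs.values()))),
    }


def cobinding_truth_match(config: Optional[SimulationConfig] = None) -> dict:
    """Union-region TF membership vs the planted co-binding table."""
    config = config or SimulationConfig()
    ds = simulate_all(config)
    out = {}
    for ctx in CONTEXTS:
        table = count_cobinding(ds.tf_peaks[ctx]).table
        got = {
            (r.chrom, r.start, r.end): tuple(
                bool(getattr(r, tf)) for tf in TFS
            )
            for r in table.itertuples(index=False)
        }
        truth = ds.truth.planted_cobinding
        sub = truth[truth["context"] == ctx]
        n_match = 0
        for r in sub.itertuples(index=False):
            if got.get((r.chrom, r.start, r.end)) == tuple(
                bool(getattr(r, tf)) for tf in TFS
            ):
                n_match += 1
        out[ctx] = {
            "planted_regions": len(sub),
            "union_regions": len(got),
            "matching": n_match,
            "match_pct": 100.0 * n_match / len(sub),
        }
    return out


def circuit_recovery(config: Optional[SimulationConfig] = None) -> dict:
    """Planted vs inferred signed TF-TF circuit edges."""
    config = config or SimulationConfig(noise_sd=0.0)
    ds = simulate_all(config)
    graph = build_circuit(deg_tables_for(ds))
    planted = {
        (r.regulator, r.target, r.context,
         "activates" if r.sign == "activates" else "represses")
        for r in ds.truth.planted_circuit.itertuples(index=False)
    }
    inferred = {
        (r.regulator, r.target, r.context, r.sign)
        for r in graph.edges.itertuples(index=False)
    }
    n_ok = len(planted & inferred)
    return {
        "planted_edges": len(planted),
        "inferred_edges": len(inferred),
        "recovered_pct": 100.0 * n_ok / len(planted),
        "spurious_edges": len(inferred - planted),
    }
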