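"""End-to-end orchestration: simulate -> enhancers -> cobinding -> deg ->
targets -> panel, with a reproducibility manifest.

Stages run in dependency order and never mutate each other's outputs; a
rerun with the same config reproduces all outputs byte-identically (the
manifest deliberately records no wall-clock information). Analysis
parameters default to values scaled for the synthetic mini-genome (e.g.
stitch distance 2,000 bp on a 2 Mb genome rather than the 12,500 bp used on
a full-size genome); every parameter is recorded in the manifest and
serialized config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cobinding import (
    TFS,
    compare_contexts,
    count_cobinding,
    enhancer_binding_permutation,
    signal_matrix,
)
from .enhancers import (
    assign_regions_to_genes,
    build_state_map,
    call_super,
    loop_anchor_overlap,
    stitch,
)
from .expression import (
    DegTable,
    call_high_confidence,
    log2fc,
    loess_normalize,
    tpm,
)
from .intervals import IntervalSet, write_bed
from .panel import cluster_tissues, co_positivity, rank_by_correlation
from .simulate import (
    CELL_LINES,
    CONTEXTS,
    SimulationConfig,
    SyntheticDataset,
    simulate_all,
    simulate_positivity,
    simulate_tissue_panel,
    write_dataset,
)
from .wiring import (
    build_circuit,
    calls_to_frame,
    classify_targets,
    rewiring_summary,
    write_calls,
)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All parameters of a pipeline run; serialized verbatim to the output
    directory so a run is reproducible from its manifest alone."""

    outdir: str = "tfrewire_run"
    seed: int = 7
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # enhancer landscape
    stitch_distance: int = 2_000
    tss_exclusion_window: int = 2_500
    promoter_window: int = 2_000
    loop_slop: int = 0
    # cobinding / permutation
    n_permutations: int = 999
    # expression
    deg_threshold: float = 0.5
    loess_span: float = 0.6
    pseudocount: float = 1.0
    anchor: str = "spikeins_only"
    # panel
    panel_k: int = 5

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)
        self.sim.seed = self.seed

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _hc_frame(deg_tables: dict[str, DegTable]) -> DegTable:
    """Concatenate per-TF DegTables into one table (tf column set)."""
    per_cell = pd.concat([d.per_cell_line for d in deg_tables.values()],
                         ignore_index=True)
    per_ctx = pd.concat([d.per_context for d in deg_tables.values()],
                        ignore_index=True)
    thr = next(iter(deg_tables.values())).threshold
    return DegTable(per_cell_line=per_cell, per_context=per_ctx, threshold=thr)


def run_all(config: PipelineConfig,
            dataset: Optional[SyntheticDataset] = None) -> dict:
    """Run every stage; returns the manifest (also written to outdir).

    When ``dataset`` is None the synthetic study is simulated from
    ``config.sim`` (config.simulate must be true); passing a pre-built
    dataset lets callers rerun downstream stages on fixed inputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "tfrewire",
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    # --- stage: simulate -------------------------------------------------
    if dataset is None:
        if not config.simulate:
            raise ValueError("no dataset supplied and simulate disabled")
        dataset = simulate_all(config.sim)
    write_dataset(dataset, outdir / "simulate")
    manifest["stages"]["simulate"] = {
        "n_genes": int(len(dataset.genes)),
        "n_tads": int(len(dataset.tads.tads)),
        "n_peaks": {
            ctx: {tf: len(dataset.tf_peaks[ctx][tf]) for tf in TFS}
            for ctx in CONTEXTS
        },
    }

    # --- stage: enhancers ------------------------------------------------
    enh_dir = outdir / "enhancers"
    enh_dir.mkdir(exist_ok=True)
    state_maps = {}
    regions_by_ctx = {}
    enh_stats = {}
    for ctx in CONTEXTS:
        regions = stitch(
            dataset.h3k27ac[ctx], config.stitch_distance,
            tss_exclusion=(dataset.genes, config.tss_exclusion_window),
        )
        regions = call_super(regions)
        regions_by_ctx[ctx] = regions
        state_maps[ctx] = build_state_map(
            dataset.h3k27ac[ctx], dataset.h3k27me3[ctx], dataset.genes,
            promoter_window=config.promoter_window,
            stitch_distance=config.stitch_distance,
            tss_exclusion_window=config.tss_exclusion_window,
            context=ctx,
        )
        rows = [
            (r.interval.chrom, r.interval.start, r.interval.end,
             len(r.constituents), r.total_signal, r.rank, r.is_super)
            for r in sorted(regions, key=lambda r: r.rank)
        ]
        pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "n_constituents",
                     "total_signal", "rank", "is_super"],
        ).to_csv(enh_dir / f"regions_{ctx}.tsv", sep="\t", index=False)
        assign = assign_regions_to_genes(regions, dataset.genes, dataset.tads)
        assign.to_csv(enh_dir / f"region_genes_{ctx}.tsv", sep="\t",
                      index=False)
        counts, frac = loop_anchor_overlap(
            dataset.loops[ctx], regions, slop=config.loop_slop
        )
        enh_stats[ctx] = {
            "n_regions": len(regions),
            "n_super": int(sum(r.is_super for r in regions)),
            "se_loop_fraction": frac,
        }
        for name, ivs in state_maps[ctx].classes().items():
            write_bed(ivs, enh_dir / f"{name}_{ctx}.bed")
    manifest["stages"]["enhancers"] = enh_stats

    # --- stage: cobinding ------------------------------------------------
    cob_dir = outdir / "cobinding"
    cob_dir.mkdir(exist_ok=True)
    cob_stats = {}
    for ctx in CONTEXTS:
        table = count_cobinding(dataset.tf_peaks[ctx], state_maps[ctx],
                                context=ctx)
        table.table.to_csv(cob_dir / f"cobinding_{ctx}.tsv", sep="\t",
                           index=False)
        pd.DataFrame(
            sorted(table.per_tf_cobound_fraction.items()),
            columns=["tf", "fraction_cobound_ge2"],
        ).to_csv(cob_dir / f"per_tf_cobound_{ctx}.tsv", sep="\t", index=False)
        cob_stats[ctx] = {
            "n_union_regions": len(table.regions),
            "n_bound_by_4": int((table.table["n_tfs_bound"] == 4).sum()),
        }
    comparisons = {}
    for tf in TFS:
        comp = compare_contexts(
            dataset.tf_peaks["FTSEC"][tf], dataset.tf_peaks["HGSC"][tf],
            tf=tf, context_a="FTSEC", context_b="HGSC",
        )
        comparisons[tf] = comp
        pd.DataFrame(
            [(tf, comp.specific_a, comp.specific_b, comp.common_regions,
              comp.fraction_common)],
            columns=["tf", "specific_FTSEC", "specific_HGSC", "common",
                     "fraction_common"],
        ).to_csv(cob_dir / f"compare_{tf}.tsv", sep="\t", index=False)
    perm_stats = {}
    for ctx in CONTEXTS:
        other = CONTEXTS[1 - CONTEXTS.index(ctx)]
        own_enh = IntervalSet(
            list(state_maps[ctx].typical_enhancers)
            + list(state_maps[ctx].super_enhancers)
        ).merge(0)
        other_enh = IntervalSet(
            list(state_maps[other].typical_enhancers)
            + list(state_maps[other].super_enhancers)
        ).merge(0)
        specific = IntervalSet(
            [own_enh[i] for i in np.nonzero(~own_enh.overlaps_any(other_enh))[0]],
            label=f"{ctx}_specific_enhancers",
        )
        if len(specific) == 0:
            specific = own_enh
        result, k_frac = enhancer_binding_permutation(
            specific, dataset.tf_peaks[ctx], dataset.layout,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        k_frac.to_csv(cob_dir / f"bound_by_k_{ctx}.tsv", sep="\t", index=False)
        perm_stats[ctx] = {
            "observed": result.observed_statistic,
            "p_empirical": result.p_empirical,
            "n_permutations": result.n_permutations,
            "n_specific_enhancers": len(specific),
        }
        (cob_dir / f"permtest_{ctx}.json").write_text(
            json.dumps(perm_stats[ctx], indent=1, sort_keys=True)
        )
    manifest["stages"]["cobinding"] = {**cob_stats, "permutation": perm_stats}

    # signal-profile matrix around context-specific PAX8 peaks
    for ctx in CONTEXTS:
        comp = comparisons["PAX8"]
        centers = (comp.specific_a_peaks if ctx == "FTSEC"
                   else comp.specific_b_peaks)
        if len(centers) == 0:
            continue
        mat, _ = signal_matrix(
            dataset.h3k27ac_track[ctx], centers, window=3000, bin_size=100,
            library_size=1e6, genome=dataset.layout,
        )
        np.savetxt(cob_dir / f"profile_PAX8_{ctx}.tsv", mat, delimiter="\t",
                   fmt="%.6g")

    # --- stage: deg ------------------------------------------------------
    deg_dir = outdir / "deg"
    deg_dir.mkdir(exist_ok=True)
    line_context = {line: ctx for ctx in CONTEXTS for line in CELL_LINES[ctx]}
    norm_by_line = {}
    for line, cm in dataset.counts.items():
        t = tpm(cm)
        norm = loess_normalize(
            t, spikein_mask=cm.spikein_mask, anchor=config.anchor,
            span=config.loess_span, pseudocount=config.pseudocount,
        )
        norm_by_line[line] = (norm, cm)
        norm.round(4).to_csv(deg_dir / f"norm_tpm_{line}.tsv", sep="\t")
    deg_tables: dict[str, DegTable] = {}
    for tf in TFS:
        fc_cols = {}
        for line, (norm, cm) in norm_by_line.items():
            genes_only = ~cm.spikein_mask
            fc = log2fc(norm, cm.sample_meta, f"si{tf}",
                        pseudocount=config.pseudocount)
            fc_cols[line] = fc.loc[genes_only, line]
        fc_frame = pd.DataFrame(fc_cols)
        deg_tables[tf] = call_high_confidence(
            fc_frame, line_context, tf, threshold=config.deg_threshold
        )
    combined = _hc_frame(deg_tables)
    combined.per_context.to_csv(deg_dir / "deg_per_context.tsv", sep="\t",
                                index=False)
    combined.per_cell_line.round(6).to_csv(
        deg_dir / "deg_per_cell_line.tsv", sep="\t", index=False
    )
    manifest["stages"]["deg"] = {
        "n_high_confidence": {
            ctx: int(
                combined.per_context[
                    (combined.per_context["context"] == ctx)
                    & combined.per_context["high_confidence"]
                ].shape[0]
            )
            for ctx in CONTEXTS
        }
    }

    # --- stage: targets --------------------------------------------------
    tgt_dir = outdir / "targets"
    tgt_dir.mkdir(exist_ok=True)
    calls_by_ctx = {}
    for ctx in CONTEXTS:
        calls = classify_targets(
            combined, dataset.tf_peaks[ctx], dataset.genes, dataset.tads,
            context=ctx, promoter_window=config.promoter_window,
        )
        calls_by_ctx[ctx] = calls
        write_calls(calls, tgt_dir / f"targets_{ctx}.tsv")
    rewiring = rewiring_summary(calls_by_ctx["FTSEC"], calls_by_ctx["HGSC"])
    rewiring.to_csv(tgt_dir / "rewiring.tsv", sep="\t", index=False)
    circuit = build_circuit(deg_tables)
    circuit.edges.round(6).to_csv(tgt_dir / "circuit_edges.tsv", sep="\t",
                                  index=False)
    (tgt_dir / "circuit.dot").write_text(circuit.to_dot())
    manifest["stages"]["targets"] = {
        "n_calls": {ctx: len(calls_by_ctx[ctx]) for ctx in CONTEXTS},
        "n_circuit_edges": int(len(circuit.edges)),
    }

    # --- stage: panel ----------------------------------------------------
    pan_dir = outdir / "panel"
    pan_dir.mkdir(exist_ok=True)
    expr, planted_clusters = simulate_tissue_panel(config.sim)
    assignment, centers = cluster_tissues(expr, k=config.panel_k,
                                          seed=config.seed)
    assignment.to_frame().to_csv(pan_dir / "clusters.tsv", sep="\t")
    ranking = rank_by_correlation(expr)
    ranking.round(6).to_csv(pan_dir / "correlation_rank.tsv", sep="\t",
                            index=False)
    pos = co_positivity(simulate_positivity(config.sim))
    pos.round(6).to_csv(pan_dir / "co_positivity.tsv", sep="\t", index=False)
    manifest["stages"]["panel"] = {
        "n_tissues": int(assignment.shape[0]),
        "top_correlated_tissue": str(ranking.iloc[0]["tissue"]),
    }

    config.to_yaml(outdir / "config.yaml")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
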