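"""Synthetic mini-genomes, cistromes, and knockdown count matrices with
planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at a scale where every stage runs in seconds:

* a mini-genome of a few megabases tiled by TADs, with gene TSSs inside
  TADs;
* candidate regulatory sites bound by subsets of the four master TFs
  (MECOM, PAX8, SOX17, WT1), each site either common to both cellular
  contexts (FTSEC and HGSC) or specific to one, so context comparison has
  a known answer;
* H3K27ac peaks whose total-signal distribution is a hockey stick: many
  low-signal typical enhancer loci plus a few isolated, multi-constituent,
  high-signal super-enhancer loci per context (co-bound by all four TFs),
  so super-enhancer calling has an exact planted count; H3K27me3 loci get
  the analogous treatment and are interval-disjoint from active enhancers;
* Hi-C loops anchored at super-enhancer constituents;
* knockdown RNA-seq count matrices (two cell lines per context, two
  control conditions plus one siRNA condition per TF, with ERCC-style
  spike-in rows drawn identically across samples). Planted targets are
  shifted by +/- ``deg_effect_log2fc`` in the matching knockdown samples
  of BOTH cell lines of their context; all gene (non-spike-in) rows of
  knockdown samples are additionally multiplied by ``2**global_shift`` to
  emulate the global transcriptional shift that only spike-in anchoring
  can reveal.

Every element is placed on a 1.5 kb slot grid with at most one element per
slot, so distinct planted peaks never overlap or abut: the merged union
regions seen by the co-binding stage are exactly the planted elements.
Planted target modes (direct / putative / indirect) are derived by an
independent brute-force geometry scan inside the generator, so pipeline
classification can be compared against them.

Counts are log-normal on the log2 scale (integer baseline exponents, so a
noise-free simulation yields exact powers of two) rather than
negative-binomial: downstream only consumes log2 ratios and loess on the
log scale, and the simpler noise model is recorded in the config. All
randomness flows from ``numpy.random.default_rng`` (PCG64) seeded from
``SimulationConfig.seed``; runs are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cobinding import TFS
from .expression import CONTROL_CONDITIONS, CountMatrix
from .genes import write_gene_models
from .intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_bedpe,
)
from .tads import TadMap, write_tads

CONTEXTS = ("FTSEC", "HGSC")
CELL_LINES: dict[str, tuple[str, str]] = {
    "FTSEC": ("FT282", "FT246"),
    "HGSC": ("KURAMOCHI", "OVSAHO"),
}
RNG_ALGORITHM = "numpy PCG64 via numpy.random.default_rng"

# Planted cross-regulation among the four TFs (regulator, target, context,
# edge sign). "activates" plants a DOWN shift of the target on regulator
# knockdown; "represses" plants an UP shift. PAX8 and WT1 drive the other
# factors in both contexts; MECOM and SOX17 participate more in the tumor
# context, where MECOM represses SOX17 and WT1 and SOX17 represses PAX8.
DEFAULT_CIRCUIT: tuple[tuple[str, str, str, str], ...] = tuple(
    [("PAX8", t, ctx, "activates")
     for ctx in CONTEXTS for t in ("MECOM", "SOX17", "WT1")]
    + [("WT1", t, ctx, "activates")
       for ctx in CONTEXTS for t in ("MECOM", "PAX8", "SOX17")]
    + [("SOX17", t, ctx, "activates")
       for ctx in CONTEXTS for t in ("MECOM", "WT1")]
    + [("SOX17", "PAX8", "HGSC", "represses"),
       ("MECOM", "SOX17", "HGSC", "represses"),
       ("MECOM", "WT1", "HGSC", "represses")]
)

__all__ = [
    "CONTEXTS",
    "CELL_LINES",
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_cistromes",
    "simulate_knockdown_counts",
    "simulate_tissue_panel",
    "simulate_positivity",
    "simulate_all",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``peaks_per_tf`` is the number of candidate multi-TF regulatory sites;
    each TF binds a subset of them in each context, so realized per-TF peak
    counts are somewhat below this bound. ``noise_sd`` is the standard
    deviation of per-observation Gaussian noise on log2 counts.
    ``global_shift`` (log2) is the planted composition distortion: gene rows
    of every knockdown sample are multiplied by ``2**global_shift`` while
    spike-in rows are untouched, so the shift is spike-in-certified biology.
    Four replicates per condition keep the log2FC sampling error at
    ``noise_sd`` = 0.1 well inside a +/-0.1 recovery band.
    """

    seed: int = 7
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    n_tads: int = 20
    peaks_per_tf: int = 500
    fraction_context_specific: float = 0.8
    n_spikeins: int = 92
    deg_effect_log2fc: float = 2.0
    noise_sd: float = 0.1
    n_samples_per_condition: int = 4
    global_shift: float = 0.0
    # secondary layout knobs
    n_superenhancers: int = 10       # planted per context
    n_supermethylated: int = 4       # planted per context
    n_methyl_loci: int = 30          # typical H3K27me3 loci per context
    n_direct_targets: int = 3        # per TF per context
    n_putative_targets: int = 3
    n_indirect_targets: int = 3
    peak_width: int = 500
    slot_spacing: int = 1_250
    tad_gap: int = 2_000
    promoter_window: int = 2_000
    rng_algorithm: str = RNG_ALGORITHM

    def validate(self) -> None:
        counts = dict(
            n_chroms=self.n_chroms, chrom_length=self.chrom_length,
            n_genes=self.n_genes, n_tads=self.n_tads,
            peaks_per_tf=self.peaks_per_tf, n_spikeins=self.n_spikeins,
            n_samples_per_condition=self.n_samples_per_condition,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not 0.0 <= self.fraction_context_specific <= 1.0:
            raise ValueError("fraction_context_specific must lie in [0, 1]")
        if self.n_tads < self.n_chroms:
            raise ValueError("need at least one TAD per chromosome")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Machine-readable planted ground truth.

    ``planted_targets`` rows: tf, gene, context, mode, sign,
    expected_log2fc (on the spike-in-anchored scale: planted effect plus
    the global shift). ``planted_cobinding`` rows: context, chrom, start,
    end, one boolean column per TF. ``planted_clusters`` maps tissue ->
    archetype id for the tissue panel (empty until the panel is simulated).
    """

    planted_superenhancers: dict[str, IntervalSet]
    planted_supermethylated: dict[str, IntervalSet]
    planted_cobinding: pd.DataFrame
    planted_targets: pd.DataFrame
    planted_circuit: pd.DataFrame
    planted_clusters: dict[str, int]
    global_shift: float
    rng_algorithm: str = RNG_ALGORITHM

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "rng_algorithm": self.rng_algorithm,
            "global_shift": self.global_shift,
            "planted_superenhancers": {
                ctx: [[iv.chrom, iv.start, iv.end] for iv in ivs]
                for ctx, ivs in self.planted_superenhancers.items()
            },
            "planted_supermethylated": {
                ctx: [[iv.chrom, iv.start, iv.end] for iv in ivs]
                for ctx, ivs in self.planted_supermethylated.items()
            },
            "planted_cobinding": self.planted_cobinding.to_dict("records"),
            "planted_targets": self.planted_targets.to_dict("records"),
            "planted_circuit": self.planted_circuit.to_dict("records"),
            "planted_clusters": self.planted_clusters,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())

        def frame(records, columns):
            return pd.DataFrame(records, columns=columns)

        payload["planted_cobinding"] = frame(
            payload["planted_cobinding"],
            ["context", "chrom", "start", "end", *TFS],
        )
        payload["planted_targets"] = frame(
            payload["planted_targets"],
            ["tf", "gene", "context", "mode", "sign", "expected_log2fc"],
        )
        payload["planted_circuit"] = frame(
            payload["planted_circuit"],
            ["regulator", "target", "context", "sign"],
        )
        return cls(
            planted_superenhancers={
                ctx: IntervalSet([GenomicInterval(c, s, e) for c, s, e in rows])
                for ctx, rows in payload["planted_superenhancers"].items()
            },
            planted_supermethylated={
                ctx: IntervalSet([GenomicInterval(c, s, e) for c, s, e in rows])
                for ctx, rows in payload["planted_supermethylated"].items()
            },
            planted_cobinding=payload["planted_cobinding"],
            planted_targets=payload["planted_targets"],
            planted_circuit=payload["planted_circuit"],
            planted_clusters=dict(payload["planted_clusters"]),
            global_shift=float(payload["global_shift"]),
            rng_algorithm=payload["rng_algorithm"],
        )


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    config: SimulationConfig
    layout: GenomeLayout
    genes: pd.DataFrame
    tads: TadMap
    tf_peaks: dict[str, dict[str, IntervalSet]]      # context -> tf -> peaks
    h3k27ac: dict[str, IntervalSet]                  # context -> signal peaks
    h3k27me3: dict[str, IntervalSet]
    h3k27ac_track: dict[str, SignalTrack]
    loops: dict[str, list[tuple[GenomicInterval, GenomicInterval]]]
    counts: dict[str, CountMatrix]                   # cell line -> matrix
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeLayout, pd.DataFrame, TadMap]:
    """Mini-genome: chromosomes, TAD tiling, gene models.

    TADs tile each chromosome (shrunk by a small gap at each boundary, so
    the map has thin unassigned strips); every gene's TSS lies inside
    exactly one TAD. Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    layout = GenomeLayout.from_lengths({n: config.chrom_length for n in names})

    # distribute TADs across chromosomes as evenly as possible
    per_chrom = np.full(config.n_chroms, config.n_tads // config.n_chroms)
    per_chrom[: config.n_tads % config.n_chroms] += 1
    tads: list[GenomicInterval] = []
    for ci, chrom in enumerate(names):
        k = int(per_chrom[ci])
        L = config.chrom_length
        # breakpoints with a minimum domain width
        min_w = max(4 * config.tad_gap, L // (4 * k))
        bounds = None
        for _ in range(1000):
            cuts = np.sort(rng.integers(min_w, L - min_w, size=k - 1)) if k > 1 \
                else np.array([], dtype=np.int64)
            cand = np.concatenate([[0], cuts, [L]])
            if np.all(np.diff(cand) >= min_w):
                bounds = cand
                break
        if bounds is None:  # dense tiling fallback: even spacing
            bounds = np.linspace(0, L, k + 1).astype(np.int64)
        for a, b in zip(bounds[:-1], bounds[1:]):
            tads.append(
                GenomicInterval(chrom, int(a) + config.tad_gap // 2,
                                int(b) - config.tad_gap // 2)
            )
    tad_map = TadMap(tads)

    genes = _place_genes(config, layout, tad_map, rng)
    return layout, genes, tad_map


def _slot_grid(config: SimulationConfig, layout: GenomeLayout) -> pd.DataFrame:
    rows = []
    margin = 5_000
    for chrom in layout.chrom_names:
        centers = np.arange(margin, layout.length_of(chrom) - margin,
                            config.slot_spacing, dtype=np.int64)
        for si, c in enumerate(centers):
            rows.append((chrom, si, int(c)))
    return pd.DataFrame(rows, columns=["chrom", "slot", "center"])


def _place_genes(
    config: SimulationConfig,
    layout: GenomeLayout,
    tads: TadMap,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign the gene slots of the grid; first four genes ARE the TF genes."""
    grid = _slot_grid(config, layout)
    inside = np.array(
        [tads.tad_index_of(r.chrom, r.center) is not None
         for r in grid.itertuples(index=False)]
    )
    eligible = grid[inside].reset_index(drop=True)
    if len(eligible) < config.n_genes:
        raise ValueError("genome too small for requested gene count")
    pick = rng.choice(len(eligible), size=config.n_genes, replace=False)
    pick.sort()
    chosen = eligible.iloc[pick]
    ids = list(TFS) + [f"G{i:04d}" for i in range(5, config.n_genes + 1)]
    lengths = rng.choice([500, 1000, 2000, 4000], size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": ids[: config.n_genes],
            "chrom": chosen["chrom"].to_numpy(),
            "strand": strands,
            "tss": chosen["center"].to_numpy(),
            "length": lengths,
        }
    )
    return genes


# ---------------------------------------------------------------------------
# cistromes
# ---------------------------------------------------------------------------

def _split_common_specific(
    n_per_context: int, fraction_specific: float, rng: np.random.Generator
) -> list[str]:
    """Class labels giving exactly ``n_per_context`` loci in each context."""
    n_common = int(round((1.0 - fraction_specific) * n_per_context))
    labels = ["common"] * n_common
    for ctx in CONTEXTS:
        labels += [ctx] * (n_per_context - n_common)
    return labels


class _SlotPool:
    """Hands out free slots / consecutive-slot blocks from the grid."""

    def __init__(self, grid: pd.DataFrame, rng: np.random.Generator,
                 used_centers: set[tuple[str, int]]):
        self.rng = rng
        self.by_chrom: dict[str, np.ndarray] = {}
        self.used: dict[str, np.ndarray] = {}
        for chrom, sub in grid.groupby("chrom"):
            centers = sub.sort_values("slot")["center"].to_numpy()
            self.by_chrom[chrom] = centers
            self.used[chrom] = np.array(
                [(chrom, int(c)) in used_centers for c in centers]
            )
        self.chroms = list(self.by_chrom)

    def take_block(self, width: int) -> tuple[str, np.ndarray]:
        """Reserve ``width`` consecutive free slots; returns their centers."""
        for _ in range(10_000):
            chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
            centers = self.by_chrom[chrom]
            if len(centers) < width:
                continue
            start = int(self.rng.integers(0, len(centers) - width + 1))
            if not self.used[chrom][start : start + width].any():
                self.used[chrom][start : start + width] = True
                return chrom, centers[start : start + width]
        raise ValueError("slot grid exhausted; genome too small for config")

    def take_singles(self, n: int) -> list[tuple[str, int]]:
        free = [
            (chrom, int(c))
            for chrom in self.chroms
            for c, u in zip(self.by_chrom[chrom], self.used[chrom])
            if not u
        ]
        if len(free) < n:
            raise ValueError("slot grid exhausted; genome too small for config")
        idx = self.rng.choice(len(free), size=n, replace=False)
        out = [free[i] for i in sorted(idx)]
        for chrom, c in out:
            centers = self.by_chrom[chrom]
            self.used[chrom][np.searchsorted(centers, c)] = True
        return out


def _peak_at(chrom: str, center: int, width: int,
             signal: Optional[float] = None,
             name: Optional[str] = None) -> GenomicInterval:
    half = width // 2
    return GenomicInterval(chrom, center - half, center - half + width,
                           signal=signal, name=name)


def simulate_cistromes(
    config: SimulationConfig,
    layout: GenomeLayout,
    genes: pd.DataFrame,
    tads: TadMap,
) -> tuple[dict[str, dict[str, IntervalSet]], dict[str, IntervalSet],
           dict[str, IntervalSet], SyntheticTruth]:
    """Plant TF peaks, H3K27ac/H3K27me3 signal peaks, and derived truth.

    Returns (tf_peaks[context][tf], h3k27ac[context], h3k27me3[context],
    truth). Truth covers co-binding membership per planted region,
    super-enhancer / super-methylated intervals per context, and the planted
    target table (with modes from an independent geometry scan and signs
    assigned at random, plus the planted TF-TF circuit).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 23])
    grid = _slot_grid(config, layout)
    gene_slots = {(r.chrom, int(r.tss)) for r in genes.itertuples(index=False)}

    # reserve ~1/4 of TADs as TF-binding deserts so indirect targets (DEGs
    # with no TF peak anywhere in their TAD) exist by construction
    tad_list = tads.tads
    n_desert = max(1, len(tad_list) // 5)
    desert_idx = set(
        int(i) for i in rng.choice(len(tad_list), size=n_desert, replace=False)
    )
    desert = [tad_list[i] for i in sorted(desert_idx)]

    def _in_desert(chrom: str, pos: int) -> bool:
        return any(t.chrom == chrom and t.start <= pos < t.end for t in desert)

    blocked = set(gene_slots)
    for r in grid.itertuples(index=False):
        if _in_desert(r.chrom, int(r.center)):
            blocked.add((r.chrom, int(r.center)))
    pool = _SlotPool(grid, rng, used_centers=blocked)
    w = config.peak_width

    # --- super-enhancer loci: 7-slot blocks, constituents on middle 3 slots
    se_labels = _split_common_specific(
        config.n_superenhancers, config.fraction_context_specific, rng
    )
    se_loci = []  # (label, chrom, constituent centers)
    for label in se_labels:
        chrom, centers = pool.take_block(7)
        se_loci.append((label, chrom, centers[2:5]))
    sm_labels = _split_common_specific(
        config.n_supermethylated, config.fraction_context_specific, rng
    )
    sm_loci = []
    for label in sm_labels:
        chrom, centers = pool.take_block(7)
        sm_loci.append((label, chrom, centers[2:5]))

    # --- candidate co-binding sites
    n_sites = config.peaks_per_tf
    site_slots = pool.take_singles(n_sites)
    k_weights = np.array([0.15, 0.15, 0.25, 0.45])
    site_rows = []
    for chrom, center in site_slots:
        k = int(rng.choice([1, 2, 3, 4], p=k_weights))
        members = sorted(rng.choice(len(TFS), size=k, replace=False))
        if rng.random() < config.fraction_context_specific:
            label = CONTEXTS[int(rng.integers(2))]
        else:
            label = "common"
        site_rows.append((chrom, center, label, tuple(members)))

    # --- typical H3K27me3 loci, per context, independent slots
    me3_slots = {ctx: pool.take_singles(config.n_methyl_loci)
                 for ctx in CONTEXTS}

    # --- assemble per-context peak sets
    tf_peaks: dict[str, dict[str, list[GenomicInterval]]] = {
        ctx: {tf: [] for tf in TFS} for ctx in CONTEXTS
    }
    h3k27ac: dict[str, list[GenomicInterval]] = {ctx: [] for ctx in CONTEXTS}
    h3k27me3: dict[str, list[GenomicInterval]] = {ctx: [] for ctx in CONTEXTS}
    cobind_rows = []  # context, chrom, start, end, per-TF flags

    def _active(label: str, ctx: str) -> bool:
        return label in ("common", ctx)

    for si, (chrom, center, label, members) in enumerate(site_rows):
        peak = _peak_at(chrom, center, w, name=f"site{si:05d}")
        for ctx in CONTEXTS:
            if not _active(label, ctx):
                continue
            flags = [ti in members for ti in range(len(TFS))]
            for ti, tf in enumerate(TFS):
                if flags[ti]:
                    tf_peaks[ctx][tf].append(peak)
            cobind_rows.append((ctx, chrom, peak.start, peak.end, *flags))

    se_truth: dict[str, list[GenomicInterval]] = {ctx: [] for ctx in CONTEXTS}
    for li, (label, chrom, centers) in enumerate(se_loci):
        sigs = rng.uniform(400, 600, size=len(centers))
        consts = [
            _peak_at(chrom, int(c), w, signal=float(s),
                     name=f"se{li:03d}_c{j}")
            for j, (c, s) in enumerate(zip(centers, sigs))
        ]
        span = GenomicInterval(chrom, consts[0].start, consts[-1].end)
        for ctx in CONTEXTS:
            if not _active(label, ctx):
                continue
            se_truth[ctx].append(span)
            for c in consts:
                h3k27ac[ctx].append(c)
                for tf in TFS:  # super-enhancers are co-bound by all four
                    tf_peaks[ctx][tf].append(
                        GenomicInterval(c.chrom, c.start, c.end, name=c.name)
                    )
                cobind_rows.append(
                    (ctx, chrom, c.start, c.end, True, True, True, True)
                )

    sm_truth: dict[str, list[GenomicInterval]] = {ctx: [] for ctx in CONTEXTS}
    for li, (label, chrom, centers) in enumerate(sm_loci):
        sigs = rng.uniform(400, 600, size=len(centers))
        consts = [
            _peak_at(chrom, int(c), w, signal=float(s))
            for c, s in zip(centers, sigs)
        ]
        span = GenomicInterval(chrom, consts[0].start, consts[-1].end)
        for ctx in CONTEXTS:
            if _active(label, ctx):
                sm_truth[ctx].append(span)
                h3k27me3[ctx].extend(consts)
    for ctx in CONTEXTS:
        for chrom, center in me3_slots[ctx]:
            h3k27me3[ctx].append(
                _peak_at(chrom, center, w, signal=float(rng.uniform(1, 3)))
            )

    # typical-enhancer H3K27ac at a thinned subset of active sites: no two
    # marked sites within 2 grid slots, so stitching never chains typical
    # loci and the hockey stick's lower arm stays tight
    for ctx in CONTEXTS:
        active_sites = [
            (chrom, center) for chrom, center, label, _ in site_rows
            if _active(label, ctx)
        ]
        active_sites.sort()
        last: dict[str, int] = {}
        for chrom, center in active_sites:
            if chrom in last and center - last[chrom] < 2 * config.slot_spacing + 1:
                continue
            if rng.random() < 0.7:
                h3k27ac[ctx].append(
                    _peak_at(chrom, center, w, signal=float(rng.uniform(1, 3)))
                )
                last[chrom] = center

    # --- planted direct targets: TF peak on the gene promoter
    non_tf_genes = [g for g in genes["gene_id"] if g not in TFS]
    non_tf_genes = [non_tf_genes[i]
                    for i in rng.permutation(len(non_tf_genes))]
    gene_info = {str(r.gene_id): r for r in genes.itertuples(index=False)}
    next_gene = iter(non_tf_genes)
    direct_rows = []  # (tf, gene, contexts)
    for tf in TFS:
        labels = _split_common_specific(
            config.n_direct_targets, config.fraction_context_specific, rng
        )
        for label in labels:
            gene = next(next_gene)
            while _in_desert(gene_info[gene].chrom, int(gene_info[gene].tss)):
                gene = next(next_gene)  # keep deserts free of TF peaks
            ctxs = list(CONTEXTS) if label == "common" else [label]
            row = gene_info[gene]
            peak = _peak_at(row.chrom, int(row.tss), w,
                            name=f"prom_{tf}_{gene}")
            for ctx in ctxs:
                tf_peaks[ctx][tf].append(peak)
            direct_rows.append((tf, gene, tuple(ctxs)))
    # promoter peaks planted by several TFs on one gene would share a region;
    # gene draws above are without replacement, so regions stay one-TF
    for tf, gene, ctxs in direct_rows:
        row = gene_info[gene]
        peak = _peak_at(row.chrom, int(row.tss), w)
        flags = [t == tf for t in TFS]
        for ctx in ctxs:
            cobind_rows.append((ctx, row.chrom, peak.start, peak.end, *flags))

    peaks_out = {
        ctx: {tf: IntervalSet(ivs, label=f"{tf}/{ctx}")
              for tf, ivs in tf_peaks[ctx].items()}
        for ctx in CONTEXTS
    }
    ac_out = {ctx: IntervalSet(h3k27ac[ctx], label=f"H3K27ac/{ctx}")
              for ctx in CONTEXTS}
    me3_out = {ctx: IntervalSet(h3k27me3[ctx], label=f"H3K27me3/{ctx}")
               for ctx in CONTEXTS}

    # --- independent geometry scan -> planted target modes
    def scan_mode(tf: str, ctx: str, gene: str) -> str:
        row = gene_info[gene]
        tss = int(row.tss)
        pw = config.promoter_window
        plist = peaks_out[ctx][tf]
        for p in plist:
            if p.chrom == row.chrom and p.start < tss + pw and p.end > tss - pw:
                return "direct"
        tad = tads.containing(row.chrom, tss)
        if tad is None:
            return "indirect"
        for p in plist:
            if p.chrom == tad.chrom and p.start < tad.end and p.end > tad.start:
                return "putative"
        return "indirect"

    target_rows = []
    effect = config.deg_effect_log2fc
    for tf in TFS:
        mine_direct = [(g, cs) for t, g, cs in direct_rows if t == tf]
        for ctx in CONTEXTS:
            chosen: list[tuple[str, str]] = []
            for gene, ctxs in mine_direct:
                if ctx in ctxs:
                    chosen.append((gene, scan_mode(tf, ctx, gene)))
            # pick putative / indirect genes from the realized geometry
            need = {"putative": config.n_putative_targets,
                    "indirect": config.n_indirect_targets}
            for gene in non_tf_genes:
                if all(v <= 0 for v in need.values()):
                    break
                if any(g == gene for g, _ in chosen):
                    continue
                if any(r[0] == tf and r[1] == gene and r[2] == ctx
                       for r in target_rows):
                    continue
                m = scan_mode(tf, ctx, gene)
                if m in need and need[m] > 0:
                    chosen.append((gene, m))
                    need[m] -= 1
            for gene, mode in chosen:
                sign = "up" if rng.random() < 0.5 else "down"
                delta = effect if sign == "up" else -effect
                target_rows.append(
                    (tf, gene, ctx, mode, sign, delta + config.global_shift)
                )

    # --- planted circuit: cross-regulation among the TF genes + self-knockdown
    circuit_rows = []
    for regulator, target, ctx, sign in DEFAULT_CIRCUIT:
        circuit_rows.append((regulator, target, ctx, sign))
    for tf in TFS:
        for ctx in CONTEXTS:
            circuit_rows.append((tf, tf, ctx, "activates"))
    for regulator, target, ctx, sign in circuit_rows:
        direction = "down" if sign == "activates" else "up"
        delta = -effect if direction == "down" else effect
        target_rows.append(
            (regulator, target, ctx, scan_mode(regulator, ctx, target),
             direction, delta + config.global_shift)
        )

    truth = SyntheticTruth(
        planted_superenhancers={ctx: IntervalSet(se_truth[ctx])
                                for ctx in CONTEXTS},
        planted_supermethylated={ctx: IntervalSet(sm_truth[ctx])
                                 for ctx in CONTEXTS},
        planted_cobinding=pd.DataFrame(
            cobind_rows, columns=["context", "chrom", "start", "end", *TFS]
        ),
        planted_targets=pd.DataFrame(
            target_rows,
            columns=["tf", "gene", "context", "mode", "sign",
                     "expected_log2fc"],
        ),
        planted_circuit=pd.DataFrame(
            circuit_rows, columns=["regulator", "target", "context", "sign"]
        ),
        planted_clusters={},
        global_shift=config.global_shift,
    )
    return peaks_out, ac_out, me3_out, truth


def h3k27ac_tracks(h3k27ac: Mapping[str, IntervalSet]) -> dict[str, SignalTrack]:
    """Step-function signal tracks matching the H3K27ac peak calls."""
    tracks = {}
    for ctx, peaks in h3k27ac.items():
        by: dict[str, list[tuple[int, int, float]]] = {}
        for iv in peaks:
            by.setdefault(iv.chrom, []).append(
                (iv.start, iv.end, float(iv.signal or 0.0))
            )
        segments = {}
        for chrom, rows in by.items():
            rows.sort()
            arr = np.asarray(rows)
            segments[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        tracks[ctx] = SignalTrack(segments)
    return tracks


def simulate_loops(
    config: SimulationConfig,
    layout: GenomeLayout,
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    h3k27ac: Mapping[str, IntervalSet],
) -> dict[str, list[tuple[GenomicInterval, GenomicInterval]]]:
    """Hi-C loops: every planted super-enhancer gets a loop from one of its
    constituents to a gene TSS on the same chromosome, plus random
    background loops."""
    rng = np.random.default_rng([config.seed, 31])
    loops: dict[str, list[tuple[GenomicInterval, GenomicInterval]]] = {}
    for ctx in CONTEXTS:
        out = []
        for se in truth.planted_superenhancers[ctx]:
            a = GenomicInterval(se.chrom, se.start, se.start + config.peak_width)
            same = genes[genes["chrom"] == se.chrom]
            row = same.iloc[int(rng.integers(len(same)))]
            tss = int(row["tss"])
            b = GenomicInterval(se.chrom, max(0, tss - 500), tss + 500)
            out.append((a, b))
        for _ in range(10):
            chrom = layout.chrom_names[int(rng.integers(config.n_chroms))]
            L = layout.length_of(chrom)
            s1 = int(rng.integers(0, L - 1000))
            s2 = int(rng.integers(0, L - 1000))
            out.append(
                (GenomicInterval(chrom, s1, s1 + 1000),
                 GenomicInterval(chrom, s2, s2 + 1000))
            )
        loops[ctx] = out
    return loops


# ---------------------------------------------------------------------------
# knockdown counts
# ---------------------------------------------------------------------------

def simulate_knockdown_counts(
    config: SimulationConfig,
    genes: pd.DataFrame,
    truth: SyntheticTruth,
) -> dict[str, CountMatrix]:
    """Knockdown RNA-seq count matrices, one per cell line.

    Baseline log2 expression per gene is an integer (so noise-free counts
    are exact powers of two); planted targets shift by their planted effect
    in the matching siRNA condition of both cell lines of their context;
    spike-in rows share one baseline across all samples; gene rows of
    knockdown samples are multiplied by ``2**global_shift``.
    """
    config.validate()
    if len(truth.planted_targets) == 0:
        raise ValueError("truth contains no planted targets")
    rng = np.random.default_rng([config.seed, 47])
    gene_ids = [str(g) for g in genes["gene_id"]]
    spike_ids = [f"ERCC-{i:05d}" for i in range(1, config.n_spikeins + 1)]
    all_ids = gene_ids + spike_ids
    n_genes = len(gene_ids)

    lengths = np.concatenate([
        genes["length"].to_numpy(dtype=np.int64),
        rng.choice([500, 1000, 2000, 4000], size=config.n_spikeins),
    ])
    # integer log2 baselines for the per-kb READ RATE, converted to counts
    # via the (power-of-two) lengths: counts stay exact powers of two while
    # every row's TPM floor sits two orders of magnitude above the
    # pseudocount, keeping log-ratio distortion < 0.02
    rate_exp = np.concatenate([
        rng.integers(6, 13, size=n_genes),
        rng.integers(7, 14, size=config.n_spikeins),
    ]).astype(float)
    base = rate_exp + np.log2(lengths / 1000.0)
    gene_meta = pd.DataFrame(
        {"length": lengths,
         "is_spikein": [False] * n_genes + [True] * config.n_spikeins},
        index=pd.Index(all_ids, name="gene_id"),
    )

    # (condition, context) -> per-gene planted log2 shift
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    delta: dict[tuple[str, str], np.ndarray] = {}
    for r in truth.planted_targets.itertuples(index=False):
        key = (f"si{r.tf}", r.context)
        vec = delta.setdefault(key, np.zeros(n_genes))
        if r.gene in gene_pos:
            vec[gene_pos[r.gene]] += (
                float(r.expected_log2fc) - truth.global_shift
            )

    conditions = list(CONTROL_CONDITIONS) + [f"si{tf}" for tf in TFS]
    out: dict[str, CountMatrix] = {}
    for ctx in CONTEXTS:
        for line in CELL_LINES[ctx]:
            cols = {}
            meta_rows = []
            for cond in conditions:
                for rep in range(1, config.n_samples_per_condition + 1):
                    sample = f"{line}_{cond}_r{rep}"
                    log2v = base.copy()
                    if cond.startswith("si"):
                        d = delta.get((cond, ctx))
                        if d is not None:
                            log2v[:n_genes] += d
                        log2v[:n_genes] += config.global_shift
                    if config.noise_sd > 0:
                        log2v = log2v + rng.normal(
                            0.0, config.noise_sd, size=len(log2v)
                        )
                    cols[sample] = np.rint(np.exp2(log2v)).astype(np.int64)
                    meta_rows.append((sample, line, ctx, cond, rep))
            counts = pd.DataFrame(cols, index=pd.Index(all_ids, name="gene_id"))
            sample_meta = pd.DataFrame(
                meta_rows,
                columns=["sample_id", "cell_line", "context", "condition",
                         "replicate"],
            ).set_index("sample_id")
            out[line] = CountMatrix(counts, gene_meta.copy(), sample_meta)
    return out


# ---------------------------------------------------------------------------
# tissue panel / IHC
# ---------------------------------------------------------------------------

PANEL_ARCHETYPES: dict[int, tuple[tuple[str, ...], tuple[float, ...]]] = {
    # cluster id -> (tissues, per-TF mean log2 expression)
    0: (("fallopian_tube", "uterus"), (6.0, 6.5, 6.0, 5.5)),          # all high
    1: (("adrenal_gland", "pancreas"), (5.5, 1.0, 1.0, 1.0)),         # MECOM
    2: (("kidney", "thyroid"), (5.0, 5.0, 1.0, 1.0)),                 # MECOM+PAX8
    3: (("lung", "colon", "stomach"), (1.0, 1.0, 5.5, 1.0)),          # SOX17
    4: (tuple(f"tissue_{i:02d}" for i in range(12)), (1.0,) * 4),      # low
}


def simulate_tissue_panel(
    config: SimulationConfig, n_samples_per_tissue: int = 10
) -> tuple[pd.DataFrame, dict[str, int]]:
    """21-tissue expression panel with one planted co-regulated tissue.

    Tissues follow five archetype profiles; the fallopian tube (and only
    it) additionally carries a shared latent factor loading on all four TFs,
    so it is the planted rank-1 tissue for mean pairwise TF correlation.
    Returns (long table with sample/tissue/TF columns, tissue -> cluster).
    """
    rng = np.random.default_rng([config.seed, 59])
    rows = []
    clusters: dict[str, int] = {}
    for cid, (tissues, means) in PANEL_ARCHETYPES.items():
        for tissue in tissues:
            clusters[tissue] = cid
            for s in range(n_samples_per_tissue):
                latent = rng.normal(0.0, 1.5) if tissue == "fallopian_tube" else 0.0
                vals = [
                    m + latent + rng.normal(0.0, 0.5) for m in means
                ]
                rows.append((f"{tissue}_s{s:02d}", tissue, *vals))
    expr = pd.DataFrame(rows, columns=["sample", "tissue", *TFS])
    return expr, clusters


def simulate_positivity(
    config: SimulationConfig,
) -> pd.DataFrame:
    """IHC positivity-rate table across ovarian histotypes.

    HGSC and fallopian tube samples mostly stain for all four factors;
    mucinous tumors stain weakly (WT1 in particular below the 0.1
    positivity threshold), matching the qualitative pattern the panel
    analysis is meant to expose.
    """
    rng = np.random.default_rng([config.seed, 61])
    spec = {
        "HGSC": (40, (0.7, 0.75, 0.7, 0.65), 0.12),
        "fallopian_tube": (12, (0.35, 0.5, 0.5, 0.2), 0.08),
        "clear_cell": (20, (0.5, 0.6, 0.4, 0.04), 0.05),
        "endometrioid": (15, (0.45, 0.55, 0.35, 0.05), 0.05),
        "mucinous": (9, (0.06, 0.2, 0.05, 0.02), 0.03),
    }
    rows = []
    for histotype, (n, means, sd) in spec.items():
        for s in range(n):
            vals = np.clip(rng.normal(means, sd), 0.0, 1.0)
            rows.append((f"{histotype}_s{s:02d}", histotype, *vals))
    return pd.DataFrame(rows, columns=["sample", "histotype", *TFS])


# ---------------------------------------------------------------------------
# one-call bundle + writer
# ---------------------------------------------------------------------------

def simulate_all(config: Optional[SimulationConfig] = None) -> SyntheticDataset:
    config = config or SimulationConfig()
    layout, genes, tads = simulate_genome(config)
    tf_peaks, h3k27ac, h3k27me3, truth = simulate_cistromes(
        config, layout, genes, tads
    )
    loops = simulate_loops(config, layout, genes, truth, h3k27ac)
    counts = simulate_knockdown_counts(config, genes, truth)
    _, clusters = simulate_tissue_panel(config)
    truth.planted_clusters = clusters
    return SyntheticDataset(
        config=config,
        layout=layout,
        genes=genes,
        tads=tads,
        tf_peaks=tf_peaks,
        h3k27ac=h3k27ac,
        h3k27me3=h3k27me3,
        h3k27ac_track=h3k27ac_tracks(h3k27ac),
        loops=loops,
        counts=counts,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write every simulated artifact in the same plain-text formats the
    real pipeline reads (BED/bedGraph/BEDPE/TSV) plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "genome.tsv").open("w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in ds.layout.chrom_names:
            fh.write(f"{chrom}\t{ds.layout.length_of(chrom)}\n")
    write_gene_models(ds.genes, outdir / "genes.tsv")
    write_tads(ds.tads, outdir / "tads.tsv")
    for ctx in CONTEXTS:
        for tf in TFS:
            write_bed(ds.tf_peaks[ctx][tf],
                      outdir / f"peaks_{tf}_{ctx}.bed")
        write_bed(ds.h3k27ac[ctx], outdir / f"h3k27ac_{ctx}.bed")
        write_bed(ds.h3k27me3[ctx], outdir / f"h3k27me3_{ctx}.bed")
        write_bedgraph(ds.h3k27ac_track[ctx],
                       outdir / f"h3k27ac_{ctx}.bedgraph")
        write_bedpe(ds.loops[ctx], outdir / f"loops_{ctx}.bedpe")
    for line, cm in ds.counts.items():
        cm.write(
            outdir / f"counts_{line}.tsv",
            outdir / f"gene_meta_{line}.tsv",
            outdir / f"samples_{line}.tsv",
        )
    expr, _ = simulate_tissue_panel(ds.config)
    expr.to_csv(outdir / "tissue_panel.tsv", sep="\t", index=False)
    simulate_positivity(ds.config).to_csv(
        outdir / "ihc_positivity.tsv", sep="\t", index=False
    )
    ds.truth.to_json(outdir / "truth.json")
    (outdir / "sim_config.json").write_text(
        json.dumps(asdict(ds.config), indent=1, sort_keys=True)
    )
    return outdir
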