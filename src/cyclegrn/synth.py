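"""Synthetic GRN collections, phase labels and cyclic expression.

The generator emulates the statistical structure that the downstream
analyses assume about real regulatory data: several TF→target edge lists
over a shared gene universe whose pairwise interaction overlap is tunable
(real assay types agree on only a small fraction of interactions),
heavy-tailed per-TF out-degrees, planted feed-forward loops, a five-phase
cell-cycle labeling, sinusoidal two-cycle expression with phase-offset
peaks normalized to [0, 1], and a plantable TF→phase association so that
classifiers have recoverable structure with known ground truth.

Overlap between datasets is induced by a per-TF "core" target pool shared
by all datasets; the shared fraction is solved from the requested overlap
coefficient, accounting for chance collisions among the non-core draws, so
that the expected realized overlap coefficient equals the target.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classify import NO_PHASE, PHASES, PhaseLabelSet
from .dynamics import ODEFFLModel, SinusoidForcing, solve
from .grn import GRN, write_edge_list
from .motifs import FFL

logger = logging.getLogger(__name__)


def stage_seed(root: int, stage: str) -> int:
    """Deterministic sub-seed for a named generation stage."""
    return (int(root) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic data collection.

    Defaults describe a desk-scale regime with the proportions of the real
    system: a few dozen TFs with heavy-tailed (geometric) out-degrees, a
    low pairwise interaction overlap between datasets, ~13% of genes
    cyclic with G1 the largest phase class, and a 125-minute cycle sampled
    over two periods.
    """

    n_tfs: int = 50
    n_genes: int = 600
    out_degree_mean: float = 20.0
    n_datasets: int = 3
    pairwise_overlap_target: float = 0.1
    planted_ffl_count: int = 20
    phase_sizes: dict[str, int] = field(default_factory=lambda: {
        "G1": 30, "S": 7, "S-G2": 12, "G2-M": 20, "M-G1": 11})
    n_phase_tfs: int = 10
    tf_phase_effect: float = 0.3
    period_minutes: float = 125.0
    n_timepoints: int = 50
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if sum(self.phase_sizes.values()) > self.n_genes:
            raise ValueError("phase_sizes total exceeds the gene universe")
        unknown = set(self.phase_sizes) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases in phase_sizes: {sorted(unknown)}")
        if not (0.0 <= self.pairwise_overlap_target <= 1.0):
            raise ValueError("pairwise_overlap_target must lie in [0, 1]")
        if self.period_minutes <= 0 or self.noise_sd < 0:
            raise ValueError("period must be > 0 and noise_sd ≥ 0")

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def universe(self) -> list[str]:
        return self.tf_names + self.gene_names


@dataclass
class SynthTruth:
    """Ground truth recorded alongside a generated collection."""

    tf_phase_map: dict[str, str] = field(default_factory=dict)
    planted_ffls: list[FFL] = field(default_factory=list)
    true_ode_params: dict[tuple[str, str, str], dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GRN collection

def _solve_core_fraction(degrees: np.ndarray, pool_size: int,
                         target: float) -> float:
    """Shared-core fraction x such that the expected overlap coefficient of
    any dataset pair equals ``target``.

    Per TF with degree d and core c = x·d, the expected pairwise overlap is
    c + (d−c)²/(P−c) (shared core plus chance collisions among the non-core
    draws from the remaining pool). Solved globally over the degree draws.
    """
    d = degrees.astype(float)
    total = d.sum()

    def gap(x):
        c = x * d
        return float(np.sum(c + (d - c) ** 2 / (pool_size - c)) - target * total)

    if gap(0.0) > 0:
        raise ValueError(
            "pairwise_overlap_target is below the chance overlap implied by "
            "the degree distribution; increase the target or the universe"
        )
    if target >= 1.0:
        return 1.0
    return brentq(gap, 0.0, 1.0, xtol=1e-12)


def generate_grn_collection(config: SynthConfig
                            ) -> tuple[list[GRN], SynthTruth]:
    """n_datasets GRNs over a shared universe, plus ground truth.

    Per-TF out-degrees are geometric with the configured mean and shared
    across datasets; each TF's target set is a shared core plus
    dataset-specific uniform draws, calibrated so the expected pairwise
    interaction overlap coefficient equals ``pairwise_overlap_target``.
    Planted FFL triplets are added to every dataset and recorded.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "grn"))
    tfs = config.tf_names
    universe = np.array(config.universe)
    pool_size = len(universe) - 1  # a TF never targets itself here

    p = 1.0 / max(config.out_degree_mean, 1.0)
    degrees = np.minimum(rng.geometric(p, size=config.n_tfs), pool_size)

    if config.n_datasets > 1:
        x = _solve_core_fraction(degrees, pool_size,
                                 config.pairwise_overlap_target)
    else:
        x = 0.0

    edge_sets: list[set[tuple[str, str]]] = [set() for _ in range(config.n_datasets)]
    for i, tf in enumerate(tfs):
        d = int(degrees[i])
        pool = universe[universe != tf]
        # randomized rounding keeps the expected core size exactly x·d
        cf = x * d
        c = int(math.floor(cf)) + int(rng.random() < (cf - math.floor(cf)))
        c = min(c, d)
        core_idx = rng.choice(len(pool), size=c, replace=False)
        core = pool[core_idx]
        rest = np.delete(pool, core_idx)
        for ds in range(config.n_datasets):
            extra = rng.choice(len(rest), size=d - c, replace=False)
            for tg in core:
                edge_sets[ds].add((tf, str(tg)))
            for tg in rest[extra]:
                edge_sets[ds].add((tf, str(tg)))

    truth = SynthTruth()
    if config.planted_ffl_count > 0:
        genes = config.gene_names
        seen: set[tuple[str, str, str]] = set()
        while len(truth.planted_ffls) < config.planted_ffl_count:
            pi, si = rng.choice(config.n_tfs, size=2, replace=False)
            t = genes[int(rng.integers(len(genes)))]
            trip = (tfs[int(pi)], tfs[int(si)], t)
            if trip in seen:
                continue
            seen.add(trip)
            truth.planted_ffls.append(FFL(*trip))
            params = {
                "alpha_S": float(-rng.uniform(0.02, 0.15)),
                "alpha_T": float(-rng.uniform(0.02, 0.15)),
                "beta_ST": float(rng.uniform(0.02, 0.1)),
                "beta_PS": float(rng.uniform(0.02, 0.1)),
                "beta_PT": float(rng.uniform(0.02, 0.1)),
            }
            truth.true_ode_params[trip] = params
            for ds in range(config.n_datasets):
                edge_sets[ds].update({(trip[0], trip[1]), (trip[0], trip[2]),
                                      (trip[1], trip[2])})

    grns = [GRN(name=f"synth{ds + 1}", interactions=frozenset(edges))
            for ds, edges in enumerate(edge_sets)]
    return grns, truth


# ---------------------------------------------------------------------------
# labels and expression

def generate_phase_labels(config: SynthConfig) -> PhaseLabelSet:
    """Assign exactly phase_sizes[p] genes to each phase, the rest to none.

    Only non-TF genes receive phase labels; TF→phase associations live in
    SynthTruth.tf_phase_map instead.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "labels"))
    genes = list(config.gene_names)
    perm = rng.permutation(len(genes))
    assignment = {g: NO_PHASE for g in config.universe}
    pos = 0
    for phase in PHASES:
        k = config.phase_sizes.get(phase, 0)
        for i in perm[pos:pos + k]:
            assignment[genes[i]] = phase
        pos += k
    return PhaseLabelSet(assignment)


def phase_offset(phase: str, period: float) -> float:
    """Peak-time offset of a phase: consecutive phases peak period/5 apart."""
    return PHASES.index(phase) * period / len(PHASES)


def _normalize(trace: np.ndarray) -> np.ndarray:
    span = trace.max() - trace.min()
    if span == 0:
        return trace
    return (trace - trace.min()) / span


def generate_expression(labels: PhaseLabelSet, config: SynthConfig,
                        tf_phase_map: dict[str, str] | None = None
                        ) -> pd.DataFrame:
    """Gene × time expression matrix over two cell-cycle periods.

    Cyclic genes follow a cosine peaking at their phase offset (and again
    one period later) plus Gaussian noise; non-cyclic genes are noise
    around a constant. Every non-constant trace is min-max normalized to
    [0, 1]. Columns are times in minutes.
    """
    if config.n_timepoints < 4:
        raise ValueError("need at least 4 timepoints to resolve a cycle")
    rng = np.random.default_rng(stage_seed(config.seed, "expression"))
    times = np.linspace(0.0, 2.0 * config.period_minutes, config.n_timepoints)
    tf_phase_map = tf_phase_map or {}
    rows = {}
    for gene in sorted(labels.assignment):
        phase = labels.assignment[gene]
        if phase == NO_PHASE:
            phase = tf_phase_map.get(gene, NO_PHASE)
        if phase == NO_PHASE:
            base = np.full_like(times, 0.5)
        else:
            off = phase_offset(phase, config.period_minutes)
            base = 0.5 + 0.5 * np.cos(
                2.0 * math.pi * (times - off) / config.period_minutes)
        trace = base + rng.normal(0.0, config.noise_sd, size=times.shape)
        rows[gene] = _normalize(trace)
    return pd.DataFrame.from_dict(rows, orient="index", columns=times)


# ---------------------------------------------------------------------------
# planted TF→phase signal

def plant_tf_phase_signal(grns: list[GRN], labels: PhaseLabelSet,
                          config: SynthConfig,
                          truth: SynthTruth | None = None
                          ) -> tuple[list[GRN], SynthTruth]:
    """Link TFs to phases and boost their targeting of in-phase genes.

    The first ``n_phase_tfs`` TFs (rotating through the phases) become
    phase-linked; each gene of a linked TF's phase gains an edge from that
    TF with probability ``tf_phase_effect`` in every dataset, on top of the
    background edges already present. The association is recorded as truth.
    """
    truth = truth or SynthTruth()
    rng = np.random.default_rng(stage_seed(config.seed, "phase-signal"))
    effect = config.tf_phase_effect
    if effect > 1.0:
        logger.warning("tf_phase_effect %.3f clipped to 1", effect)
        effect = 1.0
    tfs = config.tf_names
    if not truth.tf_phase_map:
        for i in range(min(config.n_phase_tfs, len(tfs))):
            truth.tf_phase_map[tfs[i]] = PHASES[i % len(PHASES)]
    new_grns = []
    for grn in grns:
        edges = set(grn.interactions)
        for tf, phase in sorted(truth.tf_phase_map.items()):
            for gene in sorted(labels.genes_of(phase)):
                if rng.random() < effect:
                    edges.add((tf, gene))
        new_grns.append(GRN(name=grn.name, interactions=frozenset(edges)))
    return new_grns, truth


# ---------------------------------------------------------------------------
# FFL time courses

def simulate_ffl_timecourses(params: dict | ODEFFLModel,
                             forcing_spec: SinusoidForcing,
                             times, noise_sd: float, seed: int
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Primary, secondary and target traces for one FFL.

    The primary trace is the forcing f(t) itself; secondary and target are
    the ODE solution plus Gaussian noise.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if isinstance(params, ODEFFLModel):
        model = ODEFFLModel(params.alpha_S, params.alpha_T, params.beta_ST,
                            params.beta_PS, params.beta_PT,
                            forcing=forcing_spec, S0=params.S0, T0=params.T0)
    else:
        model = ODEFFLModel(forcing=forcing_spec, **params)
    S, T = solve(model, times)
    rng = np.random.default_rng(seed)
    primary = np.asarray(forcing_spec(times), dtype=float)
    S = S + rng.normal(0.0, noise_sd, size=times.shape)
    T = T + rng.normal(0.0, noise_sd, size=times.shape)
    return primary, S, T


# ---------------------------------------------------------------------------
# collection generation and serialization

@dataclass
class SynthCollection:
    config: SynthConfig
    grns: list[GRN]
    labels: PhaseLabelSet
    expression: pd.DataFrame
    truth: SynthTruth


def generate_collection(config: SynthConfig) -> SynthCollection:
    """Full generation pipeline: GRNs → labels → planted signal → expression."""
    grns, truth = generate_grn_collection(config)
    labels = generate_phase_labels(config)
    grns, truth = plant_tf_phase_signal(grns, labels, config, truth)
    expression = generate_expression(labels, config, truth.tf_phase_map)
    return SynthCollection(config=config, grns=grns, labels=labels,
                           expression=expression, truth=truth)


def write_collection(coll: SynthCollection, outdir) -> None:
    """Serialize a collection: edge-list TSVs, label TSV, expression TSV
    (header row of times in minutes) and a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for grn in coll.grns:
        write_edge_list(grn, outdir / f"edges_{grn.name}.tsv")
    coll.labels.to_tsv(outdir / "labels.tsv")
    expr = coll.expression.copy()
    expr.columns = [f"{t:.6g}" for t in expr.columns]
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    truth = {
        "tf_phase_map": coll.truth.tf_phase_map,
        "planted_ffls": [[f.primary, f.secondary, f.target]
                         for f in coll.truth.planted_ffls],
        "true_ode_params": {"|".join(k): v
                            for k, v in coll.truth.true_ode_params.items()},
        "config": {k: v for k, v in asdict(coll.config).items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1,
                                                  sort_keys=True) + "\n")
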