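"""End-to-end orchestration: simulate/ingest → compare → motifs → classify
→ importance → dynamics → enrichment, from one config with one root seed.

Every stage communicates with the next only through serialized artifacts in
the output directory, and a manifest records the config, derived seeds,
package version and a checksum of every written file, so a rerun with an
identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (CYCLIC, PHASES, SVMEnsembleConfig, SVMEnsemble,
                       PhaseLabelSet, build_feature_matrix)
from .dynamics import random_triplets, validate_ffl_set
from .enrichment import read_annotations, go_enrichment
from .grn import (GRN, interaction_uniqueness, pairwise_overlap,
                  per_tf_degree_correlation, randomized_overlap_null,
                  read_edge_list)
from .importance import (ImportanceTable, build_importance_grn,
                         combine_important_features,
                         known_regulator_enrichment)
from .motifs import enumerate_ffls, expected_ffl_stats, ffl_overlap, write_ffls
from .synth import SynthConfig, generate_collection, stage_seed, write_collection

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "overlap", "motifs", "classify", "importance",
              "dynamics", "enrich")


@dataclass
class PipelineConfig:
    outdir: str = "cyclegrn_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulate: SynthConfig = field(default_factory=SynthConfig)
    edge_lists: dict[str, str] = field(default_factory=dict)  # name → path
    labels_path: str | None = None
    expression_path: str | None = None
    annotations_path: str | None = None
    svm: SVMEnsembleConfig = field(default_factory=SVMEnsembleConfig)
    feature_kinds: tuple[str, ...] = ("tf", "ffl")
    classes: tuple[str, ...] = (CYCLIC,) + PHASES
    percentiles: tuple[float, ...] = (10.0, 25.0)
    n_perm: int = 1000
    max_dynamics_ffls: int = 10
    n_control_triplets: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SynthConfig(**raw.pop("simulate", {}))
        svm = SVMEnsembleConfig(**raw.pop("svm", {}))
        cfg = cls(simulate=sim, svm=svm, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        })
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in order; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    timers: dict[str, float] = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        fn = _STAGES[stage]
        t0 = time.monotonic()
        logger.info("stage %s: starting", stage)
        try:
            fn(config, out, state)
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise StageError(stage, exc) from exc
        timers[stage] = round(time.monotonic() - t0, 3)
        logger.info("stage %s: done in %.1fs", stage, timers[stage])

    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "stages": list(config.stages),
        "config": dataclasses.asdict(config),
        "timers_ignore": None,  # timers vary run to run; kept out of checksums
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    manifest.pop("timers_ignore")
    _dump_json(manifest, out / "manifest.json")
    return out


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> None:
    sim = dataclasses.replace(cfg.simulate, seed=stage_seed(cfg.seed, "simulate"))
    coll = generate_collection(sim)
    write_collection(coll, out / "data")
    state["grns"] = coll.grns
    state["labels"] = coll.labels
    state["expression"] = coll.expression
    state["truth"] = coll.truth


def _load_inputs(cfg: PipelineConfig, out: Path, state: dict) -> None:
    """Read stage inputs from serialized artifacts (or configured paths)."""
    if "grns" not in state:
        data_dir = out / "data"
        paths = dict(cfg.edge_lists) or {
            p.stem.removeprefix("edges_"): p
            for p in sorted(data_dir.glob("edges_*.tsv"))
        }
        if not paths:
            raise FileNotFoundError(
                "no edge lists: enable the simulate stage or set edge_lists")
        state["grns"] = [read_edge_list(p, name) for name, p in paths.items()]
    if "labels" not in state:
        path = cfg.labels_path or out / "data" / "labels.tsv"
        if Path(path).exists():
            state["labels"] = PhaseLabelSet.from_tsv(path)
    if "expression" not in state:
        path = cfg.expression_path or out / "data" / "expression.tsv"
        if Path(path).exists():
            df = pd.read_csv(path, sep="\t", index_col=0)
            df.columns = [float(c) for c in df.columns]
            state["expression"] = df


def _stage_overlap(cfg: PipelineConfig, out: Path, state: dict) -> None:
    _load_inputs(cfg, out, state)
    grns: list[GRN] = state["grns"]
    pool = set().union(*(g.targets for g in grns))
    rows = []
    for i in range(len(grns)):
        for j in range(i + 1, len(grns)):
            a, b = grns[i], grns[j]
            stats = randomized_overlap_null(
                a, b, pool, n_perm=cfg.n_perm,
                seed=stage_seed(cfg.seed, f"overlap-{a.name}-{b.name}"))
            try:
                r = per_tf_degree_correlation(a, b)
            except ValueError:
                r = float("nan")
            rows.append({
                "a": a.name, "b": b.name,
                "observed": stats.observed_overlap,
                "coefficient": stats.overlap_coefficient,
                "null_mean": stats.null_mean, "null_sd": stats.null_sd,
                "z": stats.z, "p": stats.p_two_tailed,
                "degree_pcc": r,
            })
    result = {"pairs": rows}
    if len(grns) >= 2:
        uniq = interaction_uniqueness(grns)
        result["union_interactions"] = uniq.n_union
        result["fraction_unique"] = uniq.fraction_unique
        result["fraction_tfs_majority_unique"] = uniq.fraction_tfs_majority_unique
    _dump_json(result, out / "overlap.json")
    state["overlap"] = result


def _stage_motifs(cfg: PipelineConfig, out: Path, state: dict) -> None:
    _load_inputs(cfg, out, state)
    motif_dir = out / "motifs"
    motif_dir.mkdir(exist_ok=True)
    per_grn = {}
    ffl_sets = {}
    for grn in state["grns"]:
        ffls = enumerate_ffls(grn)
        ffl_sets[grn.name] = ffls
        write_ffls(ffls, motif_dir / f"ffls_{grn.name}.tsv")
        ms = expected_ffl_stats(grn, len(ffls))
        per_grn[grn.name] = {
            "observed": ms.observed, "lambda": ms.lam,
            "expected_mean": ms.expected_mean,
            "expected_sd": ms.expected_sd, "z": ms.z,
        }
    result: dict = {"per_grn": per_grn}
    if len(ffl_sets) >= 2:
        uniq, common = ffl_overlap(list(ffl_sets.values()))
        result["ffl_fraction_unique"] = uniq
        result["ffl_common_to_all"] = common
    _dump_json(result, out / "motifs" / "motifs.json")
    state["ffl_sets"] = ffl_sets


def _feature_sources(cfg: PipelineConfig, state: dict, kind: str):
    if kind == "tf":
        return [(g.name, g) for g in state["grns"]]
    if kind == "ffl":
        return [(name, ffls) for name, ffls in state["ffl_sets"].items()]
    raise ValueError(f"unknown feature kind {kind!r}")


def _stage_classify(cfg: PipelineConfig, out: Path, state: dict) -> None:
    _load_inputs(cfg, out, state)
    if "labels" not in state:
        raise FileNotFoundError("no phase labels available for classification")
    if "ffl" in cfg.feature_kinds and "ffl_sets" not in state:
        raise FileNotFoundError("classify needs the motifs stage for FFL features")
    cls_dir = out / "classify"
    cls_dir.mkdir(exist_ok=True)
    results = {}
    auc_rows = []
    for kind in cfg.feature_kinds:
        matrix = build_feature_matrix(_feature_sources(cfg, state, kind))
        for positive in cfg.classes:
            svm_cfg = dataclasses.replace(
                cfg.svm, seed=stage_seed(cfg.seed, f"svm-{kind}-{positive}"))
            key = f"{kind}_{positive}"
            try:
                res = SVMEnsemble(matrix, state["labels"], positive,
                                  svm_cfg).fit()
            except ValueError as exc:
                # a feature kind may cover too few genes of this class
                logger.warning("classify %s: infeasible (%s)", key, exc)
                _dump_json({"positive_class": positive, "kind": kind,
                            "status": "infeasible", "reason": str(exc)},
                           cls_dir / f"{key}.json")
                continue
            results[key] = res
            best_c, best_r = res.best_params
            _dump_json({"positive_class": positive, "kind": kind,
                        "best_C": best_c, "best_R": best_r,
                        "auc": res.best_auc},
                       cls_dir / f"{key}.json")
            res.feature_weights.rename("weight").to_csv(
                cls_dir / f"{key}_weights.tsv", sep="\t")
            for (c, r), auc in sorted(res.auc_by_params.items()):
                auc_rows.append({"positive_class": positive, "dataset": kind,
                                 "C": c, "R": r, "auc": auc})
    pd.DataFrame(auc_rows).to_csv(cls_dir / "auc_grid.tsv", sep="\t",
                                  index=False)
    state["ensembles"] = results


def _stage_importance(cfg: PipelineConfig, out: Path, state: dict) -> None:
    if "ensembles" not in state:
        raise FileNotFoundError("importance needs the classify stage")
    imp_dir = out / "importance"
    imp_dir.mkdir(exist_ok=True)
    tables = {key: ImportanceTable.from_weights(res.feature_weights)
              for key, res in state["ensembles"].items()}
    for key, tab in tables.items():
        tab.to_frame().to_csv(imp_dir / f"{key}.tsv", sep="\t")
    kind = cfg.feature_kinds[0]
    general = tables.get(f"{kind}_{CYCLIC}")
    summary: dict = {}
    if general is not None:
        phase_tabs = {ph: tables[f"{kind}_{ph}"] for ph in PHASES
                      if f"{kind}_{ph}" in tables}
        net = build_importance_grn(general, phase_tabs)
        net.to_edge_frame().to_csv(imp_dir / "importance_grn_edges.tsv",
                                   sep="\t", index=False)
        summary = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "n_isolated": len(net.isolated_nodes),
            "modules": [sorted(m) for m in net.modules],
            "top10_size": len(general.top10),
            "top25_size": len(general.top25),
        }
    _dump_json(summary, imp_dir / "importance_grn.json")
    state["importance_tables"] = tables


def _stage_dynamics(cfg: PipelineConfig, out: Path, state: dict) -> None:
    _load_inputs(cfg, out, state)
    if "expression" not in state:
        raise FileNotFoundError("dynamics needs an expression matrix")
    if "ffl_sets" not in state:
        raise FileNotFoundError("dynamics needs the motifs stage")
    expr = state["expression"]
    times = np.array([float(c) for c in expr.columns])
    all_ffls = sorted(set().union(*state["ffl_sets"].values()))
    rng = np.random.default_rng(stage_seed(cfg.seed, "dynamics"))
    if len(all_ffls) > cfg.max_dynamics_ffls:
        idx = rng.choice(len(all_ffls), size=cfg.max_dynamics_ffls,
                         replace=False)
        ffls = [all_ffls[i] for i in sorted(idx)]
    else:
        ffls = all_ffls
    val = validate_ffl_set(ffls, expr, times)
    tfs = sorted(set().union(*(g.tfs for g in state["grns"])))
    controls = random_triplets(tfs, list(expr.index), cfg.n_control_triplets,
                               rng, exclude=set(all_ffls))
    ctrl = validate_ffl_set(controls, expr, times)
    rows = [{"primary": k[0], "secondary": k[1], "target": k[2],
             "alpha_S": r.model.alpha_S, "alpha_T": r.model.alpha_T,
             "beta_ST": r.model.beta_ST, "beta_PS": r.model.beta_PS,
             "beta_PT": r.model.beta_PT, "loglik": r.log_likelihood,
             "accepted": r.accepted}
            for k, r in val.results.items()]
    pd.DataFrame(rows).to_csv(out / "dynamics_fits.tsv", sep="\t", index=False)
    _dump_json({
        "n_ffls_fit": val.n_fit,
        "ffl_acceptance_fraction": val.acceptance_fraction,
        "n_controls_fit": ctrl.n_fit,
        "control_acceptance_fraction": ctrl.acceptance_fraction,
    }, out / "dynamics.json")
    state["dynamics"] = {"ffl": val, "control": ctrl}


def _stage_enrich(cfg: PipelineConfig, out: Path, state: dict) -> None:
    if "importance_tables" not in state:
        raise FileNotFoundError("enrich needs the importance stage")
    kind = cfg.feature_kinds[0]
    general = state["importance_tables"].get(f"{kind}_{CYCLIC}")
    universe = {f.split(":", 1)[-1].split("->")[0]
                for f in general.weights.index}
    top_tfs = {f.split(":", 1)[-1].split("->")[0] for f in general.top10}
    result: dict = {}
    truth = state.get("truth")
    if truth is not None and truth.tf_phase_map:
        annotated = set(truth.tf_phase_map) & universe
        if annotated:
            result["known_regulator_p"] = known_regulator_enrichment(
                top_tfs, annotated, universe)
    if cfg.annotations_path:
        ann = read_annotations(cfg.annotations_path)
        res = go_enrichment(top_tfs & universe, universe,
                            {g: t for g, t in ann.items() if g in universe})
        result["terms"] = [
            {"term": r.term, "p": r.p, "p_adjusted": r.p_adjusted,
             "significant": r.significant} for r in res]
    _dump_json(result, out / "enrichment.json")


_STAGES = {
    "simulate": _stage_simulate,
    "overlap": _stage_overlap,
    "motifs": _stage_motifs,
    "classify": _stage_classify,
    "importance": _stage_importance,
    "dynamics": _stage_dynamics,
    "enrich": _stage_enrich,
}
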