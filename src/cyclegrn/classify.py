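"""Balanced-ensemble linear-SVM recovery of cell-cycle expression classes.

Genes are classified as cyclically expressed (in general, or in one of the
five phase classes G1, S, S-G2, G2-M, M-G1) from binary regulatory
features: presence/absence of a TF-target interaction, or membership as the
target of a specific TF→TF feed-forward loop. Because the genome is
overwhelmingly non-cyclic, each model is an ensemble over many
class-balanced training subsets: every subset keeps all positives and draws
R × n_pos negatives at random, genes inside a subset are scored
out-of-fold under k-fold cross-validation, genes outside it by the model
trained on the whole subset, and the per-gene scores averaged over subsets
yield a single AUC-ROC against the full gene set. The (C, R) pair
maximizing that averaged AUC defines the representative model, whose mean
feature weights feed the importance analysis.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .grn import GRN
from .motifs import FFL

logger = logging.getLogger(__name__)

PHASES = ("G1", "S", "S-G2", "G2-M", "M-G1")
NO_PHASE = "none"
CYCLIC = "cyclic"  # the "general" positive class: any non-none phase


@dataclass
class PhaseLabelSet:
    """One cell-cycle phase (or none) per gene."""

    assignment: dict[str, str]

    def __post_init__(self):
        bad = {p for p in self.assignment.values()} - set(PHASES) - {NO_PHASE}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    def genes_of(self, phase: str) -> set[str]:
        if phase == CYCLIC:
            return {g for g, p in self.assignment.items() if p != NO_PHASE}
        return {g for g, p in self.assignment.items() if p == phase}

    def is_positive(self, gene: str, positive_class: str) -> bool:
        p = self.assignment.get(gene, NO_PHASE)
        if positive_class == CYCLIC:
            return p != NO_PHASE
        return p == positive_class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": sorted(self.assignment),
             "phase": [self.assignment[g] for g in sorted(self.assignment)]}
        )

    @classmethod
    def from_tsv(cls, path) -> "PhaseLabelSet":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "phase"],
                         dtype=str, comment="#")
        if df.iloc[0]["gene"].lower() == "gene":
            df = df.iloc[1:]
        return cls(dict(zip(df["gene"], df["phase"])))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# feature matrices

def build_feature_matrix(sources, genes=None, kinds=None) -> pd.DataFrame:
    """Binary gene × feature matrix from GRNs and/or FFL sets.

    Parameters
    ----------
    sources : list of (tag, GRN | set[FFL]) or (tag, source, kind) tuples
        ``tag`` labels the dataset so that identically named features from
        different sources never collide. A GRN contributes one column per
        TF (1 iff the TF targets the gene); an FFL set contributes one
        column per ordered primary→secondary pair (1 iff the gene is the
        target of that FFL).
    genes : iterable, optional
        Restrict rows to these genes (before zero-row filtering).

    Genes with no feature present are dropped (they carry no information
    for any model) and the drop is logged.
    """
    if not sources:
        raise ValueError("no feature sources given")
    columns: dict[str, set[str]] = {}
    for entry in sources:
        tag, src = entry[0], entry[1]
        if isinstance(src, GRN):
            for tf, tg in src.interactions:
                columns.setdefault(f"{tag}:{tf}", set()).add(tg)
        else:
            for f in src:
                columns.setdefault(
                    f"{tag}:{f.primary}->{f.secondary}", set()
                ).add(f.target)
    col_names = sorted(columns)
    if genes is None:
        row_genes = sorted(set().union(*columns.values()))
    else:
        row_genes = sorted(set(genes))
    mat = np.zeros((len(row_genes), len(col_names)), dtype=np.int8)
    gene_idx = {g: i for i, g in enumerate(row_genes)}
    for j, c in enumerate(col_names):
        for g in columns[c]:
            i = gene_idx.get(g)
            if i is not None:
                mat[i, j] = 1
    df = pd.DataFrame(mat, index=row_genes, columns=col_names)
    keep = df.sum(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d genes with no feature present", dropped)
    df = df.loc[keep]
    if df.empty:
        raise ValueError("no gene retains at least one feature")
    return df


# ---------------------------------------------------------------------------
# ensemble configuration / results

@dataclass
class SVMEnsembleConfig:
    c_grid: tuple[float, ...] = (0.01, 0.1, 0.5, 1, 1.5, 2.0)
    r_grid: tuple[float, ...] = (0.25, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4)
    n_balanced_sets: int = 100
    n_folds: int = 10
    seed: int = 0


@dataclass
class EnsembleResult:
    """Representative model of one balanced-ensemble grid search."""

    positive_class: str
    auc_by_params: dict[tuple[float, float], float]
    scores_by_params: dict[tuple[float, float], pd.Series]
    best_params: tuple[float, float]
    best_auc: float
    feature_weights: pd.Series  # mean weight per feature at the best (C, R)
    weights_per_run: np.ndarray  # n_balanced_sets × n_features
    skipped_r: tuple[float, ...] = ()

    @property
    def best_scores(self) -> pd.Series:
        return self.scores_by_params[self.best_params]

    def summary(self) -> str:
        lines = [
            f"Balanced linear-SVM ensemble — positive class: {self.positive_class}",
            "-" * 60,
            f"best (C, R) = {self.best_params}   AUC-ROC = {self.best_auc:.4f}",
            f"grid points evaluated: {len(self.auc_by_params)}"
            + (f"   infeasible R skipped: {self.skipped_r}" if self.skipped_r else ""),
            "",
            "top features by mean weight:",
        ]
        top = self.feature_weights.sort_values(ascending=False).head(10)
        for name, w in top.items():
            lines.append(f"  {name:<30s} {w: .4f}")
        return "\n".join(lines)


def make_training_sets(labels: PhaseLabelSet, genes, positive_class: str,
                       R: float, n_sets: int, seed: int) -> list[np.ndarray]:
    """Index subsets: all positives plus round(R × n_pos) random negatives.

    Negatives are drawn uniformly without replacement, independently per
    subset; an infeasible R (more negatives requested than exist) raises.
    """
    genes = list(genes)
    y = np.array([labels.is_positive(g, positive_class) for g in genes])
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) < 5 or len(neg_idx) < 5:
        raise ValueError("need at least 5 positives and 5 negatives")
    n_neg = int(round(R * len(pos_idx)))
    if n_neg > len(neg_idx):
        raise ValueError(
            f"R={R} requires {n_neg} negatives but only {len(neg_idx)} are "
            "available; use a smaller R"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        chosen = rng.choice(neg_idx, size=n_neg, replace=False)
        sets.append(np.sort(np.concatenate([pos_idx, chosen])))
    return sets


def train_linear_svm(X, y, C: float, tol: float = 1e-6
                     ) -> tuple[np.ndarray, float]:
    """L2-regularized hinge-loss linear classifier; returns (weights, bias).

    The decision score of a sample x is w·x + b. Solved as the standard
    soft-margin SVM quadratic program.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def auc_roc(scores, labels) -> float:
    """AUC-ROC via the Mann-Whitney formulation with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


class SVMEnsemble:
    """Balanced-subsample linear-SVM ensemble over a (C, R) grid.

    statsmodels-style model object: construct from a feature matrix and
    labels, then call :meth:`fit` to obtain an :class:`EnsembleResult`.
    """

    def __init__(self, matrix: pd.DataFrame, labels: PhaseLabelSet,
                 positive_class: str = CYCLIC,
                 config: SVMEnsembleConfig | None = None):
        self.matrix = matrix
        self.labels = labels
        self.positive_class = positive_class
        self.config = config or SVMEnsembleConfig()
        self.genes = list(matrix.index)
        self.y = np.array(
            [labels.is_positive(g, positive_class) for g in self.genes]
        )
        if self.y.sum() < 5 or (~self.y).sum() < 5:
            raise ValueError("need at least 5 positives and 5 negatives "
                             "among genes with features")

    # -- internal ----------------------------------------------------------
    def _fold_assignment(self, subset: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
        """Stratified fold labels inside a training subset."""
        k = self.config.n_folds
        folds = np.empty(len(subset), dtype=int)
        for cls in (True, False):
            idx = np.flatnonzero(self.y[subset] == cls)
            perm = rng.permutation(idx)
            folds[perm] = np.arange(len(perm)) % k
        return folds

    def _score_subset(self, X: np.ndarray, subset: np.ndarray, C: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, float]:
        """Per-gene scores from one balanced subset.

        Genes inside the subset are scored out-of-fold; genes outside are
        scored by the model trained on the full subset, whose weights are
        also returned.
        """
        scores = np.empty(len(self.genes))
        folds = self._fold_assignment(subset, rng)
        for k in range(self.config.n_folds):
            test = subset[folds == k]
            train = subset[folds != k]
            if len(test) == 0:
                continue
            if len(np.unique(self.y[train])) < 2:
                # tiny subsets can produce a one-class fold; score at 0
                scores[test] = 0.0
                continue
            w, b = train_linear_svm(X[train], self.y[train], C)
            scores[test] = X[test] @ w + b
        w_full, b_full = train_linear_svm(X[subset], self.y[subset], C)
        outside = np.setdiff1d(np.arange(len(self.genes)), subset,
                               assume_unique=False)
        scores[outside] = X[outside] @ w_full + b_full
        return scores, w_full, b_full

    # -- public ------------------------------------------------------------
    def fit(self) -> EnsembleResult:
        cfg = self.config
        X = self.matrix.to_numpy(dtype=float)
        n_pos = int(self.y.sum())
        n_neg = int((~self.y).sum())
        auc_by: dict[tuple[float, float], float] = {}
        scores_by: dict[tuple[float, float], pd.Series] = {}
        weights_by: dict[tuple[float, float], np.ndarray] = {}
        skipped: list[float] = []
        for R in cfg.r_grid:
            if int(round(R * n_pos)) > n_neg:
                warnings.warn(f"R={R} infeasible ({n_pos} positives, "
                              f"{n_neg} negatives); skipped")
                skipped.append(R)
                continue
            # same balanced subsets for every C at this R
            sets = make_training_sets(self.labels, self.genes,
                                      self.positive_class, R,
                                      cfg.n_balanced_sets,
                                      seed=_sub_seed(cfg.seed, f"sets-R{R}"))
            for C in cfg.c_grid:
                rng = np.random.default_rng(
                    _sub_seed(cfg.seed, f"folds-C{C}-R{R}"))
                all_scores = np.zeros(len(self.genes))
                run_weights = np.empty((len(sets), X.shape[1]))
                for i, subset in enumerate(sets):
                    s, w, _ = self._score_subset(X, subset, C, rng)
                    all_scores += s
                    run_weights[i] = w
                all_scores /= len(sets)
                auc = auc_roc(all_scores, self.y)
                auc_by[(C, R)] = auc
                scores_by[(C, R)] = pd.Series(all_scores, index=self.genes)
                weights_by[(C, R)] = run_weights
        if not auc_by:
            raise ValueError("every R in the grid was infeasible")
        # ties broken toward the more regular model: smaller C, then smaller R
        best = min(auc_by, key=lambda cr: (-auc_by[cr], cr[0], cr[1]))
        run_weights = weights_by[best]
        mean_w = pd.Series(run_weights.mean(axis=0),
                           index=list(self.matrix.columns))
        return EnsembleResult(
            positive_class=self.positive_class,
            auc_by_params=auc_by,
            scores_by_params=scores_by,
            best_params=best,
            best_auc=auc_by[best],
            feature_weights=mean_w,
            weights_per_run=run_weights,
            skipped_r=tuple(skipped),
        )


def ensemble_evaluate(matrix: pd.DataFrame, labels: PhaseLabelSet,
                      positive_class: str = CYCLIC,
                      config: SVMEnsembleConfig | None = None
                      ) -> EnsembleResult:
    """Functional wrapper around :class:`SVMEnsemble`."""
    return SVMEnsemble(matrix, labels, positive_class, config).fit()


def _sub_seed(root: int, name: str) -> int:
    import zlib

    return (int(root) * 2654435761 + zlib.crc32(name.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# performance ANOVA

def anova_performance(auc_table: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of AUC on class and dataset.

    ``auc_table`` needs columns ``auc`` (response), ``positive_class`` and
    ``dataset`` (categorical factors). Type-I sums of squares with the
    interaction term, suitable for the balanced designs produced by running
    every class × dataset combination.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = auc_table.rename(columns={"positive_class": "cls", "dataset": "ds",
                                   "auc": "score"})
    for col in ("score", "cls", "ds"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in AUC table")
    counts = df.groupby(["cls", "ds"], observed=True).size()
    full = (df["cls"].nunique() * df["ds"].nunique())
    if len(counts) < full:
        have = set(counts.index)
        missing = [cd for cd in itertools.product(df["cls"].unique(),
                                                  df["ds"].unique())
                   if cd not in have]
        raise ValueError(f"empty design cells: {missing}")
    model = ols("score ~ C(cls) + C(ds) + C(cls):C(ds)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # F of a zero-residual fit
        table = sm.stats.anova_lm(model, typ=1)
    return table.rename(index={"C(cls)": "class", "C(ds)": "dataset",
                               "C(cls):C(ds)": "class:dataset"})
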