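import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import cyclegrn as cg
from cyclegrn import classify
from cyclegrn.classify import (CYCLIC, PHASES, SVMEnsemble, SVMEnsembleConfig,
                               PhaseLabelSet)


class TestFeatureMatrix:
    def test_tf_target_hand_construction(self):
        grn = cg.GRN.from_edges("d", [("TF1", "g1"), ("TF2", "g1"),
                                      ("TF1", "g2")])
        m = cg.build_feature_matrix([("d", grn)])
        assert list(m.columns) == ["d:TF1", "d:TF2"]
        assert m.loc["g1"].tolist() == [1, 1]
        assert m.loc["g2"].tolist() == [1, 0]

    def test_uncovered_gene_absent(self):
        grn = cg.GRN.from_edges("d", [("TF1", "g1")])
        m = cg.build_feature_matrix([("d", grn)], genes=["g1", "g9"])
        assert "g9" not in m.index

    def test_ffl_mode_on_two_tf_illustration(self, fig_grn):
        ffls = cg.enumerate_ffls(fig_grn)
        m = cg.build_feature_matrix([("d", ffls)])
        assert list(m.columns) == ["d:TF1->TF2"]
        assert sorted(m.index) == ["Tar2", "Tar3"]
        assert (m.to_numpy() == 1).all()

    def test_all_zero_errors(self):
        grn = cg.GRN.from_edges("d", [("TF1", "g1")])
        with pytest.raises(ValueError):
            cg.build_feature_matrix([("d", grn)], genes=["g7"])


class TestTrainingSets:
    def _labels(self, n_pos=10, n_neg=100):
        ass = {f"p{i}": "G1" for i in range(n_pos)}
        ass.update({f"n{i}": "none" for i in range(n_neg)})
        return PhaseLabelSet(ass), sorted(ass)

    def test_balanced_one_to_one(self):
        labels, genes = self._labels()
        sets = cg.make_training_sets(labels, genes, "G1", R=1, n_sets=10, seed=0)
        assert all(len(s) == 20 for s in sets)

    def test_ratio_scales_negatives(self):
        labels, genes = self._labels()
        sets = cg.make_training_sets(labels, genes, "G1", R=2, n_sets=5, seed=0)
        assert all(len(s) == 30 for s in sets)
        y = np.array([labels.is_positive(genes[i], "G1") for i in sets[0]])
        assert y.sum() == 10

    def test_infeasible_ratio_errors(self):
        labels, genes = self._labels(n_pos=10, n_neg=30)
        with pytest.raises(ValueError, match="smaller R"):
            cg.make_training_sets(labels, genes, "G1", R=4, n_sets=5, seed=0)

    def test_negatives_sampled_without_replacement(self):
        labels, genes = self._labels()
        sets = cg.make_training_sets(labels, genes, "G1", R=3, n_sets=20, seed=1)
        for s in sets:
            assert len(set(s)) == len(s)


class TestLinearSVM:
    def test_separable_sign(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        for C in (0.01, 1.0, 10.0):
            w, b = cg.train_linear_svm(X, y, C)
            assert w[0] > 0

    def test_label_flip_negates_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=30)) > 0
        w1, b1 = cg.train_linear_svm(X, y, 1.0)
        w2, b2 = cg.train_linear_svm(X, ~y, 1.0)
        assert np.allclose(w1, -w2, atol=1e-6)
        assert b1 == pytest.approx(-b2, abs=1e-6)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            cg.train_linear_svm(np.zeros((3, 1)), np.ones(3), 1.0)

    def test_objective_matches_qp_oracle(self):
        # direct minimization of the primal soft-margin objective
        X = np.array([[0.0, 0.0], [1.0, 0.2], [0.1, 1.0], [1.0, 1.0]])
        y = np.array([-1, 1, -1, 1])
        C = 1.0

        def primal(wb):
            w, b = wb[:2], wb[2]
            margins = y * (X @ w + b)
            return 0.5 * w @ w + C * np.clip(1 - margins, 0, None).sum()

        oracle = min(
            minimize(primal, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12,
                              "maxiter": 20000}).fun
            for x0 in ([0, 0, 0], [1, -1, 0], [0.5, 0.5, -0.5]))
        w, b = cg.train_linear_svm(X, (y > 0), C)
        ours = primal(np.array([*w, b]))
        assert ours == pytest.approx(oracle, abs=1e-4)


class TestAUC:
    def test_perfect_ranking(self):
        assert cg.auc_roc([0.1, 0.9, 0.2, 0.8], [0, 1, 0, 1]) == 1.0

    def test_all_tied_scores(self):
        assert cg.auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_counted_pairs(self):
        # pairs: (.9,.8)+, (.9,.3)+, (.4,.8)−, (.4,.3)+ → 3/4
        assert cg.auc_roc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=50)
        y = rng.random(50) > 0.5
        base = cg.auc_roc(s, y)
        assert cg.auc_roc(np.exp(2 * s) + 7, y) == pytest.approx(base)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            cg.auc_roc([1, 2], [1, 1])


def _toy_problem(n_pos=12, n_neg=48, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_pos + n_neg)]
    y = np.array([1] * n_pos + [0] * n_neg)
    X = rng.random((len(genes), 6)) < 0.3
    if signal:
        X[:n_pos, 0] = True
        X[n_pos:, 0] = False
    X[:, 5] |= ~X.any(axis=1)  # keep every row nonzero
    mat = pd.DataFrame(X.astype(int), index=genes,
                       columns=[f"d:TF{j}" for j in range(6)])
    labels = PhaseLabelSet({g: ("G1" if y[i] else "none")
                            for i, g in enumerate(genes)})
    return mat, labels


SMALL = SVMEnsembleConfig(c_grid=(0.1, 1.0), r_grid=(1.0, 2.0),
                          n_balanced_sets=5, n_folds=5, seed=7)


class TestEnsemble:
    def test_recovers_planted_single_feature(self):
        mat, labels = _toy_problem()
        res = cg.ensemble_evaluate(mat, labels, "G1", SMALL)
        assert res.best_auc >= 0.95
        assert res.feature_weights.idxmax() == "d:TF0"

    def test_deterministic_under_seed(self):
        mat, labels = _toy_problem()
        r1 = cg.ensemble_evaluate(mat, labels, "G1", SMALL)
        r2 = cg.ensemble_evaluate(mat, labels, "G1", SMALL)
        assert r1.best_params == r2.best_params
        assert r1.auc_by_params == r2.auc_by_params
        assert np.array_equal(r1.weights_per_run, r2.weights_per_run)

    def test_infeasible_r_skipped_with_warning(self):
        mat, labels = _toy_problem(n_pos=12, n_neg=20)
        cfg = SVMEnsembleConfig(c_grid=(1.0,), r_grid=(1.0, 4.0),
                                n_balanced_sets=3, n_folds=3, seed=0)
        with pytest.warns(UserWarning, match="infeasible"):
            res = cg.ensemble_evaluate(mat, labels, "G1", cfg)
        assert res.skipped_r == (4.0,)

    def test_all_r_infeasible_errors(self):
        mat, labels = _toy_problem(n_pos=20, n_neg=10)
        cfg = SVMEnsembleConfig(c_grid=(1.0,), r_grid=(3.0,),
                                n_balanced_sets=3, n_folds=3, seed=0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                cg.ensemble_evaluate(mat, labels, "G1", cfg)

def test_leakage_guard_by_index(monkeypatch):
    """Every out-of-fold score comes from a model whose training indices
    exclude the scored gene."""
    mat, labels = _toy_problem()
    calls: list[np.ndarray] = []

    def recorder(X, y, C):
        calls.append(X)
        return np.zeros(X.shape[1]), float(len(calls) - 1)

    monkeypatch.setattr(classify, "train_linear_svm", recorder)
    ens = SVMEnsemble(mat, labels, "G1", SMALL)
    X = mat.to_numpy(float)
    # tag every gene row uniquely so training membership is recoverable
    X = X + np.arange(len(X))[:, None] * 1000.0
    subset = np.arange(30)
    scores, _, _ = ens._score_subset(X, subset, 1.0, np.random.default_rng(0))
    full_model = len(calls) - 1
    for gi in subset:
        model_id = int(scores[gi])
        assert model_id != full_model  # inside genes are scored out-of-fold
        row_tags = (calls[model_id][:, 0] // 1000).astype(int)
        assert gi not in row_tags


class TestAnova:
    @staticmethod
    def _table(noise=0.0, seed=0, classes=("a", "b", "c"),
               datasets=("d1", "d2", "d3", "d4", "d5"), reps=2):
        rng = np.random.default_rng(seed)
        rows = []
        for ci, c in enumerate(classes):
            for di, d in enumerate(datasets):
                for _ in range(reps):
                    rows.append({"positive_class": c, "dataset": d,
                                 "auc": 0.5 + 0.05 * ci + 0.02 * di
                                 + noise * rng.normal()})
        return pd.DataFrame(rows)

    def test_constant_response_zero_ss(self):
        df = self._table(classes=("a", "b"), datasets=("d1", "d2"))
        df["auc"] = 0.7
        tab = cg.anova_performance(df)
        assert tab["sum_sq"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_additive_design_has_zero_interaction(self):
        df = self._table(noise=0.0, classes=("a", "b"), datasets=("d1", "d2"))
        tab = cg.anova_performance(df)
        assert tab.loc["class:dataset", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_decomposition_matches_mean_oracle(self):
        df = self._table(noise=0.05, seed=2)
        tab = cg.anova_performance(df)
        # direct mean decomposition for a balanced two-way layout
        g = df["auc"].mean()
        ca = df.groupby("positive_class")["auc"].mean()
        da = df.groupby("dataset")["auc"].mean()
        cell = df.groupby(["positive_class", "dataset"])["auc"].mean()
        n_per = len(df) // (len(ca) * len(da))
        ss_c = n_per * len(da) * ((ca - g) ** 2).sum()
        ss_d = n_per * len(ca) * ((da - g) ** 2).sum()
        ss_int = n_per * sum(
            (cell[c, d] - ca[c] - da[d] + g) ** 2
            for c in ca.index for d in da.index)
        ss_res = sum((row.auc - cell[row.positive_class, row.dataset]) ** 2
                     for row in df.itertuples())
        assert tab.loc["class", "sum_sq"] == pytest.approx(ss_c, abs=1e-10)
        assert tab.loc["dataset", "sum_sq"] == pytest.approx(ss_d, abs=1e-10)
        assert tab.loc["class:dataset", "sum_sq"] == pytest.approx(ss_int, abs=1e-10)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(ss_res, abs=1e-10)
        assert tab["sum_sq"].sum() == pytest.approx(
            ((df["auc"] - g) ** 2).sum(), abs=1e-10)

    def test_empty_cells_named_in_error(self):
        df = self._table(classes=("a", "b"), datasets=("d1", "d2"))
        df = df[~((df["positive_class"] == "a") & (df["dataset"] == "d2"))]
        with pytest.raises(ValueError, match="empty design cells"):
            cg.anova_performance(df)
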