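import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

import spermsnc as s
from spermsnc.errors import ValidationError
from spermsnc.multivariate import LinearSvmModel, PanelMatrix, _auc_mannwhitney


def eigen_pca_oracle(X):
    """Independent oracle: eigendecomposition of the covariance matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(X.shape[0] - 1, X.shape[1])
    vals, vecs = vals[:k], vecs[:, :k]
    for j in range(k):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] *= -1
    scores = Xc @ vecs
    return scores, vecs.T, 100.0 * vals / vals.sum()


class TestPca:
    def test_two_samples_put_everything_on_pc1(self):
        X = np.array([[0.0, 1.0, 2.0], [2.0, 3.0, 1.0]])
        res = s.pca(X)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_variance_sums_to_100(self):
        rng = np.random.default_rng(2)
        res = s.pca(rng.normal(size=(15, 6)))
        assert res.variance_explained.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.variance_explained) <= 1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 5)) @ np.diag([3, 2, 1, 0.5, 0.2])
        res = s.pca(X)
        scores_o, loadings_o, var_o = eigen_pca_oracle(X)
        assert np.allclose(res.scores, scores_o, atol=1e-8)
        assert np.allclose(res.loadings, loadings_o, atol=1e-8)
        assert np.allclose(res.variance_explained, var_o, atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            s.pca(np.ones((4, 3)))

    def test_sign_deterministic_across_runs(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        a, b = s.pca(X), s.pca(X.copy())
        assert np.array_equal(a.scores, b.scores)
        # chosen sign convention: max-|loading| entry positive
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0


def _panel_from_arrays(X, labels):
    return PanelMatrix(X=np.asarray(X, float), samples=[f"s{i}" for i in range(len(X))],
                       features=[f"f{j}" for j in range(np.shape(X)[1])],
                       labels=np.asarray(labels), positive_label="H-GQE")


class TestLinearSvm:
    def test_separable_1d_boundary_between_classes(self):
        X = np.array([[-1.0], [-1.2], [-0.9], [1.0], [1.1], [0.95]])
        labels = np.array(["L-GQE"] * 3 + ["H-GQE"] * 3)
        model = s.train_linear_svm(_panel_from_arrays(X, labels))
        boundary = -model.bias / model.weights[0]
        assert -0.9 < boundary < 0.95
        scores = model.decision_scores(X)
        assert np.all((scores > 0) == (labels == "H-GQE"))

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValidationError):
            s.train_linear_svm(_panel_from_arrays(X, ["H-GQE"] * 4))

    def test_objective_matches_constrained_qp_oracle(self):
        """Primal objective 0.5||w||^2 + C*sum(hinge) agrees with an
        independent SLSQP solution of the slack-variable QP."""
        rng = np.random.default_rng(4)
        n, p, C = 10, 2, 1.0
        X = np.vstack([rng.normal(-0.8, 1, (5, p)), rng.normal(0.8, 1, (5, p))])
        y = np.array([-1.0] * 5 + [1.0] * 5)
        labels = np.where(y > 0, "H-GQE", "L-GQE")
        model = s.train_linear_svm(_panel_from_arrays(X, labels), C=C, tol=1e-9)

        def primal(wb):
            w, b = wb[:p], wb[p]
            margins = 1 - y * (X @ w + b)
            return 0.5 * w @ w + C * np.clip(margins, 0, None).sum()

        ours = primal(np.r_[model.weights, model.bias])

        # oracle: minimize 0.5||w||^2 + C*sum(xi) s.t. xi >= 0, xi >= 1 - y f(x)
        def qp_obj(z):
            w, xi = z[:p], z[p + 1 :]
            return 0.5 * w @ w + C * xi.sum()

        cons = [
            {"type": "ineq", "fun": lambda z, i=i: z[p + 1 + i]} for i in range(n)
        ] + [
            {
                "type": "ineq",
                "fun": lambda z, i=i: z[p + 1 + i]
                - (1 - y[i] * (X[i] @ z[:p] + z[p])),
            }
            for i in range(n)
        ]
        best = None
        for seed in range(3):
            z0 = np.random.default_rng(seed).normal(size=p + 1 + n) * 0.1
            r = minimize(qp_obj, z0, constraints=cons, method="SLSQP",
                         options={"maxiter": 500, "ftol": 1e-12})
            if r.success and (best is None or r.fun < best):
                best = r.fun
        assert best is not None
        assert ours == pytest.approx(best, abs=1e-4)


class TestCrossval:
    def test_separable_panel_scores_correctly_signed(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(-5, 0.3, (8, 3)), rng.normal(5, 0.3, (8, 3))])
        labels = np.array(["L-GQE"] * 8 + ["H-GQE"] * 8)
        scores = s.crossval_scores(_panel_from_arrays(X, labels))
        assert np.all((scores > 0) == (labels == "H-GQE"))

    def test_minimal_n3_returns_three_scores(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [5.0, 5.0]])
        labels = np.array(["L-GQE", "L-GQE", "H-GQE"])
        assert len(s.crossval_scores(_panel_from_arrays(X, labels))) == 3

    def test_label_permutation_gives_chance_auc(self):
        """Out-of-fold AUC on permuted labels averages near 0.5."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 5))
        aucs = []
        for i in range(20):
            perm_rng = np.random.default_rng(100 + i)
            labels = np.array(["H-GQE"] * 10 + ["L-GQE"] * 20)
            perm_rng.shuffle(labels)
            panel = _panel_from_arrays(X, labels)
            scores = s.crossval_scores(panel)
            aucs.append(s.roc_auc(scores, labels).auc)
        assert 0.35 <= np.mean(aucs) <= 0.65


class TestRocAuc:
    def test_perfect_ordering(self):
        labels = np.array(["H-GQE", "H-GQE", "L-GQE", "L-GQE"])
        assert s.roc_auc([4.0, 3.0, 2.0, 1.0], labels).auc == 1.0

    def test_constant_scores_give_half(self):
        labels = np.array(["H-GQE", "H-GQE", "L-GQE", "L-GQE"])
        res = s.roc_auc([1.0] * 4, labels)
        assert res.auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(9)
        labels = np.array(["H-GQE"] * 12 + ["L-GQE"] * 18)
        res = s.roc_auc(rng.normal(size=30), labels)
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_trapezoid_equals_mannwhitney_and_sklearn(self):
        rng = np.random.default_rng(10)
        for trial in range(10):
            labels = np.array(["H-GQE"] * 10 + ["L-GQE"] * 20)
            scores = np.round(rng.normal(size=30), 1)  # induce ties
            res = s.roc_auc(scores, labels)
            assert res.auc == pytest.approx(
                _auc_mannwhitney(scores, (labels == "H-GQE").astype(int)), abs=1e-12
            )
            assert res.auc == pytest.approx(
                roc_auc_score((labels == "H-GQE").astype(int), scores), abs=1e-12
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array(["H-GQE"] * 5 + ["L-GQE"] * 7)
        scores = rng.normal(size=12)
        base = s.roc_auc(scores, labels).auc
        assert s.roc_auc(np.exp(scores), labels).auc == pytest.approx(base)
        assert s.roc_auc(scores**3 + scores, labels).auc == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            s.roc_auc([1.0, 2.0], np.array(["H-GQE", "H-GQE"]))
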