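"""Outcome-weighted learning: residualization, the weighted hinge solver,
and the pooled sequential fit."""
import numpy as np
import pytest

from conftest import history_from_arrays, make_randomized_history
from srat.basis import Basis
from srat.errors import DegenerateProblemError, PositivityError
from srat.owl import (
    DecisionFunction,
    OWLConfig,
    fit_owl,
    fit_weighted_svm,
    load_rule,
    owl_weights,
    predict_rule,
    residualize_rewards,
    save_rule,
    weighted_hinge_objective,
)
from srat.scenarios import optimal_rule, sample_covariates

LINEAR = Basis("linear")


class TestResidualize:
    def test_constant_rewards_vanish(self):
        X = np.random.default_rng(0).uniform(-1, 1, (30, 4))
        res = residualize_rewards(X, np.full(30, 3.7), LINEAR)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_exact_linear_signal_vanishes(self):
        X = np.random.default_rng(1).uniform(-1, 1, (30, 4))
        res = residualize_rewards(X, 3.0 * X[:, 0], LINEAR)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Quadratic signal on a linear basis: residuals equal R minus the
        best linear fit computed from the normal equations directly."""
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, (50, 1))
        R = X[:, 0] ** 2
        res = residualize_rewards(X, R, LINEAR)
        design = np.hstack([np.ones((50, 1)), X])
        coef = np.linalg.solve(design.T @ design, design.T @ R)
        assert np.allclose(res, R - design @ coef, atol=1e-10)
        assert res.mean() == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficient_design_warns(self):
        X = np.ones((10, 2))  # duplicate constant columns
        with pytest.warns(UserWarning, match="rank-deficient"):
            residualize_rewards(X, np.arange(10.0), LINEAR)


class TestWeightedSVM:
    def test_separable_symmetric_instance(self):
        f = fit_weighted_svm(
            np.array([[1.0], [-1.0]]), np.array([1, -1]), np.ones(2), lam=1e-3
        )
        assert f.coef[0] > 0
        assert np.array_equal(f.decide(np.array([[1.0], [-1.0]])), [1, -1])

    def test_duplication_invariance(self):
        """With the 1/n normalization, duplicating every point leaves the
        optimizer unchanged."""
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (15, 3))
        y = rng.choice([-1, 1], 15)
        w = np.abs(rng.normal(1, 1, 15)) + 0.1
        f1 = fit_weighted_svm(X, y, w, lam=0.05, tol=1e-8)
        f2 = fit_weighted_svm(
            np.vstack([X, X]), np.r_[y, y], np.r_[w, w], lam=0.05, tol=1e-8
        )
        o1 = weighted_hinge_objective(f1.intercept, f1.coef, X, y, w, 0.05)
        o2 = weighted_hinge_objective(f2.intercept, f2.coef, X, y, w, 0.05)
        assert o2 == pytest.approx(o1, abs=1e-6)

    def test_matches_libsvm_oracle(self):
        """The SMO solution matches libsvm's SMO (an independent
        implementation of the same dual) in objective value."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(4)
        for _ in range(5):
            n, p = 40, 4
            X = rng.uniform(-1, 1, (n, p))
            y = rng.choice([-1, 1], n)
            w = np.abs(rng.normal(1, 2, n)) + 1e-3
            lam = 0.02
            f = fit_weighted_svm(X, y, w, lam=lam, tol=1e-8)
            mine = weighted_hinge_objective(f.intercept, f.coef, X, y, w, lam)
            clf = SVC(kernel="linear", C=1.0, tol=1e-9)
            clf.fit(X, y, sample_weight=w / (2 * lam * n))
            ref = weighted_hinge_objective(
                clf.intercept_[0], clf.coef_[0], X, y, w, lam
            )
            assert mine <= ref + 1e-6

    def test_degenerate_inputs(self):
        X = np.ones((4, 2))
        with pytest.raises(DegenerateProblemError):
            fit_weighted_svm(X, np.array([1, 1, -1, -1]), np.zeros(4), lam=0.1)
        with pytest.raises(ValueError):
            fit_weighted_svm(X, np.array([1, 1, -1, -1]), -np.ones(4), lam=0.1)
        with pytest.warns(UserWarning, match="one label class"):
            f = fit_weighted_svm(
                X, np.array([1, 1, -1, -1]), np.array([1.0, 1, 0, 0]), lam=0.1
            )
        assert np.all(f.decide(np.random.uniform(-1, 1, (5, 2))) == 1)

    def test_scale_equivariance(self):
        """Multiplying rewards (weights) by c and lam by c leaves the
        decision boundary unchanged."""
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (40, 3))
        y = rng.choice([-1, 1], 40)
        w = np.abs(rng.normal(1, 1, 40)) + 0.1
        f1 = fit_weighted_svm(X, y, w, lam=0.05, tol=1e-9)
        f2 = fit_weighted_svm(X, y, 7.0 * w, lam=7.0 * 0.05, tol=1e-9)
        grid = rng.uniform(-1, 1, (200, 3))
        assert np.array_equal(f1.decide(grid), f2.decide(grid))


class TestFitOWL:
    def test_separable_rule_recovered(self, spec1):
        """R = 1, pi = 0.5, A = sign(x1): the weighted classification
        problem is separable and the fit classifies the training arms."""
        rng = np.random.default_rng(6)
        X = sample_covariates(60, spec1, rng)
        A = np.where(X[:, 0] >= 0, 1, -1)
        hist = history_from_arrays(X, A, np.ones(60), 0.5)
        # small lam: the hinge term dominates and the separable instance
        # is classified exactly
        f = fit_owl(hist, OWLConfig(residualize=False, tol=1e-8, lam=1e-5))
        assert np.array_equal(f.decide(X), A)

    def test_flip_invariance(self, spec1):
        """Negating rewards and arms simultaneously gives the same fit."""
        rng = np.random.default_rng(7)
        X = sample_covariates(40, spec1, rng)
        A = rng.choice([-1, 1], 40)
        R = rng.normal(0, 1, 40)
        h1 = history_from_arrays(X, A, R, 0.5)
        h2 = history_from_arrays(X, -A, -R, 0.5)
        f1 = fit_owl(h1, OWLConfig(residualize=False, tol=1e-8))
        f2 = fit_owl(h2, OWLConfig(residualize=False, tol=1e-8))
        assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-6)

    def test_pilot_only_structural_identity(self, spec1):
        """With an empty main segment the pooled objective reduces to the
        pilot-only fit: fit_owl equals fit_weighted_svm on pilot weights."""
        rng = np.random.default_rng(8)
        hist = make_randomized_history(spec1, 30, rng)
        cfg = OWLConfig(residualize=False, tol=1e-8, lam=1.0 / 30)
        f1 = fit_owl(hist, cfg)
        weights, labels = owl_weights(hist.R, hist.propensity, hist.A)
        f2 = fit_weighted_svm(hist.X, labels, weights, lam=1.0 / 30, tol=1e-8)
        assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-8)

    def test_positivity_enforced(self, spec1):
        with pytest.raises(PositivityError):
            owl_weights(np.ones(3), np.array([0.5, 1.0, 0.5]), np.ones(3))

    def test_fisher_consistency_smoke(self, spec1):
        """Under pure randomization with residualization, the fitted rule
        approaches the optimal rule: high agreement at n = 2000 on a fresh
        sample, and higher still at n = 8000."""
        agreements = {}
        for n in (2000, 8000):
            vals = []
            for seed in (1, 2, 3):
                rng = np.random.default_rng(seed)
                hist = make_randomized_history(spec1, n, rng)
                f = fit_owl(hist, OWLConfig(residualize=True, tol=1e-4))
                X_new = sample_covariates(20_000, spec1, rng)
                vals.append(np.mean(f.decide(X_new) == optimal_rule(X_new, spec1)))
            agreements[n] = np.mean(vals)
        assert agreements[2000] > 0.90
        assert agreements[8000] > agreements[2000]


class TestPredictRule:
    def test_sign_conventions(self):
        zero = DecisionFunction(LINEAR, intercept=0.0, coef=np.zeros(3))
        neg = DecisionFunction(LINEAR, intercept=-1.0, coef=np.zeros(3))
        X = np.random.default_rng(10).uniform(-1, 1, (20, 3))
        assert np.all(predict_rule(zero, X) == 1)
        assert np.all(predict_rule(neg, X) == -1)

    def test_matching_hyperplane_reproduces_optimal_rule(self, spec1):
        """Coefficients (0.2, -1, -1, 0...) on the linear basis define the
        scenario-1 optimal separating hyperplane."""
        coef = np.zeros(10)
        coef[:2] = -1.0
        f = DecisionFunction(LINEAR, intercept=0.2, coef=coef)
        X = sample_covariates(5000, spec1, np.random.default_rng(11))
        assert np.array_equal(f.decide(X), optimal_rule(X, spec1))

    def test_dimension_mismatch(self):
        f = DecisionFunction(LINEAR, intercept=0.0, coef=np.zeros(3))
        with pytest.raises(ValueError):
            f.value(np.ones((4, 5)))

    def test_rule_roundtrip(self, tmp_path):
        f = DecisionFunction(LINEAR, intercept=0.5, coef=np.array([1.0, -2.0]), n_fit=7)
        path = tmp_path / "rule.tsv"
        save_rule(f, path)
        g = load_rule(path)
        assert np.allclose(g.coefficients, f.coefficients)
        assert g.basis.kind == "linear"
        assert g.n_fit == 7
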