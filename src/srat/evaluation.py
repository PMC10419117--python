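"""Value functions, regrets, decision accuracies and rate arithmetic.

The value V(f) of a rule is the expected reward in an independent population
treated by sign(f).  It is estimated by Monte Carlo on a fresh covariate
sample; by default the *conditional-mean* reward Q0(X, sign f(X)) is
averaged (noise-free evaluation: same expectation as averaging noisy
rewards, strictly smaller variance).  All comparisons between rules are
paired on a shared covariate sample, so V(f*) - V(f*) is exactly zero and
regrets are nonnegative up to Monte-Carlo error.

Two regret notions follow the sequential-trial setting:

* test regret  V(f*) - V(f_n): population loss of the final learned rule;
* training regret  (1/n) sum_i [V(f_{i-1}) - R_i]: the average gap between
  the value of the rule in force and the reward actually realized.

For logged randomized data the self-normalized inverse-propensity-weighted
estimator scores a rule without refitting:

    sum_i R_i 1[A_i = sign f(X_i)] / pi_i  /  sum_i 1[A_i = sign f(X_i)] / pi_i.

The rate calculator exposes the polynomial decay exponents of the two
regrets under the truncation schedules eps_i = eps0 * i**(-(1-theta)/4):
test regret decays as n**(-theta/2) (up to log factors) and training regret
as n**(-(1-theta')/4); the two match at theta = 1/3 with common exponent 1/6.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .owl import DecisionFunction
from .scenarios import ScenarioSpec, conditional_mean, optimal_rule, sample_covariates
from .utils import as_rng, sign_pm


def estimate_value(
    f: DecisionFunction,
    scenario: ScenarioSpec,
    mc_size: int = 100_000,
    rng=None,
    X: Optional[np.ndarray] = None,
    noise_free: bool = True,
) -> float:
    """Monte-Carlo estimate of V(f) on a fresh (or supplied) covariate sample."""
    if X is None:
        if mc_size < 1:
            raise ValueError("mc_size must be >= 1")
        X = sample_covariates(mc_size, scenario, as_rng(rng))
    decisions = f.decide(X)
    q = conditional_mean(X, decisions, scenario)
    if not noise_free:
        q = q + np.sqrt(scenario.variance(X)) * as_rng(rng).standard_normal(len(q))
    return float(np.mean(q))


def checkpoint_values(
    checkpoints: np.ndarray, basis, scenario: ScenarioSpec, X: np.ndarray
) -> np.ndarray:
    """V(f_i) for a stack of intercept-first coefficient vectors, evaluated
    noise-free on a shared covariate sample (vectorized over checkpoints)."""
    phi = basis.with_intercept(X)  # (m, p+1)
    decisions = sign_pm(phi @ np.atleast_2d(checkpoints).T)  # (m, k)
    m0 = conditional_mean(X, np.zeros(X.shape[0]), scenario)  # main effect only
    tau = conditional_mean(X, np.ones(X.shape[0]), scenario) - m0
    return np.mean(m0[:, None] + tau[:, None] * decisions, axis=0)


def training_regret(
    result,
    scenario: ScenarioSpec,
    mc_size: int = 100_000,
    rng=None,
    X: Optional[np.ndarray] = None,
) -> float:
    """(1/n) sum_i [V(f_{i-1}) - R_i] over the main trial."""
    n = result.n_main
    if n < 1:
        raise ValueError("training regret requires at least one main-trial record")
    if result.checkpoints.shape[0] < n:
        raise ValueError("missing rule checkpoints")
    if X is None:
        X = sample_covariates(mc_size, scenario, as_rng(rng))
    values = checkpoint_values(result.checkpoints[:n], result.basis, scenario, X)
    rewards = result.history.R[result.history.mask("main")]
    return float(np.mean(values - rewards))


def test_regret(
    f: DecisionFunction,
    scenario: ScenarioSpec,
    mc_size: int = 100_000,
    rng=None,
    X: Optional[np.ndarray] = None,
) -> float:
    """V(f*) - V(f) on a paired covariate sample; f* is the analytic
    optimal rule of the scenario."""
    if X is None:
        X = sample_covariates(mc_size, scenario, as_rng(rng))
    v_opt = float(np.mean(conditional_mean(X, optimal_rule(X, scenario), scenario)))
    v_f = float(np.mean(conditional_mean(X, f.decide(X), scenario)))
    return v_opt - v_f


def false_decision_ratio(
    decisions: np.ndarray, X: np.ndarray, scenario: ScenarioSpec
) -> float:
    """Fraction of decisions disagreeing with the optimal rule (1 - accuracy)."""
    decisions = np.asarray(decisions)
    X = np.atleast_2d(X)
    if decisions.shape[0] != X.shape[0]:
        raise ValueError("decisions and covariates must have equal length")
    return float(np.mean(decisions != optimal_rule(X, scenario)))


def weighted_regret(train_regret: float, test_regret: float, lam: float) -> float:
    """lam * test + (1 - lam) * train, the exploration-exploitation tradeoff
    objective; endpoints recover the pure regrets."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    return lam * test_regret + (1.0 - lam) * train_regret


def ipw_cv_value(records, f: DecisionFunction) -> float:
    """Self-normalized IPW value of f on logged records.

    Raises when no record is consistent with f (the estimate is undefined,
    never silently zero).
    """
    X, A, R, pi = records.X, records.A, records.R, records.propensity
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("all propensities must lie in (0, 1)")
    consistent = A == f.decide(X)
    if not np.any(consistent):
        raise ValueError("no record is consistent with the rule; IPW value undefined")
    w = consistent / pi
    return float(np.sum(w * R) / np.sum(w))


def rate_exponents(theta: float, theta_prime: float) -> tuple[float, float]:
    """Polynomial decay exponents (test, training) of the two regrets under
    the schedules eps_i = eps0 * i**(-(1-theta)/4) and
    eps'_i = eps0' * i**(-(1-theta')/4): (theta/2, (1-theta')/4)."""
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    if theta_prime > 1.0:
        raise ValueError("theta_prime must be <= 1")
    return theta / 2.0, (1.0 - theta_prime) / 4.0


def balance_theta() -> float:
    """The schedule exponent at which the two regret rates coincide:
    theta/2 = (1 - theta)/4, i.e. theta = 1/3 (common exponent 1/6)."""
    return 1.0 / 3.0


def evaluate_trial(
    result, scenario: ScenarioSpec, X_test: np.ndarray
) -> dict[str, float]:
    """Replicate-level metrics of one trial on a shared test sample."""
    hist = result.history
    main = hist.mask("main")
    X_train = hist.X[main]
    final = result.final_rule
    train_fdr = false_decision_ratio(hist.A[main], X_train, scenario)
    test_fdr = false_decision_ratio(final.decide(X_test), X_test, scenario)
    return {
        "train_regret": training_regret(result, scenario, X=X_test),
        "test_regret": test_regret(final, scenario, X=X_test),
        "train_fdr": train_fdr,
        "test_fdr": test_fdr,
        "train_correct": 1.0 - train_fdr,
        "test_correct": 1.0 - test_fdr,
        "mean_reward": float(np.mean(hist.R[main])),
    }
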