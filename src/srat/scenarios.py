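"""Synthetic two-arm trial scenarios.

Each scenario describes a patient population and reward model:

* covariates X ~ N(0, Sigma) truncated to a hypercube (componentwise),
* a main effect m0(x) common to both arms,
* an antisymmetric treatment effect T0(x, a) = tau(x) * a for arms
  a in {-1, +1}, written via the effect contrast tau,
* a reward R | X, A ~ Normal(m0(X) + T0(X, A), nu0(X)).

The optimal individualized treatment rule follows from the contrast alone:
d*(x) = sign(tau(x)), with sign(0) = +1.

Two presets are provided. Both use d = 10 covariates with unit variances and
0.1 off-diagonal covariance, truncation to [-1, 1] per coordinate, main
effect m0(x) = 1 + 2*x1 + x2^2 + 2*x2*x3 and reward variance
nu0(x) = 0.2*x1^2*x3 + 1 (range [0.8, 1.2] on the support):

* ``scenario1`` (linear):    tau(x) = 0.5*(0.2 - x1 - x2)
* ``scenario2`` (nonlinear): tau(x) = 0.5*(0.2 - x1^2 - x2)
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigurationError
from .utils import as_rng, sign_pm

ArrayFunc = Callable[[np.ndarray], np.ndarray]


def _default_main_effect(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(X)
    if X.shape[1] < 3:
        raise ValueError("main effect requires at least 3 covariates")
    return 1.0 + 2.0 * X[:, 0] + X[:, 1] ** 2 + 2.0 * X[:, 1] * X[:, 2]


def _default_variance(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(X)
    if X.shape[1] < 3:
        raise ValueError("variance function requires at least 3 covariates")
    return 0.2 * X[:, 0] ** 2 * X[:, 2] + 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A data-generating process for a two-arm adaptive trial.

    ``effect_contrast`` is tau(x); the treatment effect is T0(x, a) =
    tau(x) * a, which enforces antisymmetry in the arm exactly.
    """

    name: str
    d: int
    sigma: np.ndarray
    lower: float = -1.0
    upper: float = 1.0
    main_effect: ArrayFunc = _default_main_effect
    effect_contrast: ArrayFunc = None
    variance: ArrayFunc = _default_variance

    def __post_init__(self):
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.shape != (self.d, self.d):
            raise ConfigurationError("sigma must be d x d")
        if not np.allclose(sigma, sigma.T):
            raise ConfigurationError("sigma must be symmetric")
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("sigma must be positive definite") from exc
        if self.effect_contrast is None:
            raise ConfigurationError("effect_contrast is required")
        if not self.lower < self.upper:
            raise ConfigurationError("truncation bounds must satisfy lower < upper")
        object.__setattr__(self, "sigma", sigma)


def _equicorrelation(d: int, rho: float) -> np.ndarray:
    return np.full((d, d), rho) + (1.0 - rho) * np.eye(d)


def scenario(name: str) -> ScenarioSpec:
    """Preset scenarios addressable by name.

    ``scenario1``/``linear`` has a linear effect contrast; ``scenario2``/
    ``nonlinear`` a quadratic one.
    """
    aliases = {"linear": "scenario1", "nonlinear": "scenario2"}
    name = aliases.get(name, name)
    if name == "scenario1":
        contrast = lambda X: 0.5 * (0.2 - np.atleast_2d(X)[:, 0] - np.atleast_2d(X)[:, 1])
    elif name == "scenario2":
        contrast = lambda X: 0.5 * (0.2 - np.atleast_2d(X)[:, 0] ** 2 - np.atleast_2d(X)[:, 1])
    else:
        raise ConfigurationError(f"unknown scenario {name!r}")
    return ScenarioSpec(name=name, d=10, sigma=_equicorrelation(10, 0.1), effect_contrast=contrast)


def get_scenario(spec_or_name) -> ScenarioSpec:
    if isinstance(spec_or_name, ScenarioSpec):
        return spec_or_name
    return scenario(spec_or_name)


def sample_covariates(n: int, spec: ScenarioSpec, rng) -> np.ndarray:
    """Draw n i.i.d. covariate vectors from N(0, Sigma) conditioned on the
    truncation hypercube, by rejection of full multivariate-normal draws.

    Rejection keeps the conditional law exact; the realized off-diagonal
    correlations are attenuated relative to Sigma because truncation is
    applied after sampling (Sigma is not renormalized).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    L = np.linalg.cholesky(spec.sigma)
    out = np.empty((n, spec.d))
    filled = 0
    accept_est = 0.6827 ** spec.d  # per-coordinate N(0,1) mass on [-1,1]
    while filled < n:
        need = n - filled
        m = min(int(need / max(accept_est, 1e-4) * 1.2) + 64, 4_000_000)
        Z = rng.standard_normal((m, spec.d)) @ L.T
        ok = Z[np.all((Z >= spec.lower) & (Z <= spec.upper), axis=1)]
        if ok.shape[0] > 0:
            accept_est = max(ok.shape[0] / m, 1e-4)
        take = min(ok.shape[0], need)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def main_effect(x: np.ndarray, spec: ScenarioSpec | None = None) -> np.ndarray:
    """m0(x); default 1 + 2*x1 + x2^2 + 2*x2*x3."""
    fn = spec.main_effect if spec is not None else _default_main_effect
    out = fn(np.atleast_2d(x))
    return out if np.ndim(x) > 1 else float(out[0])


def treatment_effect(x: np.ndarray, a, spec: ScenarioSpec) -> np.ndarray:
    """T0(x, a) = tau(x) * a for a in {-1, +1}."""
    a_arr = np.asarray(a)
    if not np.all(np.isin(a_arr, (-1, 1))):
        raise ValueError("arm must be -1 or +1")
    out = spec.effect_contrast(np.atleast_2d(x)) * a_arr
    return out if (np.ndim(x) > 1 or a_arr.ndim > 0) else float(out[0])


def reward_variance(x: np.ndarray, spec: ScenarioSpec | None = None) -> np.ndarray:
    """nu0(x); default 0.2*x1^2*x3 + 1."""
    fn = spec.variance if spec is not None else _default_variance
    out = fn(np.atleast_2d(x))
    return out if np.ndim(x) > 1 else float(out[0])


def conditional_mean(X: np.ndarray, A, spec: ScenarioSpec) -> np.ndarray:
    """Q0(x, a) = m0(x) + T0(x, a), the mean reward of arm a at x."""
    X2 = np.atleast_2d(X)
    return spec.main_effect(X2) + spec.effect_contrast(X2) * np.asarray(A)


def sample_rewards(X: np.ndarray, A, spec: ScenarioSpec, rng) -> np.ndarray:
    """Draw rewards R ~ Normal(Q0(X, A), nu0(X)) row-wise."""
    rng = as_rng(rng)
    X2 = np.atleast_2d(X)
    mean = conditional_mean(X2, A, spec)
    sd = np.sqrt(spec.variance(X2))
    return mean + sd * rng.standard_normal(X2.shape[0])


def sample_reward(x: np.ndarray, a: int, spec: ScenarioSpec, rng) -> float:
    return float(sample_rewards(np.atleast_2d(x), a, spec, rng)[0])


def optimal_rule(x: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    """The arm maximizing T0(x, a): sign(tau(x)), with sign(0) = +1."""
    out = sign_pm(spec.effect_contrast(np.atleast_2d(x)))
    return out if np.ndim(x) > 1 else int(out[0])
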