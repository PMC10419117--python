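"""Exploration policies: randomization probabilities and their bookkeeping.

All policies produce, for main-trial patient i >= 1, the probability p_i of
*following* the current estimated rule d(x) = sign(f(x)).  Positivity is
enforced by the truncation sequence

    eps_i = eps0 * i**(-(1 - theta) / 4),   eps0 in (0, 0.5], theta in (0, 1],

and every stochastic policy keeps p_i inside the band [eps_i, 1 - eps_i].

* epsilon-greedy ("srat_e"): p_i = 1 - eps_i, the exploitation-maximal
  choice inside the band.  With eps0 = 0.5 and theta = 1 it degenerates to
  pure randomization (a classical RCT).
* Boltzmann ("srat_b"): p_i follows an inverse-logit of the UCB-based
  benefit of the rule's arm over its opposite, truncated to the band; the
  benefit comes from per-arm ridge regressions of reward on the basis.
* LinUCB ("linucb"): deterministically picks the arm with the larger upper
  confidence bound; a limiting case of the Boltzmann policy as eps, gamma -> 0.

The per-arm ridge states use an identity prior: W_a = I + Phi' Phi,
Y_a = Phi' R over the records observed on arm a, beta_a = W_a^{-1} Y_a, with
phi including an explicit intercept column.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .basis import Basis
from .errors import ConfigurationError
from .utils import sign_pm


@dataclass(frozen=True)
class EpsilonSchedule:
    """Truncation schedule eps_i = eps0 * i**(-(1-theta)/4)."""

    eps0: float = 0.1
    theta: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.eps0 <= 0.5:
            raise ConfigurationError("eps0 must lie in (0, 0.5]")
        if not 0.0 < self.theta <= 1.0:
            raise ConfigurationError("theta must lie in (0, 1]")


def epsilon_at(i: int, sched: EpsilonSchedule) -> float:
    """eps_i for main-trial index i >= 1; constant eps0 when theta = 1."""
    if i < 1:
        raise ValueError("main-trial index starts at 1")
    return sched.eps0 * float(i) ** (-(1.0 - sched.theta) / 4.0)


def srat_e_prob(i: int, sched: EpsilonSchedule) -> float:
    """Epsilon-greedy follow probability p_i = 1 - eps_i."""
    return 1.0 - epsilon_at(i, sched)


@dataclass(frozen=True)
class BoltzmannConfig:
    """UCB width alpha_i (held constant) and temperature gamma_i = base**i."""

    alpha: float = 0.2
    gamma_base: float = 0.999

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigurationError("alpha must be nonnegative")
        if not 0.0 < self.gamma_base:
            raise ConfigurationError("gamma_base must be positive")


def gamma_at(i: int, config: BoltzmannConfig) -> float:
    if i < 1:
        raise ValueError("main-trial index starts at 1")
    return config.gamma_base**i


class RidgeArmState:
    """Incremental ridge regression for one arm: W = I + Phi'Phi, Y = Phi'R."""

    def __init__(self, arm: int, dim: int):
        if arm not in (-1, 1):
            raise ValueError("arm must be -1 or +1")
        self.arm = arm
        self.W = np.eye(dim)
        self.Y = np.zeros(dim)

    @property
    def beta(self) -> np.ndarray:
        return np.linalg.solve(self.W, self.Y)

    def copy(self) -> "RidgeArmState":
        out = RidgeArmState(self.arm, self.W.shape[0])
        out.W = self.W.copy()
        out.Y = self.Y.copy()
        return out


def ridge_init(history, arm: int, basis: Basis) -> RidgeArmState:
    """Batch-initialize an arm's ridge state from pilot records on that arm.

    The identity prior keeps W positive definite even with zero records.
    """
    dim = basis.n_features(history.d) + 1
    state = RidgeArmState(arm, dim)
    mask = history.A == arm
    if np.any(mask):
        phi = basis.with_intercept(history.X[mask])
        state.W += phi.T @ phi
        state.Y += phi.T @ history.R[mask]
    return state


def ridge_update(state: RidgeArmState, phi: np.ndarray, r: float) -> RidgeArmState:
    """Rank-one update W += phi phi', Y += r phi (returns a new state)."""
    phi = np.asarray(phi, dtype=float).ravel()
    out = state.copy()
    out.W += np.outer(phi, phi)
    out.Y += r * phi
    return out


def ucb_score(state: RidgeArmState, phi: np.ndarray, alpha: float) -> float:
    """Upper confidence bound phi'beta + alpha * sqrt(phi' W^{-1} phi)."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    phi = np.asarray(phi, dtype=float).ravel()
    mean = float(phi @ state.beta)
    width = float(np.sqrt(phi @ np.linalg.solve(state.W, phi)))
    return mean + alpha * width


def benefit(
    states: Dict[int, RidgeArmState], phi: np.ndarray, alpha: float, d_hat: int
) -> float:
    """UCB of the rule's arm minus UCB of the opposite arm."""
    if d_hat not in (-1, 1):
        raise ValueError("d_hat must be -1 or +1")
    return ucb_score(states[d_hat], phi, alpha) - ucb_score(states[-d_hat], phi, alpha)


def srat_b_prob(b_hat: float, eps_i: float, gamma_i: float) -> float:
    """Boltzmann follow probability, truncated to [eps_i, 1 - eps_i].

    p = 1 - eps_i when the benefit is nonnegative (the ridge model agrees
    with the rule); otherwise the inverse logit of b_hat / gamma_i, floored
    at eps_i.
    """
    if not 0.0 < eps_i <= 0.5:
        raise ValueError("eps_i must lie in (0, 0.5]")
    if gamma_i <= 0:
        raise ValueError("gamma_i must be positive")
    if b_hat >= 0:
        return 1.0 - eps_i
    z = b_hat / gamma_i
    inv_logit = 1.0 / (1.0 + np.exp(-z)) if z > -700 else 0.0
    return max(eps_i, inv_logit)


def linucb_choose(states: Dict[int, RidgeArmState], phi: np.ndarray, alpha: float) -> int:
    """Deterministic arm: sign of UCB(+1) - UCB(-1), with sign(0) = +1."""
    diff = ucb_score(states[1], phi, alpha) - ucb_score(states[-1], phi, alpha)
    return int(sign_pm(diff))


# --------------------------------------------------------------------------
# Stateful policy objects consumed by the trial engine


class Policy:
    """Base class: per-patient follow probability plus model bookkeeping."""

    name = "policy"
    deterministic = False
    uses_ridge = False

    def reset(self, pilot, basis: Basis) -> None:  # noqa: ARG002
        return None

    def epsilon(self, i: int) -> float:
        raise NotImplementedError

    def prob(self, i: int, phi: np.ndarray, d_hat: int) -> float:
        raise NotImplementedError

    def update(self, phi: np.ndarray, arm: int, reward: float) -> None:  # noqa: ARG002
        return None


class EpsilonGreedyPolicy(Policy):
    """srat_e: p_i = 1 - eps_i, independent of history and covariates."""

    name = "srat_e"

    def __init__(self, eps0: float = 0.1, theta: float = 1.0):
        self.schedule = EpsilonSchedule(eps0, theta)

    def epsilon(self, i: int) -> float:
        return epsilon_at(i, self.schedule)

    def prob(self, i, phi, d_hat):  # noqa: ARG002
        return srat_e_prob(i, self.schedule)


def rct_policy() -> EpsilonGreedyPolicy:
    """Pure randomization: the eps0 = 0.5, theta = 1 special case."""
    p = EpsilonGreedyPolicy(eps0=0.5, theta=1.0)
    p.name = "rct"
    return p


class _RidgePolicy(Policy):
    uses_ridge = True

    def __init__(self):
        self.states: Optional[Dict[int, RidgeArmState]] = None

    def reset(self, pilot, basis: Basis) -> None:
        self.states = {a: ridge_init(pilot, a, basis) for a in (-1, 1)}

    def update(self, phi: np.ndarray, arm: int, reward: float) -> None:
        # only the realized arm's model is updated
        self.states[arm] = ridge_update(self.states[arm], phi, reward)

    def ridge_rule_coefficients(self) -> np.ndarray:
        """Coefficients of the ridge-mean rule sign(phi . (beta_+ - beta_-))."""
        return self.states[1].beta - self.states[-1].beta


class BoltzmannPolicy(_RidgePolicy):
    """srat_b: benefit-driven follow probability inside the truncation band."""

    name = "srat_b"

    def __init__(
        self,
        eps0: float = 0.1,
        theta: float = 1.0,
        alpha: float = 0.2,
        gamma_base: float = 0.999,
    ):
        super().__init__()
        self.schedule = EpsilonSchedule(eps0, theta)
        self.config = BoltzmannConfig(alpha=alpha, gamma_base=gamma_base)

    def epsilon(self, i: int) -> float:
        return epsilon_at(i, self.schedule)

    def prob(self, i: int, phi: np.ndarray, d_hat: int) -> float:
        b_hat = benefit(self.states, phi, self.config.alpha, d_hat)
        return srat_b_prob(b_hat, self.epsilon(i), gamma_at(i, self.config))


class LinUCBPolicy(_RidgePolicy):
    """Deterministic two-arm disjoint-model LinUCB."""

    name = "linucb"
    deterministic = True

    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def choose(self, phi: np.ndarray) -> int:
        return linucb_choose(self.states, phi, self.alpha)


def make_policy(name: str, **params) -> Policy:
    """Policy factory for configuration files: srat_e, srat_b, linucb, rct."""
    name = name.lower()
    if name == "srat_e":
        return EpsilonGreedyPolicy(
            eps0=params.get("eps0", 0.1), theta=params.get("theta", 1.0)
        )
    if name == "srat_b":
        return BoltzmannPolicy(
            eps0=params.get("eps0", 0.1),
            theta=params.get("theta", 1.0),
            alpha=params.get("alpha", 0.2),
            gamma_base=params.get("gamma_base", 0.999),
        )
    if name == "linucb":
        return LinUCBPolicy(alpha=params.get("alpha", 0.2))
    if name == "rct":
        return rct_policy()
    raise ConfigurationError(f"unknown policy {name!r}")
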