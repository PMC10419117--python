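"""Outcome-weighted learning (OWL) of a linear decision rule.

OWL turns reward maximization into weighted classification: the rule
d(x) = sign(f(x)) is estimated by minimizing the inverse-propensity-weighted
hinge loss

    (1/n) * sum_i  (R_i / pi_i) * [1 - A_i f(X_i)]_+  +  lambda * ||beta||^2

over linear f on a basis expansion, with the intercept unpenalized. Rewards
may first be residualized against a least-squares fit of R on the basis
(both arms pooled), which reduces the variance of the weights without
changing the population minimizer. Negative weights are handled by flipping
the sign of the reward and the arm label simultaneously, which leaves the
objective unchanged.

The weighted hinge + ridge problem is solved in the dual by a dedicated SMO
routine (see ``_solver``) after mapping the (1/n, lambda) normalization onto
the SVM convention C_i = w_i / (2 * lambda * n); warm starts from the
previous refit's dual vector make the per-patient refit loop cheap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._solver import solve_weighted_hinge
from .basis import Basis
from .errors import DegenerateProblemError, PositivityError
from .utils import sign_pm


@dataclass
class DecisionFunction:
    """A linear decision rule f(x) = intercept + beta . phi(x); the treatment
    decision is sign(f(x)) with sign(0) = +1."""

    basis: Basis
    intercept: float
    coef: np.ndarray
    n_fit: int = 0

    def value(self, X: np.ndarray) -> np.ndarray:
        phi = self.basis.transform(np.atleast_2d(X))
        if phi.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"feature dimension {phi.shape[1]} incompatible with rule "
                f"dimension {self.coef.shape[0]}"
            )
        return self.intercept + phi @ self.coef

    def decide(self, X: np.ndarray) -> np.ndarray:
        out = sign_pm(self.value(np.atleast_2d(X)))
        return out if np.ndim(X) > 1 else int(out[0])

    @property
    def coefficients(self) -> np.ndarray:
        """Intercept-first coefficient vector (length p + 1)."""
        return np.concatenate([[self.intercept], self.coef])

    @classmethod
    def from_coefficients(cls, c: np.ndarray, basis: Basis, n_fit: int = 0):
        c = np.asarray(c, dtype=float)
        return cls(basis=basis, intercept=float(c[0]), coef=c[1:].copy(), n_fit=n_fit)


@dataclass
class OWLConfig:
    """Estimation settings for the OWL refits.

    lam: ridge penalty on beta; None means 1/n_records at each refit, so the
        regularization vanishes as data accrue.
    tol: solver tolerance forwarded to liblinear.
    residualize: subtract a pooled least-squares main-effect fit from the
        rewards before weighting.
    basis: feature expansion of the decision function.
    """

    lam: Optional[float] = None
    tol: float = 1e-8
    residualize: bool = True
    basis: Basis = field(default_factory=Basis)

    def __post_init__(self):
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be positive")


def residualize_rewards(X: np.ndarray, R: np.ndarray, basis: Basis) -> np.ndarray:
    """R_i minus a least-squares fit of R on (1, phi(X)) pooled over arms.

    Falls back to the minimum-norm solution (with a warning) when the design
    is rank deficient.
    """
    X = np.atleast_2d(X)
    R = np.asarray(R, dtype=float)
    design = basis.with_intercept(X)
    if len(R) < design.shape[1]:
        raise ValueError(
            f"need at least {design.shape[1]} records to residualize on this basis"
        )
    coef, _, rank, _ = np.linalg.lstsq(design, R, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient design in reward residualization; using the "
            "minimum-norm least-squares fit",
            stacklevel=2,
        )
    return R - design @ coef


def weighted_hinge_objective(
    intercept: float,
    coef: np.ndarray,
    features: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    lam: float,
) -> float:
    """(1/n) sum_i w_i [1 - y_i f(x_i)]_+ + lam ||beta||^2 (intercept free)."""
    f = intercept + features @ np.asarray(coef)
    hinge = np.maximum(0.0, 1.0 - labels * f)
    return float(np.mean(weights * hinge) + lam * np.dot(coef, coef))


class SolverState:
    """Warm-start carrier for sequential refits: the dual vector of the
    previous fit, aligned with the record order."""

    def __init__(self):
        self.alpha: Optional[np.ndarray] = None


def fit_weighted_svm(
    features: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    basis: Optional[Basis] = None,
    state: Optional[SolverState] = None,
) -> DecisionFunction:
    """Minimize the weighted hinge loss with ridge penalty lam over linear f.

    ``basis`` only tags the returned rule; ``features`` are already expanded.
    ``tol`` bounds the SMO maximal-violating-pair gap at termination.
    Raises DegenerateProblemError when no weight is positive; returns the
    constant rule (with a warning) when only one label class carries weight.
    ``state``, when given, provides and receives the warm-start dual vector.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative (flip labels instead)")
    if lam <= 0:
        raise ValueError("lam must be positive")
    n, p = features.shape
    basis = basis if basis is not None else Basis("linear")
    active = weights > 0
    if not np.any(active):
        raise DegenerateProblemError("all weights are zero")
    present = np.unique(labels[active])
    if present.size == 1:
        warnings.warn(
            "only one label class carries positive weight; returning the "
            "constant rule for that class",
            stacklevel=2,
        )
        return DecisionFunction(
            basis=basis, intercept=float(present[0]), coef=np.zeros(p), n_fit=n
        )
    # (1/n) sum w_i hinge + lam ||beta||^2  ==  2*lam * [ 0.5||v||^2
    #   + sum C_i hinge ]  with  C_i = w_i / (2 lam n)  and  beta = v.
    C = weights / (2.0 * lam * n)
    alpha0 = state.alpha if state is not None else None
    v, b, alpha, _, _ = solve_weighted_hinge(
        features, labels.astype(float), C, tol=tol, alpha0=alpha0
    )
    if state is not None:
        state.alpha = alpha
    return DecisionFunction(basis=basis, intercept=b, coef=v, n_fit=n)


def owl_weights(
    R: np.ndarray, propensity: np.ndarray, A: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """IPW classification weights and labels: w = R / pi, with negative
    weights folded in by flipping the arm label, (w, a) -> (|w|, sign(w)*a)."""
    R = np.asarray(R, dtype=float)
    propensity = np.asarray(propensity, dtype=float)
    A = np.asarray(A)
    if np.any((propensity <= 0) | (propensity >= 1)):
        raise PositivityError("all propensities must lie in (0, 1)")
    w = R / propensity
    labels = np.where(w < 0, -A, A)
    return np.abs(w), labels


def fit_owl(
    history, config: OWLConfig, state: Optional[SolverState] = None
) -> DecisionFunction:
    """Fit the OWL rule on the pooled pilot + main-trial history.

    Implements the sequential refit objective: hinge terms from both
    segments, weights R~_j / pi_j, and the 1/(n0 + i) normalization (the
    total record count). ``state`` warm-starts the solver across refits.
    """
    n = len(history)
    if n == 0:
        raise ValueError("history is empty")
    X, A, R, pi = history.X, history.A, history.R, history.propensity
    if config.residualize and n >= config.basis.with_intercept(X[:1]).shape[1]:
        R = residualize_rewards(X, R, config.basis)
    weights, labels = owl_weights(R, pi, A)
    lam = config.lam if config.lam is not None else 1.0 / n
    features = config.basis.transform(X)
    return fit_weighted_svm(
        features, labels, weights, lam=lam, tol=config.tol,
        basis=config.basis, state=state,
    )


def predict_rule(f: DecisionFunction, x: np.ndarray):
    """sign(f(x)) in {-1, +1}, with sign(0) = +1."""
    return f.decide(x)


def save_rule(f: DecisionFunction, path) -> None:
    """Serialize a fitted rule as a plain-text coefficient file."""
    with open(path, "w") as fh:
        fh.write(f"basis\t{f.basis.kind}\n")
        fh.write(f"n_fit\t{f.n_fit}\n")
        fh.write("coefficients\t" + "\t".join(f"{c:.17g}" for c in f.coefficients) + "\n")


def load_rule(path) -> DecisionFunction:
    fields = {}
    with open(path) as fh:
        for line in fh:
            key, _, rest = line.rstrip("\n").partition("\t")
            fields[key] = rest
    coefs = np.array([float(v) for v in fields["coefficients"].split("\t")])
    return DecisionFunction.from_coefficients(
        coefs, Basis(fields["basis"]), n_fit=int(fields.get("n_fit", 0))
    )
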