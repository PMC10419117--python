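"""Feature expansions shared by the decision-rule learner and the per-arm
ridge models.

A basis maps an (n, d) covariate matrix to an (n, p) feature matrix
*without* an intercept column; callers that need one (the ridge states, the
design matrix of the residualizing regression) request it explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class Basis:
    """A named feature map over covariates.

    kind:
        "linear"    -> phi(x) = x
        "quadratic" -> phi(x) = (x, x**2): linear plus per-coordinate squares
        "custom"    -> user-supplied callable (n, d) -> (n, p)
    """

    kind: str = "linear"
    func: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        if self.kind not in ("linear", "quadratic", "custom"):
            raise ConfigurationError(f"unknown basis kind {self.kind!r}")
        if self.kind == "custom" and self.func is None:
            raise ConfigurationError("custom basis requires a callable")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "linear":
            return X
        if self.kind == "quadratic":
            return np.hstack([X, X**2])
        return np.atleast_2d(self.func(X))

    def with_intercept(self, X: np.ndarray) -> np.ndarray:
        """Feature matrix with a leading column of ones."""
        phi = self.transform(X)
        return np.hstack([np.ones((phi.shape[0], 1)), phi])

    def n_features(self, d: int) -> int:
        if self.kind == "linear":
            return d
        if self.kind == "quadratic":
            return 2 * d
        return self.transform(np.zeros((1, d))).shape[1]


def default_basis(scenario_name: str) -> Basis:
    """Expansion conventionally paired with each preset scenario: linear
    terms when the treatment-effect contrast is linear, linear plus
    quadratic terms when it is quadratic in the covariates."""
    if scenario_name in ("scenario1", "linear"):
        return Basis("linear")
    if scenario_name in ("scenario2", "nonlinear"):
        return Basis("quadratic")
    raise ConfigurationError(f"no default basis for scenario {scenario_name!r}")
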