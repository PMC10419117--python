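import numpy as np
import pytest

from srat.history import MAIN, PILOT, TrialHistory
from srat.scenarios import sample_covariates, sample_rewards, scenario


@pytest.fixture(scope="session")
def spec1():
    return scenario("scenario1")


@pytest.fixture(scope="session")
def spec2():
    return scenario("scenario2")


def make_randomized_history(spec, n, rng, phase=PILOT):
    """An i.i.d. fair-coin randomized history (propensity 0.5 throughout)."""
    X = sample_covariates(n, spec, rng)
    A = rng.choice(np.array([-1, 1]), size=n)
    R = sample_rewards(X, A, spec, rng)
    hist = TrialHistory(spec.d)
    for k in range(n):
        hist.append(X[k], int(A[k]), R[k], 0.5, phase=phase, p=0.5)
    return hist


def history_from_arrays(X, A, R, propensity, phase=MAIN):
    X = np.atleast_2d(X)
    hist = TrialHistory(X.shape[1])
    pi = np.broadcast_to(np.asarray(propensity, dtype=float), (X.shape[0],))
    for k in range(X.shape[0]):
        hist.append(X[k], int(A[k]), float(R[k]), float(pi[k]), phase=phase)
    return hist
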