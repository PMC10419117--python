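"""The sequential trial engine.

A trial consists of a purely randomized pilot of n0 patients (arms drawn
i.i.d. fair-coin, propensity 0.5) followed by a main phase of n patients.
For main-trial patient i the engine

1. evaluates the rule in force, d = sign(f_{i-1}(x_i)),
2. asks the exploration policy for the follow probability p_i,
3. draws the follow indicator I_i (+1 with probability p_i) and assigns
   A_i = I_i * d, recording the realized-arm propensity pi_i (p_i if
   followed, else 1 - p_i),
4. observes the reward and refits the outcome-weighted-learning rule on the
   pooled history with the 1/(n0 + i) normalization.

LinUCB is handled specially: its assignment is deterministic (the arm with
the larger upper confidence bound), its recorded propensity is 1, and its
rule checkpoints are the ridge-mean rules sign(phi . (beta_+ - beta_-));
no IPW-weighted OWL fit ever sees its records.

The engine also implements the replay construction for logged randomized
data: candidates are taken from the logged stream in order, the engine
draws its own treatment suggestion, and a record is kept only when the
logged arm agrees with the suggestion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .basis import Basis, default_basis
from .errors import ConfigurationError, PositivityError
from .history import MAIN, PILOT, TrialHistory
from .owl import DecisionFunction, OWLConfig, SolverState, fit_owl
from .policies import LinUCBPolicy, Policy, make_policy
from .scenarios import ScenarioSpec, get_scenario, sample_covariates, sample_rewards
from .utils import as_rng


@dataclass
class TrialConfig:
    """Configuration of one sequential trial run."""

    scenario: Union[str, ScenarioSpec] = "scenario1"
    policy: Union[str, Policy] = "srat_e"
    policy_params: dict = field(default_factory=dict)
    n0: int = 30
    n: int = 100
    owl: Optional[OWLConfig] = None
    #: refit the OWL rule every this many main-trial patients (None: never)
    refit_interval: Optional[int] = 1
    #: SMO gap tolerance for the warm-started in-loop refits; the final rule
    #: is always refit at the (tighter) OWLConfig tolerance
    refit_tol: float = 0.02
    seed: Optional[int] = None

    def resolve(self) -> tuple[ScenarioSpec, Policy, OWLConfig]:
        spec = get_scenario(self.scenario)
        policy = (
            self.policy
            if isinstance(self.policy, Policy)
            else make_policy(self.policy, **self.policy_params)
        )
        owl = self.owl
        if owl is None:
            owl = OWLConfig(basis=default_basis(spec.name), tol=1e-6)
        return spec, policy, owl


@dataclass
class TrialResult:
    """Records, rule checkpoints f_0..f_n (intercept-first coefficients),
    per-step follow probabilities and truncation levels."""

    config: TrialConfig
    seed: Optional[int]
    history: TrialHistory
    checkpoints: np.ndarray  # (n+1, p+1)
    p: np.ndarray  # (n,)
    eps: np.ndarray  # (n,)
    basis: Basis
    policy_name: str

    @property
    def n_main(self) -> int:
        return self.p.shape[0]

    def rule_at(self, i: int) -> DecisionFunction:
        """The rule in force after i main-trial patients (f_i)."""
        return DecisionFunction.from_coefficients(self.checkpoints[i], self.basis)

    @property
    def final_rule(self) -> DecisionFunction:
        return self.rule_at(self.n_main)


def run_pilot(
    n0: int, scenario: ScenarioSpec, rng, X: Optional[np.ndarray] = None
) -> TrialHistory:
    """Purely randomized pilot: arms i.i.d. fair-coin, propensity 0.5."""
    if n0 < 1:
        raise ValueError("pilot size n0 must be >= 1")
    rng = as_rng(rng)
    if X is None:
        X = sample_covariates(n0, scenario, rng)
    arms = rng.choice(np.array([-1, 1]), size=n0)
    rewards = sample_rewards(X, arms, scenario, rng)
    hist = TrialHistory(scenario.d)
    for k in range(n0):
        hist.append(X[k], int(arms[k]), rewards[k], 0.5, phase=PILOT, p=0.5)
    return hist


def decide_treatment(
    f: DecisionFunction, x: np.ndarray, i: int, policy: Policy, rng, basis: Basis
) -> tuple[int, int, float, float]:
    """One assignment: returns (arm, follow, propensity, p_i).

    For stochastic policies the follow indicator is +1 with probability p_i
    and the arm is follow * sign(f(x)); p_i is checked against the
    truncation band [eps_i, 1 - eps_i].  For LinUCB the arm is the
    deterministic UCB argmax and the recorded propensity is 1.
    """
    rng = as_rng(rng)
    x = np.atleast_2d(x)
    d_hat = int(f.decide(x)[0])
    if isinstance(policy, LinUCBPolicy):
        phi = basis.with_intercept(x)[0]
        arm = policy.choose(phi)
        follow = 1 if arm == d_hat else -1
        return arm, follow, 1.0, 1.0
    phi = basis.with_intercept(x)[0] if policy.uses_ridge else None
    p_i = float(policy.prob(i, phi, d_hat))
    eps_i = policy.epsilon(i)
    if not (0.0 < p_i < 1.0):
        raise PositivityError(f"p_{i} = {p_i} outside (0, 1)")
    if p_i < eps_i - 1e-12 or p_i > 1.0 - eps_i + 1e-12:
        raise PositivityError(
            f"p_{i} = {p_i} violates the truncation band [{eps_i}, {1 - eps_i}]"
        )
    follow = 1 if rng.random() < p_i else -1
    arm = follow * d_hat
    propensity = p_i if follow == 1 else 1.0 - p_i
    return int(arm), int(follow), float(propensity), p_i


def run_trial(config: TrialConfig, rng=None) -> TrialResult:
    """Run a full sequential trial; deterministic given config.seed."""
    spec, policy, owl_cfg = config.resolve()
    if config.n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = as_rng(rng if rng is not None else config.seed)
    basis = owl_cfg.basis
    X_all = sample_covariates(config.n0 + config.n, spec, rng)
    history = run_pilot(config.n0, spec, rng, X=X_all[: config.n0])
    policy.reset(history, basis)

    linucb = isinstance(policy, LinUCBPolicy)
    solver_state = SolverState()
    p_dim = basis.n_features(spec.d) + 1
    checkpoints = np.empty((config.n + 1, p_dim))
    if linucb:
        checkpoints[0] = policy.ridge_rule_coefficients()
    else:
        f0 = fit_owl(history, owl_cfg, state=solver_state)
        checkpoints[0] = f0.coefficients
    current = DecisionFunction.from_coefficients(checkpoints[0], basis)

    p_list = np.empty(config.n)
    eps_list = np.full(config.n, np.nan)
    loop_cfg = replace(owl_cfg, tol=max(config.refit_tol, owl_cfg.tol))
    for i in range(1, config.n + 1):
        x = X_all[config.n0 + i - 1]
        arm, follow, propensity, p_i = decide_treatment(
            current, x, i, policy, rng, basis
        )
        reward = float(sample_rewards(x[None, :], arm, spec, rng)[0])
        history.append(x, arm, reward, propensity, phase=MAIN, follow=follow, p=p_i)
        if policy.uses_ridge:
            policy.update(basis.with_intercept(x[None, :])[0], arm, reward)
        p_list[i - 1] = p_i
        if not linucb:
            eps_list[i - 1] = policy.epsilon(i)
        if linucb:
            checkpoints[i] = policy.ridge_rule_coefficients()
        elif config.refit_interval is not None and i % config.refit_interval == 0:
            fi = fit_owl(history, loop_cfg, state=solver_state)
            checkpoints[i] = fi.coefficients
        else:
            checkpoints[i] = checkpoints[i - 1]
        current = DecisionFunction.from_coefficients(checkpoints[i], basis)
    # the deliverable rule: refit the full history at the tight tolerance
    if not linucb and config.refit_interval is not None:
        fn = fit_owl(history, owl_cfg, state=solver_state)
        checkpoints[config.n] = fn.coefficients
    return TrialResult(
        config=config,
        seed=config.seed,
        history=history,
        checkpoints=checkpoints,
        p=p_list,
        eps=eps_list,
        basis=basis,
        policy_name=policy.name,
    )


def replay_trial(logged, config: TrialConfig, rng=None) -> TrialResult:
    """Replay a logged randomized study through the adaptive design.

    ``logged`` is a TrialHistory (or table convertible via
    TrialHistory.from_frame) whose arms were randomized independently of
    covariates.  The stream is consumed in order; the first n0 kept records
    come from uniform suggestions and form the pilot.  Afterwards each
    candidate receives the policy's suggestion I_i * d(x); the record is
    kept only when the logged arm matches, with the suggestion probability
    of the realized arm recorded as its propensity.  Stops when n records
    have been kept or the stream is exhausted (with a warning).
    """
    from .history import TrialHistory as TH

    if not isinstance(logged, TrialHistory):
        logged = TH.from_frame(logged)
    spec, policy, owl_cfg = config.resolve()
    rng = as_rng(rng if rng is not None else config.seed)
    basis = owl_cfg.basis
    X, A, R = logged.X, logged.A, logged.R
    n_stream = len(logged)

    kept = TrialHistory(logged.d)
    cursor = 0
    # pilot: uniform suggestions
    while len(kept) < config.n0 and cursor < n_stream:
        suggestion = int(rng.choice(np.array([-1, 1])))
        if suggestion == A[cursor]:
            kept.append(X[cursor], A[cursor], R[cursor], 0.5, phase=PILOT, p=0.5)
        cursor += 1
    if len(kept) < config.n0:
        warnings.warn(
            f"logged stream exhausted after {len(kept)} pilot records "
            f"(needed {config.n0}); returning a partial result",
            stacklevel=2,
        )
    policy.reset(kept, basis)
    solver_state = SolverState()
    p_dim = basis.n_features(spec.d) + 1
    checkpoint_list = []
    p_vals = []
    eps_vals = []
    linucb = isinstance(policy, LinUCBPolicy)
    if linucb:
        coefs = policy.ridge_rule_coefficients()
    elif len(kept) > 0:
        coefs = fit_owl(kept, owl_cfg, state=solver_state).coefficients
    else:
        coefs = np.zeros(p_dim)
    checkpoint_list.append(coefs.copy())
    current = DecisionFunction.from_coefficients(coefs, basis)
    loop_cfg = replace(owl_cfg, tol=max(config.refit_tol, owl_cfg.tol))

    i = 0  # kept main-trial count
    while i < config.n and cursor < n_stream:
        x = X[cursor]
        arm, follow, propensity, p_i = decide_treatment(
            current, x, i + 1, policy, rng, basis
        )
        suggestion = arm
        if suggestion == A[cursor]:
            i += 1
            kept.append(
                x, A[cursor], R[cursor], propensity, phase=MAIN, follow=follow, p=p_i
            )
            if policy.uses_ridge:
                policy.update(basis.with_intercept(x[None, :])[0], A[cursor], R[cursor])
            p_vals.append(p_i)
            eps_vals.append(np.nan if linucb else policy.epsilon(i))
            if linucb:
                coefs = policy.ridge_rule_coefficients()
            elif config.refit_interval is not None and i % config.refit_interval == 0:
                coefs = fit_owl(kept, loop_cfg, state=solver_state).coefficients
            checkpoint_list.append(coefs.copy())
            current = DecisionFunction.from_coefficients(coefs, basis)
        cursor += 1
    if i < config.n:
        warnings.warn(
            f"logged stream exhausted after {i} kept main-trial records "
            f"(target {config.n})",
            stacklevel=2,
        )
    if not linucb and config.refit_interval is not None and len(kept) > 0:
        coefs = fit_owl(kept, owl_cfg, state=solver_state).coefficients
        checkpoint_list[-1] = coefs
    return TrialResult(
        config=config,
        seed=config.seed,
        history=kept,
        checkpoints=np.array(checkpoint_list),
        p=np.array(p_vals),
        eps=np.array(eps_vals),
        basis=basis,
        policy_name=policy.name,
    )


def kfold_replay_value(
    logged, config: TrialConfig, n_folds: int = 5, rng=None
) -> np.ndarray:
    """K-fold replay evaluation of the learned rule on logged data.

    The logged records are partitioned at random into n_folds folds; each
    fold in turn is held out, the replay runs on the remaining records (in
    their original order), and the final rule is scored on the held-out fold
    with the self-normalized IPW value estimator under the logged
    propensities.  Returns the per-fold value estimates.
    """
    from .evaluation import ipw_cv_value
    from .history import TrialHistory as TH

    if not isinstance(logged, TrialHistory):
        logged = TH.from_frame(logged)
    rng = as_rng(rng if rng is not None else config.seed)
    n = len(logged)
    if n_folds < 2 or n_folds > n:
        raise ConfigurationError("n_folds must be in [2, n_records]")
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    df = logged.to_frame()
    values = np.empty(n_folds)
    for k, hold in enumerate(folds):
        hold_set = np.zeros(n, dtype=bool)
        hold_set[hold] = True
        train = TH.from_frame(df.loc[~hold_set].reset_index(drop=True))
        test = TH.from_frame(df.loc[hold_set].reset_index(drop=True))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = replay_trial(train, config, rng=rng)
        values[k] = ipw_cv_value(test, result.final_rule)
    return values
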