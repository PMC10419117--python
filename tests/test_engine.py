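"""The sequential trial loop: pilot, assignment bookkeeping, determinism,
and the logged-data replay."""
import warnings

import numpy as np
import pytest

from conftest import make_randomized_history
from srat.basis import Basis
from srat.engine import (
    TrialConfig,
    decide_treatment,
    kfold_replay_value,
    replay_trial,
    run_pilot,
    run_trial,
)
from srat.history import TrialHistory
from srat.owl import DecisionFunction
from srat.policies import EpsilonGreedyPolicy


def _flat_rule(d=10):
    coef = np.zeros(d)
    coef[0] = 1.0
    return DecisionFunction(Basis("linear"), intercept=0.0, coef=coef)


class TestPilot:
    def test_default_pilot(self, spec1):
        hist = run_pilot(30, spec1, np.random.default_rng(0))
        assert len(hist) == 30
        assert np.all(hist.propensity == 0.5)
        assert np.all(hist.phase == "pilot")
        assert set(hist.A) <= {-1, 1}

    def test_empty_pilot_rejected(self, spec1):
        with pytest.raises(ValueError):
            run_pilot(0, spec1, np.random.default_rng(0))

    def test_fair_coin_arms(self, spec1):
        hist = run_pilot(4000, spec1, np.random.default_rng(1))
        assert np.mean(hist.A == 1) == pytest.approx(0.5, abs=0.03)


class TestDecideTreatment:
    def test_propensity_complementarity(self, spec1):
        """The recorded propensity is that of the realized arm; following
        and deviating propensities sum to one."""
        rng = np.random.default_rng(2)
        policy = EpsilonGreedyPolicy(eps0=0.1, theta=1.0)
        f = _flat_rule()
        x = np.zeros(10)
        x[0] = 0.7
        for _ in range(50):
            arm, follow, prop, p = decide_treatment(f, x, 3, policy, rng, Basis("linear"))
            assert arm == follow * f.decide(x)
            assert prop == pytest.approx(p if follow == 1 else 1 - p)

    def test_empirical_follow_rate(self, spec1):
        rng = np.random.default_rng(3)
        policy = EpsilonGreedyPolicy(eps0=0.1, theta=1.0)  # p = 0.9
        f = _flat_rule()
        x = np.zeros(10)
        x[0] = -0.4
        follows = [
            decide_treatment(f, x, 1, policy, rng, Basis("linear"))[1]
            for _ in range(10_000)
        ]
        assert np.mean(np.array(follows) == 1) == pytest.approx(0.9, abs=0.01)


class TestRunTrial:
    def test_rct_probabilities_constant(self):
        cfg = TrialConfig(policy="rct", n0=10, n=20, seed=4)
        result = run_trial(cfg)
        assert np.all(result.p == 0.5)
        assert np.all(result.eps == 0.5)

    def test_fixed_seed_reproducible(self):
        cfg = TrialConfig(
            policy="srat_e", policy_params={"eps0": 0.1, "theta": 0.5},
            n0=10, n=15, seed=5,
        )
        r1, r2 = run_trial(cfg), run_trial(cfg)
        assert np.array_equal(r1.checkpoints, r2.checkpoints)
        assert np.array_equal(r1.history.R, r2.history.R)
        assert np.array_equal(r1.p, r2.p)

    def test_zero_main_phase(self):
        result = run_trial(TrialConfig(n0=12, n=0, seed=6))
        assert result.checkpoints.shape[0] == 1
        assert len(result.history) == 12
        assert result.n_main == 0

    def test_bookkeeping_identity(self):
        """A_i * I_i equals the decision of the rule in force (the
        checkpoint fitted before patient i arrived)."""
        cfg = TrialConfig(
            policy="srat_e", policy_params={"eps0": 0.2, "theta": 0.3},
            n0=15, n=40, seed=7,
        )
        result = run_trial(cfg)
        hist = result.history
        main = hist.mask("main")
        X, A, I = hist.X[main], hist.A[main], hist.follow[main]
        for i in range(1, result.n_main):  # final checkpoint is refit tighter
            rule = result.rule_at(i - 1)
            assert A[i - 1] * I[i - 1] == rule.decide(X[i - 1])

    def test_truncation_band_respected(self):
        cfg = TrialConfig(
            policy="srat_b", policy_params={"eps0": 0.1, "theta": 0.01},
            n0=15, n=60, seed=8,
        )
        result = run_trial(cfg)
        assert np.all(result.p >= result.eps - 1e-12)
        assert np.all(result.p <= 1 - result.eps + 1e-12)

    def test_phases_partition_history(self):
        result = run_trial(TrialConfig(n0=10, n=25, seed=9))
        assert len(result.history) == 35
        assert np.sum(result.history.mask("pilot")) == 10
        assert np.sum(result.history.mask("main")) == 25

    def test_linucb_runs_with_unit_propensity(self):
        result = run_trial(TrialConfig(policy="linucb", n0=10, n=30, seed=10))
        main = result.history.mask("main")
        assert np.all(result.history.propensity[main] == 1.0)
        assert result.checkpoints.shape == (31, 11)


class TestReplay:
    def test_keep_rate_near_half(self, spec1):
        """Logged fair-coin arms are independent of any suggestion, so
        about half of the candidates are kept."""
        rng = np.random.default_rng(11)
        logged = make_randomized_history(spec1, 3000, rng)
        cfg = TrialConfig(policy="srat_e", policy_params={"eps0": 0.1, "theta": 1.0},
                          n0=20, n=10_000, refit_interval=None, seed=12)
        with pytest.warns(UserWarning, match="exhausted"):
            result = replay_trial(logged, cfg)
        keep_rate = len(result.history) / 3000
        assert keep_rate == pytest.approx(0.5, abs=0.03)

    def test_stream_exhaustion_warns(self, spec1):
        rng = np.random.default_rng(13)
        logged = make_randomized_history(spec1, 8, rng)
        cfg = TrialConfig(n0=30, n=10, seed=14)
        with pytest.warns(UserWarning, match="pilot"):
            result = replay_trial(logged, cfg)
        assert len(result.history) < 30

    def test_replay_improves_on_logged_mean_reward(self, spec1):
        """Replaying a greedy adaptive design through a logged RCT yields a
        higher training mean reward than the logged stream itself."""
        rng = np.random.default_rng(15)
        diffs = []
        for rep in range(15):
            logged = make_randomized_history(spec1, 700, np.random.default_rng(100 + rep))
            cfg = TrialConfig(
                policy="srat_e", policy_params={"eps0": 0.1, "theta": 0.01},
                n0=30, n=250, seed=200 + rep,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = replay_trial(logged, cfg)
            main = result.history.mask("main")
            diffs.append(np.mean(result.history.R[main]) - np.mean(logged.R))
        assert np.mean(diffs) > 0

    def test_kfold_replay_values_finite(self, spec1):
        rng = np.random.default_rng(16)
        logged = make_randomized_history(spec1, 400, rng)
        cfg = TrialConfig(policy="srat_e", policy_params={"eps0": 0.1, "theta": 1.0},
                          n0=15, n=60, seed=17)
        values = kfold_replay_value(logged, cfg, n_folds=4)
        assert values.shape == (4,)
        assert np.all(np.isfinite(values))


class TestHistoryTable:
    def test_roundtrip(self, spec1):
        result = run_trial(TrialConfig(n0=8, n=12, seed=18))
        df = result.history.to_frame()
        assert list(df.columns[:10]) == [f"X{j}" for j in range(1, 11)]
        back = TrialHistory.from_frame(df)
        assert np.allclose(back.X, result.history.X)
        assert np.array_equal(back.A, result.history.A)
        assert np.allclose(back.propensity, result.history.propensity)
        assert list(back.phase) == list(result.history.phase)

    def test_append_validation(self):
        hist = TrialHistory(3)
        with pytest.raises(ValueError):
            hist.append(np.zeros(2), 1, 0.0, 0.5)
        with pytest.raises(ValueError):
            hist.append(np.zeros(3), 2, 0.0, 0.5)
        with pytest.raises(ValueError):
            hist.append(np.zeros(3), 1, 0.0, 0.0)
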