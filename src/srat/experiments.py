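"""Replicate sweeps, aggregation, rate-slope fits and sample-size search.

A sweep runs one trial per (cell, replicate) where a cell is a combination
of policy, eps0, theta and n, and reduces each trial to replicate-level
metrics (training/test regret, false-decision ratios, mean reward).
Replicate r of cell c is seeded from (base_seed, c, r), so distinct cells
and replicates never share a random stream and the whole table is a pure
function of the sweep specification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .engine import TrialConfig, run_trial
from .evaluation import evaluate_trial
from .owl import OWLConfig
from .scenarios import ScenarioSpec, get_scenario, sample_covariates

SCHEDULED_POLICIES = ("srat_e", "srat_b")


@dataclass
class SweepSpec:
    """Grid specification for a replicate sweep."""

    scenario: Union[str, ScenarioSpec] = "scenario1"
    policies: Sequence[str] = ("srat_e",)
    n_grid: Sequence[int] = (100, 200, 400, 800)
    theta_grid: Sequence[float] = (0.01, 0.5, 1.0)
    eps0_grid: Sequence[float] = (0.5,)
    n_reps: int = 100
    base_seed: int = 0
    n0: int = 30
    alpha: float = 0.2
    gamma_base: float = 0.999
    mc_size: int = 20_000
    refit_interval: Optional[int] = 1
    refit_tol: float = 0.02
    owl: Optional[OWLConfig] = None

    def cells(self) -> list[dict]:
        """Enumerate grid cells; policies without a schedule collapse the
        (eps0, theta) axes."""
        out = []
        for pol in self.policies:
            if pol in SCHEDULED_POLICIES:
                combos = [(e, t) for e in self.eps0_grid for t in self.theta_grid]
            else:
                combos = [(np.nan, np.nan)]
            for eps0, theta in combos:
                for n in self.n_grid:
                    out.append({"policy": pol, "eps0": eps0, "theta": theta, "n": n})
        return out


def _policy_params(spec: SweepSpec, cell: dict) -> dict:
    if cell["policy"] == "srat_e":
        return {"eps0": cell["eps0"], "theta": cell["theta"]}
    if cell["policy"] == "srat_b":
        return {
            "eps0": cell["eps0"],
            "theta": cell["theta"],
            "alpha": spec.alpha,
            "gamma_base": spec.gamma_base,
        }
    if cell["policy"] == "linucb":
        return {"alpha": spec.alpha}
    return {}


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Run the sweep; one row per (cell, replicate).

    Per-cell failures are recorded (column ``error``) without aborting the
    sweep.
    """
    scenario = get_scenario(spec.scenario)
    rows = []
    for cell_idx, cell in enumerate(spec.cells()):
        for rep in range(spec.n_reps):
            seed_key = [spec.base_seed, cell_idx, rep]
            row = dict(cell, rep=rep, cell=cell_idx)
            try:
                cfg = TrialConfig(
                    scenario=scenario,
                    policy=cell["policy"],
                    policy_params=_policy_params(spec, cell),
                    n0=spec.n0,
                    n=int(cell["n"]),
                    owl=spec.owl,
                    refit_interval=spec.refit_interval,
                    refit_tol=spec.refit_tol,
                )
                rng = np.random.default_rng(seed_key)
                result = run_trial(cfg, rng=rng)
                X_test = sample_covariates(spec.mc_size, scenario, rng)
                row.update(evaluate_trial(result, scenario, X_test))
                row["error"] = ""
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"cell {cell} rep {rep} failed: {exc}", stacklevel=2)
                row["error"] = str(exc)
            rows.append(row)
        if progress:
            print(f"cell {cell_idx + 1}/{len(spec.cells())} done: {cell}")
    return pd.DataFrame(rows)


METRICS = (
    "train_regret",
    "test_regret",
    "train_fdr",
    "test_fdr",
    "train_correct",
    "test_correct",
    "mean_reward",
)


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error over replicates per cell, with log-scale
    columns for rate fits."""
    ok = table[table.get("error", "") == ""] if "error" in table else table
    keys = ["policy", "eps0", "theta", "n"]
    present = [m for m in METRICS if m in ok.columns]
    grouped = ok.groupby(keys, dropna=False)[present]
    agg = grouped.agg(["mean", "sem", "count"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg = agg.reset_index()
    for m in ("train_regret", "test_regret"):
        col = f"{m}_mean"
        if col in agg:
            with np.errstate(invalid="ignore", divide="ignore"):
                agg[f"log_{m}"] = np.log(agg[col].where(agg[col] > 0))
    agg["log_n"] = np.log(agg["n"].astype(float))
    return agg


def fit_log_slope(
    table: pd.DataFrame,
    metric: str = "test_regret",
    grouping: Sequence[str] = ("policy", "eps0", "theta"),
) -> pd.DataFrame:
    """Least-squares slope of log(mean metric) on log(n) per group.

    Nonpositive cell means are excluded with a warning; groups with fewer
    than 3 usable sample sizes are dropped.
    """
    agg = table if f"{metric}_mean" in table.columns else aggregate(table)
    col = f"{metric}_mean"
    rows = []
    for key, grp in agg.groupby(list(grouping), dropna=False):
        vals = grp[[col, "n"]].dropna()
        pos = vals[vals[col] > 0]
        if len(pos) < len(vals):
            warnings.warn(
                f"group {key}: excluded {len(vals) - len(pos)} nonpositive "
                f"{metric} values from the log fit",
                stacklevel=2,
            )
        if pos["n"].nunique() < 3:
            continue
        slope = np.polyfit(np.log(pos["n"].astype(float)), np.log(pos[col]), 1)[0]
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(grouping, key), slope=float(slope)))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SampleSizeResult:
    achievable: bool
    n: Optional[int] = None
    theta: Optional[float] = None


def sample_size_search(
    table: pd.DataFrame, train_req: float, test_req: float
) -> SampleSizeResult:
    """Smallest n on the grid at which some theta satisfies both
    correct-decision requirements; among qualifying theta at that n, the
    largest is reported (larger theta yields the better final rule).
    """
    agg = table if "train_correct_mean" in table.columns else aggregate(table)
    ok = agg[
        (agg["train_correct_mean"] >= train_req)
        & (agg["test_correct_mean"] >= test_req)
    ]
    if ok.empty:
        return SampleSizeResult(achievable=False)
    n_min = int(ok["n"].min())
    theta = float(ok.loc[ok["n"] == n_min, "theta"].max())
    return SampleSizeResult(achievable=True, n=n_min, theta=theta)
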