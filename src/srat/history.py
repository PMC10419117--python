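"""Per-patient records and trial histories.

A history holds the pilot and main-trial segments of a sequential trial as
column arrays: covariates X, realized arm A in {-1, +1}, reward R, the
follow indicator I in {-1, +1} (main phase only; A = I * d(X) where d is the
rule in force), the propensity pi of the realized arm, the follow
probability p, and the phase label.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import PositivityError

PILOT = "pilot"
MAIN = "main"


@dataclass
class PatientRecord:
    """One patient's row; ``follow`` is None for pilot records."""

    x: np.ndarray
    a: int
    r: float
    propensity: float
    phase: str = MAIN
    follow: Optional[int] = None
    p: Optional[float] = None
    step: int = 0


class TrialHistory:
    """Append-only store of patient records with array views."""

    def __init__(self, d: int):
        self.d = d
        self._x: list[np.ndarray] = []
        self._a: list[int] = []
        self._r: list[float] = []
        self._pi: list[float] = []
        self._i: list[float] = []
        self._p: list[float] = []
        self._phase: list[str] = []

    def append(self, x, a, r, propensity, phase=MAIN, follow=None, p=None):
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != self.d:
            raise ValueError(f"covariate dimension {x.shape[0]} != {self.d}")
        if a not in (-1, 1):
            raise ValueError("arm must be -1 or +1")
        # deterministic policies (LinUCB) record propensity exactly 1;
        # IPW-weighted fits separately require propensities in (0, 1)
        if not 0.0 < propensity <= 1.0:
            raise PositivityError(f"propensity {propensity} outside (0, 1]")
        self._x.append(x)
        self._a.append(int(a))
        self._r.append(float(r))
        self._pi.append(float(propensity))
        self._i.append(np.nan if follow is None else float(follow))
        self._p.append(np.nan if p is None else float(p))
        self._phase.append(phase)

    def __len__(self):
        return len(self._a)

    @property
    def X(self) -> np.ndarray:
        return np.array(self._x).reshape(len(self), self.d)

    @property
    def A(self) -> np.ndarray:
        return np.array(self._a, dtype=int)

    @property
    def R(self) -> np.ndarray:
        return np.array(self._r)

    @property
    def propensity(self) -> np.ndarray:
        return np.array(self._pi)

    @property
    def follow(self) -> np.ndarray:
        return np.array(self._i)

    @property
    def p(self) -> np.ndarray:
        return np.array(self._p)

    @property
    def phase(self) -> np.ndarray:
        return np.array(self._phase)

    def mask(self, phase: str) -> np.ndarray:
        return self.phase == phase

    def records(self) -> list[PatientRecord]:
        out = []
        for k in range(len(self)):
            follow = None if np.isnan(self._i[k]) else int(self._i[k])
            p = None if np.isnan(self._p[k]) else self._p[k]
            out.append(
                PatientRecord(
                    x=self._x[k], a=self._a[k], r=self._r[k],
                    propensity=self._pi[k], phase=self._phase[k],
                    follow=follow, p=p, step=k,
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Delimited-table view: X1..Xd, A, R, I, propensity, p, phase, step."""
        df = pd.DataFrame(self.X, columns=[f"X{j + 1}" for j in range(self.d)])
        df["A"] = self.A
        df["R"] = self.R
        df["I"] = self.follow
        df["propensity"] = self.propensity
        df["p"] = self.p
        df["phase"] = self.phase
        df["step"] = np.arange(len(self))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialHistory":
        """Build a history from a logged-trial table with columns X1..Xd,
        A, R, propensity and optionally I, p, phase."""
        xcols = sorted(
            (c for c in df.columns if c.startswith("X") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not xcols:
            raise ValueError("no covariate columns X1..Xd found")
        hist = cls(d=len(xcols))
        X = df[xcols].to_numpy(dtype=float)
        has_i = "I" in df.columns
        has_p = "p" in df.columns
        phases = df["phase"] if "phase" in df.columns else None
        for k in range(len(df)):
            follow = None
            if has_i and not pd.isna(df["I"].iloc[k]):
                follow = int(df["I"].iloc[k])
            hist.append(
                X[k],
                int(df["A"].iloc[k]),
                float(df["R"].iloc[k]),
                float(df["propensity"].iloc[k]),
                phase=str(phases.iloc[k]) if phases is not None else MAIN,
                follow=follow,
                p=float(df["p"].iloc[k]) if has_p and not pd.isna(df["p"].iloc[k]) else None,
            )
        return hist
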