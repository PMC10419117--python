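"""Dual SMO solver for the weighted hinge loss with ridge penalty.

Solves, in the scaled form used internally,

    min_{v, b}  0.5 ||v||^2 + sum_i C_i [1 - y_i (v . x_i + b)]_+

with an *unpenalized* intercept b, via the dual box-constrained QP

    min_a  0.5 a' Q a - e' a,   0 <= a_i <= C_i,  sum_i y_i a_i = 0,

where Q_ij = y_i y_j x_i . x_j.  Working pairs are chosen by second-order
selection (the libsvm rule): the first index maximizes the KKT violation
over the "up" set, the second maximizes the guaranteed objective decrease
over the "down" set.  The stopping rule is the maximal-violating-pair gap
m(a) - M(a) <= tol.

The solver supports warm starts from a previous dual vector: sequential
refits (one new observation per refit, mildly perturbed weights) then
converge in a small number of pair updates.  New observations are pre-seeded
at the box bound their margin indicates before the equality constraint is
repaired.

The caller maps the trial objective (1/n) sum w_i hinge + lam ||beta||^2
onto this form with C_i = w_i / (2 * lam * n); then beta = v, intercept = b.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _smo_kernel(X, y, C, alpha, tol, max_pairs):
    n, p = X.shape
    w = np.zeros(p)
    for t in range(n):
        ay = alpha[t] * y[t]
        if ay != 0.0:
            for k in range(p):
                w[k] += ay * X[t, k]
    G = np.empty(n)  # G_t = y_t (w . x_t) - 1, the dual gradient
    diag = np.empty(n)
    for t in range(n):
        s = 0.0
        q = 0.0
        for k in range(p):
            s += w[k] * X[t, k]
            q += X[t, k] * X[t, k]
        G[t] = y[t] * s - 1.0
        diag[t] = q
    m = 0.0
    M = 0.0
    pairs = 0
    ki = np.empty(n)  # row i of the kernel matrix, for second-order selection
    while pairs < max_pairs:
        # first index: maximal violation over the up set
        i = -1
        m = -1e300
        M = 1e300
        for t in range(n):
            v = -y[t] * G[t]
            if (y[t] > 0 and alpha[t] < C[t]) or (y[t] < 0 and alpha[t] > 0.0):
                if v > m:
                    m = v
                    i = t
            if (y[t] > 0 and alpha[t] > 0.0) or (y[t] < 0 and alpha[t] < C[t]):
                if v < M:
                    M = v
        if i < 0 or m - M <= tol:
            break
        for t in range(n):
            s = 0.0
            for k in range(p):
                s += X[i, k] * X[t, k]
            ki[t] = s
        # second index: maximal guaranteed decrease among violators
        j = -1
        best = 0.0
        for t in range(n):
            if (y[t] > 0 and alpha[t] > 0.0) or (y[t] < 0 and alpha[t] < C[t]):
                v = -y[t] * G[t]
                bt = m - v
                if bt > 0.0:
                    at = diag[i] + diag[t] - 2.0 * ki[t]
                    if at < 1e-12:
                        at = 1e-12
                    sc = bt * bt / at
                    if sc > best:
                        best = sc
                        j = t
        if j < 0:
            break
        eta = diag[i] + diag[j] - 2.0 * ki[j]
        if eta < 1e-12:
            eta = 1e-12
        d = (-y[i] * G[i] + y[j] * G[j]) / eta
        # box limits along the feasible direction alpha_i += y_i d, alpha_j -= y_j d
        lim_i = (C[i] - alpha[i]) if y[i] > 0 else alpha[i]
        lim_j = alpha[j] if y[j] > 0 else (C[j] - alpha[j])
        if lim_i < d:
            d = lim_i
        if lim_j < d:
            d = lim_j
        if d <= 0.0:
            break
        alpha[i] += y[i] * d
        alpha[j] -= y[j] * d
        for t in range(n):
            s = ki[t]
            for k in range(p):
                s -= X[j, k] * X[t, k]
            G[t] += y[t] * s * d
        for k in range(p):
            w[k] += d * (X[i, k] - X[j, k])
        pairs += 1
    # intercept: free support vectors satisfy b = -y_t G_t; the pair bounds
    # m, M bracket it, so (m + M) / 2 is used when no vector is free.
    nfree = 0
    bsum = 0.0
    for t in range(n):
        if 0.0 < alpha[t] < C[t]:
            nfree += 1
            bsum += -y[t] * G[t]
    if nfree > 0:
        b = bsum / nfree
    else:
        b = 0.5 * (m + M)
    return w, b, pairs, m - M


def solve_weighted_hinge(
    X: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    tol: float = 1e-6,
    alpha0: np.ndarray | None = None,
    max_pairs: int | None = None,
) -> tuple[np.ndarray, float, np.ndarray, int, float]:
    """Solve the scaled problem; returns (v, b, alpha, n_pairs, gap).

    ``alpha0`` warm-starts the dual vector; it is clipped to the current box,
    appended observations are pre-seeded at the bound their current margin
    indicates, and the equality constraint sum_i y_i alpha_i = 0 is repaired
    before iterating.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    C = np.ascontiguousarray(C, dtype=np.float64)
    n = X.shape[0]
    if alpha0 is None:
        alpha = np.zeros(n)
    else:
        old = np.asarray(alpha0, dtype=np.float64)
        n_old = min(old.shape[0], n)
        alpha = np.zeros(n)
        alpha[:n_old] = old[:n_old]
        np.clip(alpha, 0.0, C, out=alpha)
        if n_old < n:
            # seed new points at the bound suggested by the incumbent margin
            v = X.T @ (alpha * y)
            margin = y[n_old:] * (X[n_old:] @ v)
            alpha[n_old:] = np.where(margin < 1.0, C[n_old:], 0.0)
        _repair_equality(alpha, y, C)
    if max_pairs is None:
        max_pairs = max(200_000, 400 * n)
    w, b, pairs, gap = _smo_kernel(X, y, C, alpha, float(tol), int(max_pairs))
    return w, float(b), alpha, int(pairs), float(gap)


def _repair_equality(alpha: np.ndarray, y: np.ndarray, C: np.ndarray) -> None:
    """Restore sum_i y_i alpha_i = 0 in place.

    Surplus dual mass is first shed by shrinking components on the surplus
    side (largest first); if the surplus side has no mass to shed the
    deficit side is grown within its box instead.
    """
    s = float(np.dot(y, alpha))
    if s == 0.0:
        return
    side = 1.0 if s > 0 else -1.0
    excess = abs(s)
    idx = np.where((y == side) & (alpha > 0))[0]
    order = idx[np.argsort(-alpha[idx])]
    for t in order:
        if excess <= 0:
            break
        take = min(alpha[t], excess)
        alpha[t] -= take
        excess -= take
    if excess > 1e-12:
        idx = np.where((y == -side) & (alpha < C))[0]
        for t in idx:
            if excess <= 0:
                break
            take = min(C[t] - alpha[t], excess)
            alpha[t] += take
            excess -= take
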