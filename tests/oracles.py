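"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and where possible the libraries)
they validate: normal equations solved directly, BH step-up written long
form, Pearson chi-square summed term by term, the Cox partial likelihood
maximized by dense grid search, and the Kaplan-Meier product limit taken
factor by factor.
"""

from __future__ import annotations

import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Solve the least-squares problem via the normal equations X'X b = X'y.

    Returns (coefficients, residual_sd) with the residual SD using
    denominator n - p (unbiased).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    return beta, float(np.sqrt(resid @ resid / df))


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, written long form."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


def pearson_longform(observed, expected) -> float:
    """Pearson goodness-of-fit statistic summed term by term."""
    total = 0.0
    for o, e in zip(observed, expected):
        total += (o - e) ** 2 / e
    return total


def cox_loglik(beta: float, durations, events, x) -> float:
    """Log partial likelihood of a one-covariate Cox model (distinct event
    times assumed, so Breslow/Efron/exact coincide)."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.where(events)[0]:
        at_risk = durations >= durations[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def cox_grid_mle(durations, events, x, lo=-5.0, hi=5.0, n=200001) -> float:
    """Maximize the partial likelihood over a dense beta grid."""
    grid = np.linspace(lo, hi, n)
    lls = [cox_loglik(b, durations, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])


def product_limit(durations, events):
    """Kaplan-Meier survival curve computed factor by factor.

    Returns (event_times, S(t) just after each event time).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    times = np.unique(durations[events])
    s = 1.0
    surv = []
    for t in times:
        n_risk = np.sum(durations >= t)
        d = np.sum((durations == t) & events)
        s *= 1.0 - d / n_risk
        surv.append(s)
    return times, np.asarray(surv)
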