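"""Hand-written survival oracles, independent of the package implementation.

Brute-force Efron partial likelihood (grid search), product-limit estimate,
log-rank observed-minus-expected computation, and the Cox score statistic at
beta = 0. Used to cross-check the lifelines-backed survival module.
"""

from __future__ import annotations

import numpy as np


def efron_log_partial_likelihood(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> float:
    """Efron-approximation log partial likelihood for one covariate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    risk = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(dead.sum())
        s_risk = risk[at_risk].sum()
        s_dead = risk[dead].sum()
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(s_risk - (ell / d) * s_dead)
    return float(ll)


def grid_search_cox(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    lo: float = -4.0,
    hi: float = 4.0,
    step: float = 1e-4,
) -> float:
    """Argmax of the Efron partial likelihood over a uniform beta grid."""
    grid = np.arange(lo, hi + step, step)
    ll = np.array(
        [efron_log_partial_likelihood(b, time, event, x) for b in grid]
    )
    return float(grid[np.argmax(ll)])


def km_by_hand(time: np.ndarray, event: np.ndarray) -> dict[float, float]:
    """Product-limit estimate at each event time (censored-at-t stay at risk)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    s = 1.0
    out: dict[float, float] = {}
    for t in np.unique(time[event == 1]):
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= (n - d) / n
        out[float(t)] = s
    return out


def logrank_by_hand(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> float:
    """Two-group unweighted log-rank chi-square (hypergeometric variance)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    assert len(levels) == 2
    g1 = group == levels[1]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        n = int(at_risk.sum())
        d = int(dead.sum())
        n1 = int((at_risk & g1).sum())
        d1 = int((dead & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def cox_score_statistic_at_zero(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> float:
    """Squared Cox score test statistic U(0)^2 / I(0), Breslow form.

    Equals the log-rank chi-square when no event times are tied.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    u = 0.0
    info = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        xr = x[at_risk]
        u += x[dead].sum() - d * xr.mean()
        info += d * xr.var()  # population variance over the risk set
    return float(u**2 / info)
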