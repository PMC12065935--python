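"""Independent oracles used by the test suite.

Everything here is deliberately naive — dense grid search, hand product-limit
arithmetic, brute-force partial-likelihood maximization, exhaustive pair
counting — and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def grid_search_fit(days, normalized, model: str, n_grid: int = 120,
                    lo: float = 1e-5, hi: float = 5e-2):
    """Dense log-grid least squares for the 1- and 2-parameter models.

    Returns ``(params_dict, rss)`` at the best grid node.
    """
    t = np.asarray(days, float)[1:]
    y = np.asarray(normalized, float)[1:]
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    if model == "dx":
        preds = np.exp(-grid[:, None] * t[None, :])
        rss = ((preds - y) ** 2).sum(axis=1)
        i = int(np.argmin(rss))
        return {"d": grid[i]}, float(rss[i])
    if model == "gx":
        preds = np.exp(grid[:, None] * t[None, :])
        rss = ((preds - y) ** 2).sum(axis=1)
        i = int(np.argmin(rss))
        return {"g": grid[i]}, float(rss[i])
    if model == "gd":
        gg, dd = np.meshgrid(grid, grid, indexing="ij")
        preds = (np.exp(-dd[..., None] * t) + np.exp(gg[..., None] * t) - 1.0)
        rss = ((preds - y) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        return {"g": grid[i], "d": grid[j]}, float(rss[i, j])
    raise ValueError(model)


def km_product_limit(times, events):
    """Hand Kaplan-Meier: returns (event_times, survival_after_each_time)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out_t, out_s = [], []
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= (at_risk - d) / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def cox_brute_force(times, events, x):
    """Maximize the (Breslow) log partial likelihood for one covariate.

    Valid as an oracle for Efron fits when event times are distinct, in
    which case the two tie conventions coincide.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ev = times[events == 1]
    assert len(set(ev)) == len(ev), "oracle requires distinct event times"

    def neg_lpl(beta: float) -> float:
        total = 0.0
        for i in np.flatnonzero(events == 1):
            risk = times >= times[i]
            total += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -total

    res = optimize.minimize_scalar(neg_lpl, bounds=(-50, 50), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def harrell_c_pairs(times, events, risk):
    """Exhaustive pair-counting Harrell concordance.

    Comparable pair: the member with the shorter time had an event.  Scores
    1 when the higher-risk member failed earlier, 0.5 on risk ties.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = np.asarray(risk, float)
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den
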