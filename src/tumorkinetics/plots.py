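"""Optional plotting helpers (KM curves by stratum, g distributions)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import QuartileAssignment, _merge_survival, STRATA_ORDER


def plot_km_by_stratum(assignment: QuartileAssignment, survival: pd.DataFrame,
                       endpoint: str = "os", ax=None):
    """Kaplan-Meier curves for dx and Q1-Q4 on one axis."""
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = _merge_survival(assignment, survival, endpoint)
    for stratum in STRATA_ORDER:
        sub = df[df["stratum"] == stratum]
        if sub.empty:
            continue
        kmf = KaplanMeierFitter()
        label = "No growth (dx)" if stratum == "dx" else stratum
        kmf.fit(sub["time"], sub["event"], label=label)
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("days")
    ax.set_ylabel(f"{endpoint.upper()} probability")
    return ax


def plot_g_distribution(results_frame: pd.DataFrame, survival: pd.DataFrame, ax=None):
    """Per-arm strip/box display of the fitted g distribution."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = results_frame.merge(survival[["subject_id", "arm"]], on="subject_id")
    df = df[df["g_per_day"].notna()]
    arms = sorted(df["arm"].unique())
    data = [df.loc[df["arm"] == a, "g_per_day"] * 100 for a in arms]
    ax.boxplot(data, tick_labels=arms, showfliers=False)
    rng = np.random.default_rng(0)  # display jitter only
    for i, vals in enumerate(data, start=1):
        ax.scatter(i + rng.uniform(-0.15, 0.15, len(vals)), vals, s=6, alpha=0.4)
    ax.set_ylabel("g (x 10$^{-2}$/day)")
    return ax
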