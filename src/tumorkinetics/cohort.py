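"""Cohort-level association of tumor growth rate with survival.

Given per-subject fitting results and a survival table this module provides
the analyses reported for the trials: arm comparison of g by Mann-Whitney,
quartile construction on pooled growers (decay-only ``dx`` subjects held as
their own "no growth" stratum), Kaplan-Meier summaries and Cox hazard ratios
per stratum versus the fastest quartile Q4, Harrell concordance of g versus
categorical tumor response as predictors of survival, the same quartile
machinery applied to the decay rate d, and interim "early look" analyses
that refit g from the scans available when the k-th randomized subject has
been followed 14 weeks.

Survival estimation is delegated to lifelines (Kaplan-Meier product-limit,
Cox proportional hazards with Efron tie handling, Harrell's C); the
quartile/stratum construction and the trial-specific conventions live here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .fitting import SubjectResult, classify_subject, fit_cohort, results_to_frame, TumorTrajectory

__all__ = [
    "QuartileAssignment",
    "ArmComparison",
    "CohortAnalysis",
    "EarlyLookResult",
    "compare_arms_g",
    "assign_quartiles",
    "km_by_stratum",
    "cox_by_stratum",
    "concordance_comparison",
    "quartile_analysis_on_d",
    "early_look",
    "analyze_cohort",
    "classification_counts",
]

STRATA_ORDER = ("dx", "Q1", "Q2", "Q3", "Q4")


def _safe_exp(x: float) -> float:
    """exp() that saturates instead of overflowing (huge Wald CI limits)."""
    if x > 700:
        return math.inf
    return math.exp(x)
_ENDPOINTS = {"os": ("os_days", "os_event"), "pfs": ("pfs_days", "pfs_event")}


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    return results_to_frame(list(results))


def _modeled(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["classification"].isin(["dx", "gx", "gd", "gdphi"])]


@dataclass
class QuartileAssignment:
    """g (or d) cutpoints plus the per-subject stratum labels.

    ``strata`` maps subject_id -> one of dx/Q1/Q2/Q3/Q4; ``thresholds`` are
    the three pooled cutpoints.  By default cutpoints are computed over
    subjects with value > 0 only, with the g = 0 (dx) subjects held out as
    their own stratum; set ``include_zero_in_cutpoints`` when calling
    :func:`assign_quartiles` for the alternative convention.
    """

    thresholds: tuple[float, float, float]
    strata: pd.Series  # index subject_id, values in STRATA_ORDER
    value_name: str = "g"

    def counts(self) -> pd.Series:
        return self.strata.value_counts().reindex(STRATA_ORDER, fill_value=0)


@dataclass
class ArmComparison:
    """Arm-level summary of the g distribution with a Mann-Whitney test."""

    median: dict[str, float]
    iqr: dict[str, tuple[float, float]]
    n: dict[str, int]
    u_statistic: float
    p_value: float


@dataclass
class EarlyLookResult:
    """Interim g analysis at a data cutoff defined by subject accrual."""

    k: int
    cutoff_day: float
    comparison: ArmComparison
    results: pd.DataFrame
    n_evaluable: int


@dataclass
class CohortAnalysis:
    """Bundle of every cohort-level output for reporting."""

    arm_comparison: ArmComparison
    classification_counts: pd.DataFrame
    quartiles: QuartileAssignment
    km_os: pd.DataFrame
    km_pfs: pd.DataFrame
    cox_os: pd.DataFrame
    cox_pfs: pd.DataFrame
    concordance: pd.DataFrame
    per_arm_km_os: dict[str, pd.DataFrame] = field(default_factory=dict)
    per_arm_cox_os: dict[str, pd.DataFrame] = field(default_factory=dict)


def compare_arms_g(
    results,
    survival: pd.DataFrame,
    *,
    value: str = "g_per_day",
) -> ArmComparison:
    """Median/IQR of g per arm and a two-sided Mann-Whitney test.

    Only subjects whose trajectory fit one of the four models contribute;
    dx subjects enter with g = 0.
    """
    df = _modeled(_as_frame(results)).merge(
        survival[["subject_id", "arm"]], on="subject_id", how="inner"
    )
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"expected exactly 2 arms, got {arms}")
    groups = {arm: df.loc[df["arm"] == arm, value].to_numpy(dtype=float) for arm in arms}
    for arm, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"arm {arm!r} has fewer than 2 modeled subjects")

    a, b = groups[arms[0]], groups[arms[1]]
    if np.ptp(np.concatenate([a, b])) == 0:
        u, p = len(a) * len(b) / 2.0, 1.0  # all values identical: no evidence
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ArmComparison(
        median={arm: float(np.median(v)) for arm, v in groups.items()},
        iqr={
            arm: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
            for arm, v in groups.items()
        },
        n={arm: int(len(v)) for arm, v in groups.items()},
        u_statistic=float(u),
        p_value=float(p),
    )


def assign_quartiles(
    results,
    *,
    value: str = "g_per_day",
    include_zero_in_cutpoints: bool = False,
) -> QuartileAssignment:
    """Quartile strata from the pooled distribution of g (both arms).

    Subjects with g = 0 (dx) form the separate "no growth" stratum; the
    three cutpoints are the 25/50/75th percentiles of the g > 0 subjects
    (default) or of all modeled subjects (``include_zero_in_cutpoints``).
    Values at a cutpoint go to the lower quartile.
    """
    df = _modeled(_as_frame(results)).set_index("subject_id")
    vals = df[value].astype(float)
    positive = vals[vals > 0]
    if positive.empty:
        raise ValueError(f"no subjects with {value} > 0; quartiles undefined")
    basis = vals if include_zero_in_cutpoints else positive
    q1, q2, q3 = (float(np.percentile(basis, p)) for p in (25, 50, 75))

    def stratum(v: float) -> str:
        if v <= 0:
            return "dx"
        if v <= q1:
            return "Q1"
        if v <= q2:
            return "Q2"
        if v <= q3:
            return "Q3"
        return "Q4"

    strata = vals.map(stratum)
    strata.name = "stratum"
    return QuartileAssignment((q1, q2, q3), strata, value_name=value)


def _merge_survival(assignment: QuartileAssignment, survival: pd.DataFrame,
                    endpoint: str) -> pd.DataFrame:
    if endpoint not in _ENDPOINTS:
        raise ValueError(f"endpoint must be one of {sorted(_ENDPOINTS)}")
    tcol, ecol = _ENDPOINTS[endpoint]
    df = survival.merge(
        assignment.strata.rename("stratum"), left_on="subject_id", right_index=True
    )
    return df.rename(columns={tcol: "time", ecol: "event"})[
        ["subject_id", "arm", "time", "event", "stratum"]
    ]


def km_by_stratum(
    assignment: QuartileAssignment,
    survival: pd.DataFrame,
    endpoint: str = "os",
) -> pd.DataFrame:
    """Kaplan-Meier summaries per stratum: n, events, median, 1-year rate.

    The median survival convention is the first time at which the
    product-limit estimate drops to 0.5 or below; when the curve never
    reaches 0.5 the median is not reached (NaN).  The 1-year rate is
    ``S(365) x 100``.
    """
    df = _merge_survival(assignment, survival, endpoint)
    rows = []
    for stratum in STRATA_ORDER:
        sub = df[df["stratum"] == stratum]
        if sub.empty:
            warnings.warn(f"stratum {stratum} is empty; omitted from KM table")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        median = kmf.median_survival_time_
        rows.append({
            "stratum": stratum,
            "n": int(len(sub)),
            "events": int(sub["event"].sum()),
            "median_days": float(median) if np.isfinite(median) else math.nan,
            "rate_1yr_pct": float(kmf.predict(365.0)) * 100.0,
        })
    return pd.DataFrame(rows)


def cox_by_stratum(
    assignment: QuartileAssignment,
    survival: pd.DataFrame,
    endpoint: str = "os",
    reference: str = "Q4",
) -> pd.DataFrame:
    """Stratum-indicator Cox model: hazard ratios vs the reference stratum.

    Efron tie handling.  A stratum with zero events makes its partial
    likelihood unbounded; such strata are reported with HR 0.0 and CI
    (0, inf) rather than dropped, matching the degenerate-cell presentation,
    and are excluded from the joint fit.
    """
    df = _merge_survival(assignment, survival, endpoint)
    present = [s for s in STRATA_ORDER if (df["stratum"] == s).any()]
    if df["event"].sum() == 0:
        raise ValueError("no events in any stratum; Cox model undefined")
    if reference not in present:
        raise ValueError(f"reference stratum {reference!r} has no subjects")

    zero_event = [
        s for s in present
        if s != reference and df.loc[df["stratum"] == s, "event"].sum() == 0
    ]
    fit_df = df[~df["stratum"].isin(zero_event)].copy()
    covars = [s for s in present if s not in zero_event and s != reference]
    X = pd.DataFrame({f"stratum_{s}": (fit_df["stratum"] == s).astype(float)
                      for s in covars})
    X["time"] = fit_df["time"].to_numpy()
    X["event"] = fit_df["event"].to_numpy()

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(X, duration_col="time", event_col="event")

    rows = []
    for s in present:
        if s == reference:
            rows.append({"stratum": s, "n": int((df["stratum"] == s).sum()),
                         "events": int(df.loc[df["stratum"] == s, "event"].sum()),
                         "hr": 1.0, "ci_low": math.nan, "ci_high": math.nan,
                         "reference": True})
        elif s in zero_event:
            rows.append({"stratum": s, "n": int((df["stratum"] == s).sum()),
                         "events": 0, "hr": 0.0, "ci_low": 0.0,
                         "ci_high": math.inf, "reference": False})
        else:
            name = f"stratum_{s}"
            coef = float(cph.params_[name])
            se = float(cph.standard_errors_[name])
            rows.append({"stratum": s, "n": int((df["stratum"] == s).sum()),
                         "events": int(df.loc[df["stratum"] == s, "event"].sum()),
                         "hr": _safe_exp(coef),
                         "ci_low": _safe_exp(coef - 1.959963984540054 * se),
                         "ci_high": _safe_exp(coef + 1.959963984540054 * se),
                         "reference": False})
    return pd.DataFrame(rows)


def _cox_concordance(df: pd.DataFrame, covariates: list[str]) -> float:
    # standardize covariates: a rate on the 1e-3/day scale breaks the Newton
    # step, and the z-scored predictor is a monotone transform so the
    # concordance (a rank statistic of the linear predictor) is unchanged
    X = df[covariates].astype(float)
    X = X.loc[:, X.std() > 0]
    if X.shape[1] == 0:
        return 0.5  # constant predictor: every comparable pair is a tie
    X = (X - X.mean()) / X.std()
    X["time"] = df["time"].to_numpy()
    X["event"] = df["event"].to_numpy()
    last_err: Exception | None = None
    for penalizer in (0.0, 0.01, 0.1, 1.0):
        # a monotone (perfectly separating) likelihood has no finite optimum;
        # the ridge restores one without reordering the linear predictor
        cph = CoxPHFitter(penalizer=penalizer)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(X, duration_col="time", event_col="event")
            return float(cph.concordance_index_)
        except Exception as err:  # ConvergenceError and friends
            last_err = err
    raise ValueError(f"Cox concordance model did not converge: {last_err}")


def concordance_comparison(
    results,
    survival: pd.DataFrame,
    *,
    endpoint: str = "os",
    use_log_g: bool = False,
    response_coding: str = "three_level",
) -> tuple[float, float]:
    """Harrell's C for survival from g versus from tumor response.

    Restricted to subjects with tumor growth (g > 0).  Both predictors are
    assessed through Cox models: continuous g (optionally log g) versus the
    categorical best-percent-change response (3-level by default, or binary
    responder vs not).  Returns ``(concordance_g, concordance_response)``.
    """
    df = _modeled(_as_frame(results)).merge(survival, on="subject_id", how="inner")
    df = df[df["g_per_day"] > 0].copy()
    tcol, ecol = _ENDPOINTS[endpoint]
    df = df.rename(columns={tcol: "time", ecol: "event"})
    if len(df) < 2 or df["event"].sum() == 0:
        raise ValueError("too few comparable subjects for concordance")

    df["gpred"] = np.log(df["g_per_day"]) if use_log_g else df["g_per_day"]
    c_g = _cox_concordance(df, ["gpred"])

    if response_coding == "binary":
        df["resp_responder"] = (df["response_category"] == "responder").astype(float)
        covars = ["resp_responder"]
    elif response_coding == "three_level":
        df["resp_responder"] = (df["response_category"] == "responder").astype(float)
        df["resp_progression"] = (df["response_category"] == "progression").astype(float)
        covars = [c for c in ("resp_responder", "resp_progression")
                  if df[c].nunique() > 1] or ["resp_responder"]
    else:
        raise ValueError(f"unknown response_coding {response_coding!r}")
    c_resp = _cox_concordance(df, covars)
    return c_g, c_resp


def quartile_analysis_on_d(
    results,
    survival: pd.DataFrame,
    endpoint: str = "os",
) -> tuple[QuartileAssignment, pd.DataFrame, pd.DataFrame]:
    """The g-quartile machinery applied to the fitted decay rate d.

    Subjects with a fitted d > 0 (dx, gd, gdphi) are quartiled; returns
    (assignment, KM table, Cox table).  The d = 0 pseudo-stratum is empty by
    construction since gx subjects carry no d.
    """
    df = _modeled(_as_frame(results))
    df = df[df["d_per_day"].notna() & (df["d_per_day"] > 0)]
    if df.empty:
        raise ValueError("no subjects with a fitted d > 0")
    assignment = assign_quartiles(df, value="d_per_day")
    km = km_by_stratum(assignment, survival, endpoint)
    cox = cox_by_stratum(assignment, survival, endpoint)
    return assignment, km, cox


def early_look(
    trajectories: Sequence[TumorTrajectory],
    accrual: pd.DataFrame,
    k: int,
    *,
    followup_floor_days: float = 98.0,
    survival: pd.DataFrame | None = None,
    **fit_options,
) -> EarlyLookResult:
    """Interim analysis when the k-th randomized subject reaches 14 weeks.

    ``accrual`` must carry subject_id, arm and accrual_day.  The data cutoff
    is ``accrual_day`` of the k-th subject (by randomization order) plus the
    follow-up floor (98 days = 14 weeks); each of the first k subjects keeps
    only scans acquired by the cutoff and g is refit from those truncated
    trajectories, emulating an interim database cut.
    """
    acc = accrual.sort_values("accrual_day").reset_index(drop=True)
    if k > len(acc):
        raise ValueError(f"k={k} exceeds the cohort size {len(acc)}")
    cutoff = float(acc.loc[k - 1, "accrual_day"] + followup_floor_days)
    included = set(acc.loc[: k - 1, "subject_id"])
    accrual_of = dict(zip(acc["subject_id"], acc["accrual_day"]))

    truncated = []
    for traj in trajectories:
        if traj.subject_id not in included:
            continue
        keep = traj.days + accrual_of[traj.subject_id] <= cutoff
        if keep.sum() < 2:
            continue  # no post-baseline scan by the cutoff: not evaluable yet
        truncated.append(TumorTrajectory(
            traj.subject_id, traj.days[keep], traj.sod_mm[keep], traj.floored))

    results = fit_cohort(truncated, **fit_options)
    frame = results_to_frame(results)
    arm_table = acc[["subject_id", "arm"]]
    comparison = compare_arms_g(frame, arm_table)
    return EarlyLookResult(k, cutoff, comparison, frame, len(truncated))


def classification_counts(results, survival: pd.DataFrame) -> pd.DataFrame:
    """Per-arm counts of each classification outcome (Table-1 shape)."""
    df = _as_frame(results).merge(survival[["subject_id", "arm"]], on="subject_id")
    order = ["dx", "gd", "gdphi", "gx", "not_fit", "single_scan_small_change"]
    table = (
        df.groupby(["arm", "classification"]).size().unstack(fill_value=0)
        .reindex(columns=order, fill_value=0)
    )
    table["fit_to_model"] = table[["dx", "gd", "gdphi", "gx"]].sum(axis=1)
    return table


def analyze_cohort(
    results,
    survival: pd.DataFrame,
    *,
    include_zero_in_cutpoints: bool = False,
    use_log_g: bool = False,
    response_coding: str = "three_level",
) -> CohortAnalysis:
    """Run the full cohort-level analysis suite.

    Quartiles are built on subjects pooled across both arms; KM and Cox
    tables are reported both pooled and per arm; concordance per arm.
    """
    frame = _as_frame(results)
    arm_cmp = compare_arms_g(frame, survival)
    counts = classification_counts(frame, survival)
    quart = assign_quartiles(frame, include_zero_in_cutpoints=include_zero_in_cutpoints)
    km_os = km_by_stratum(quart, survival, "os")
    km_pfs = km_by_stratum(quart, survival, "pfs")
    cox_os = cox_by_stratum(quart, survival, "os")
    cox_pfs = cox_by_stratum(quart, survival, "pfs")

    conc_rows, per_arm_km, per_arm_cox = [], {}, {}
    for arm, sub in survival.groupby("arm"):
        ids = set(sub["subject_id"])
        sub_frame = frame[frame["subject_id"].isin(ids)]
        try:
            c_g, c_resp = concordance_comparison(
                sub_frame, sub, use_log_g=use_log_g, response_coding=response_coding)
        except ValueError:
            c_g = c_resp = math.nan
        conc_rows.append({"arm": arm, "concordance_g": c_g,
                          "concordance_response": c_resp})
        arm_strata = quart.strata[quart.strata.index.isin(ids)]
        arm_quart = QuartileAssignment(quart.thresholds, arm_strata, quart.value_name)
        per_arm_km[arm] = km_by_stratum(arm_quart, sub, "os")
        try:
            per_arm_cox[arm] = cox_by_stratum(arm_quart, sub, "os")
        except ValueError:
            per_arm_cox[arm] = pd.DataFrame()

    return CohortAnalysis(
        arm_comparison=arm_cmp,
        classification_counts=counts,
        quartiles=quart,
        km_os=km_os,
        km_pfs=km_pfs,
        cox_os=cox_os,
        cox_pfs=cox_pfs,
        concordance=pd.DataFrame(conc_rows),
        per_arm_km_os=per_arm_km,
        per_arm_cox_os=per_arm_cox,
    )
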