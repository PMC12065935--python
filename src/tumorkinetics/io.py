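"""CSV readers/writers and run configuration.

Measurement input is long-format CSV with columns ``subject_id``, ``day``
(integer days from the baseline scan) and ``sod_mm`` (sum of target-lesion
diameters, mm).  The survival table carries ``subject_id``, ``arm``,
``os_days``/``os_event``, ``pfs_days``/``pfs_event`` and optionally
``accrual_day`` and ``response_category``.  Missing values are empty fields.
Report writers render g in the x 10^-2 per-day display convention and TDT in
units of 100 days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortAnalysis
from .fitting import TumorTrajectory

__all__ = [
    "MeasurementValidationError",
    "RunConfig",
    "read_measurements",
    "read_survival",
    "write_results",
    "write_survival",
    "write_trajectories",
    "write_report",
    "render_g_display",
]

_MEASUREMENT_COLUMNS = ("subject_id", "day", "sod_mm")
_SURVIVAL_REQUIRED = ("subject_id", "arm", "os_days", "os_event", "pfs_days", "pfs_event")


class MeasurementValidationError(ValueError):
    """Input failed validation; ``problems`` lists every offender."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid measurement data:\n  " + "\n  ".join(problems))


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run; serialized next to outputs."""

    seed: int = 0
    apply_20pct_rule: bool = True
    include_zero_in_cutpoints: bool = False
    response_coding: str = "three_level"
    log_scale: bool = False
    aicc: bool = False
    use_log_g: bool = False
    measurements_path: str | None = None
    survival_path: str | None = None
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def read_measurements(path: str | Path) -> tuple[list[TumorTrajectory], list[str]]:
    """Parse and validate a measurement CSV.

    Returns ``(trajectories, non_evaluable_ids)``; subjects with a baseline
    but no post-baseline assessment are non-evaluable rather than errors.
    Structural problems (missing columns, duplicate subject-days,
    non-positive baselines, unparseable values) are collected and raised
    together as :class:`MeasurementValidationError`.
    """
    df = pd.read_csv(path)
    problems = []
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementValidationError([f"missing required column(s): {missing}"])

    for col in ("day", "sod_mm"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        for idx in bad.index:
            problems.append(f"line {idx + 2}: non-numeric {col} value {df.loc[idx, col]!r}")
    if problems:
        raise MeasurementValidationError(problems)
    df["day"] = pd.to_numeric(df["day"])
    df["sod_mm"] = pd.to_numeric(df["sod_mm"])

    dupes = df.duplicated(subset=["subject_id", "day"], keep=False)
    for idx in df.index[dupes]:
        problems.append(
            f"line {idx + 2}: duplicate (subject {df.loc[idx, 'subject_id']!r}, "
            f"day {df.loc[idx, 'day']})"
        )

    trajectories, non_evaluable = [], []
    for sid, grp in df.groupby("subject_id", sort=True):
        if dupes[grp.index].any():
            continue
        grp = grp.sort_values("day")
        if grp["day"].iloc[0] != 0:
            problems.append(f"subject {sid!r}: no day-0 baseline assessment")
            continue
        if grp["sod_mm"].iloc[0] <= 0:
            problems.append(f"subject {sid!r}: baseline sod_mm must be > 0")
            continue
        if len(grp) < 2:
            non_evaluable.append(str(sid))
            continue
        trajectories.append(
            TumorTrajectory(str(sid), grp["day"].to_numpy(float), grp["sod_mm"].to_numpy(float))
        )
    if problems:
        raise MeasurementValidationError(problems)
    return trajectories, non_evaluable


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _SURVIVAL_REQUIRED if c not in df.columns]
    if missing:
        raise MeasurementValidationError([f"survival file missing column(s): {missing}"])
    return df


def write_trajectories(trajectories, path: str | Path) -> None:
    """Write trajectories in the long measurement CSV dialect."""
    rows = [
        {"subject_id": t.subject_id, "day": int(day), "sod_mm": sod}
        for t in trajectories
        for day, sod in zip(t.days, t.sod_mm)
    ]
    pd.DataFrame(rows, columns=list(_MEASUREMENT_COLUMNS)).to_csv(path, index=False)


def write_survival(survival: pd.DataFrame, path: str | Path) -> None:
    survival.to_csv(path, index=False)


def write_results(results_frame: pd.DataFrame, path: str | Path) -> None:
    results_frame.to_csv(path, index=False)


def render_g_display(g_per_day: float) -> float:
    """Render a per-day rate in the x 10^-2 per-day display convention."""
    return round(g_per_day * 100.0, 4)


def write_report(analysis: CohortAnalysis, outdir: str | Path,
                 config: RunConfig | None = None) -> list[Path]:
    """Emit the analysis as deterministic CSV tables.

    Writes classification counts, arm-level g summaries (display units),
    quartile KM and hazard-ratio tables for OS and PFS, and the concordance
    table; the resolved config (if given) is stored alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    p = outdir / "classification_counts.csv"
    analysis.classification_counts.to_csv(p)
    written.append(p)

    cmp = analysis.arm_comparison
    rows = []
    for arm in sorted(cmp.median):
        lo, hi = cmp.iqr[arm]
        rows.append({
            "arm": arm,
            "n_modeled": cmp.n[arm],
            "median_g_x1e2_per_day": render_g_display(cmp.median[arm]),
            "iqr_low_x1e2": render_g_display(lo),
            "iqr_high_x1e2": render_g_display(hi),
            "mann_whitney_p": cmp.p_value,
        })
    p = outdir / "arm_g_summary.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    for name, table in (
        ("km_os.csv", analysis.km_os),
        ("km_pfs.csv", analysis.km_pfs),
        ("cox_os.csv", analysis.cox_os),
        ("cox_pfs.csv", analysis.cox_pfs),
        ("concordance.csv", analysis.concordance),
    ):
        p = outdir / name
        table.to_csv(p, index=False)
        written.append(p)

    thresholds = pd.DataFrame(
        {"quantile": [25, 50, 75], "g_cutpoint_per_day": list(analysis.quartiles.thresholds)}
    )
    p = outdir / "quartile_thresholds.csv"
    thresholds.to_csv(p, index=False)
    written.append(p)

    if config is not None:
        p = outdir / "run_config.yaml"
        config.to_yaml(p)
        written.append(p)
    return written
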