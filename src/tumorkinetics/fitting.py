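"""Per-subject nonlinear regression and model selection.

Each subject's baseline-normalized trajectory is fitted to all admissible
candidate models by bounded nonlinear least squares; model selection keeps a
candidate only when every one of its parameters is retained at p < 0.1
(two-sided Wald test against 0) and then picks the smallest AIC.  A subject
for whom no candidate retains all of its parameters is classified
``not_fit``.  Subjects with exactly one post-baseline assessment that changed
by less than 20% from baseline (the RECIST progression threshold for a single
scan) are excluded from modeling and labelled ``single_scan_small_change``.

Conventions (the underlying statistical recipe is not uniquely determined by
the model equations; these choices are fixed and documented in the methods
note):

* Loss is least squares on the normalized burden scale; the baseline point is
  structural (``f(0) = 1``) and contributes no residual.  Log-scale fitting
  is available via ``log_scale=True``.
* ``g`` and ``d`` are bounded below at 0, ``phi`` in [0, 1]; a multi-start
  grid (g, d in {1e-4, 1e-3, 1e-2}/day, phi in {0.2, 0.5, 0.8}) guards
  against local minima, best residual sum wins.
* Wald standard errors from the Gauss-Newton covariance
  ``RSS/(n-k) (J'J)^-1``; parameter/SE referred to the normal distribution
  (two-sided).  ``phi`` is tested against 0 with the same convention.  When
  the information matrix is numerically singular (unidentified corner of the
  parameter space) the errors blow up and nothing is retained.
* AIC = ``n ln(RSS/n) + 2k`` with n the number of post-baseline points; exact
  AIC ties resolve toward the model with fewer parameters.  AICc optional.
* A model is attempted only when the number of post-baseline points is at
  least its parameter count, so a single qualifying scan admits only the
  one-parameter ``gx``/``dx`` fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .models import LN2, GrowthModel, evaluate_vector, model_jacobian

__all__ = [
    "TumorTrajectory",
    "ModelFit",
    "SubjectResult",
    "InsufficientDataError",
    "fit_single_model",
    "select_model",
    "classify_subject",
    "fit_cohort",
    "results_to_frame",
    "NOT_FIT",
    "SINGLE_SCAN_SMALL_CHANGE",
]

NOT_FIT = "not_fit"
SINGLE_SCAN_SMALL_CHANGE = "single_scan_small_change"

#: retention threshold: a parameter stays in the model when its p-value < 0.1
P_RETAIN = 0.10
#: residual sum below which a fit is treated as numerically exact
_EXACT_RSS = 1e-16
#: floor applied to RSS inside the AIC so noise-free fits stay comparable
_RSS_FLOOR = 1e-24
#: distance from the lower bound below which a rate counts as "not detected"
_BOUND_EPS = 1e-12
#: AIC differences below this are ties, resolved toward fewer parameters
_AIC_TIE = 1e-9

_SINGLE_SCAN_CHANGE_THRESHOLD = 0.20

_RATE_STARTS = (1e-4, 1e-3, 1e-2)
_PHI_STARTS = (0.2, 0.5, 0.8)
_RATE_UPPER = 1.0  # per day; generous for solid-tumor kinetics
#: starts polished per model after RSS screening of the full grid
_N_POLISH = {
    GrowthModel.DX: 2,
    GrowthModel.GX: 2,
    GrowthModel.GD: 4,
    GrowthModel.GDPHI: 6,
}


class InsufficientDataError(ValueError):
    """Fewer post-baseline points than free parameters."""


@dataclass
class TumorTrajectory:
    """One subject's serial sum-of-diameters measurements.

    ``days`` are integer-valued days since the baseline scan (``days[0] = 0``)
    and ``sod_mm`` the sum of target-lesion diameters in mm.  Rows are sorted
    by day on construction, so input order never matters.  Measurements of
    0 mm (complete disappearance of target lesions) are floored at half the
    smallest positive measurement so that relative-burden machinery stays
    defined; such subjects are flagged.
    """

    subject_id: str
    days: np.ndarray
    sod_mm: np.ndarray
    floored: bool = False

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        sod = np.asarray(self.sod_mm, dtype=float)
        if days.shape != sod.shape or days.ndim != 1:
            raise ValueError("days and sod_mm must be 1-D arrays of equal length")
        order = np.argsort(days, kind="stable")
        days, sod = days[order], sod[order]
        if len(days) < 2:
            raise ValueError(
                f"subject {self.subject_id!r}: need a baseline and at least one "
                "post-baseline assessment"
            )
        if days[0] != 0:
            raise ValueError(f"subject {self.subject_id!r}: first assessment must be day 0")
        if np.any(np.diff(days) <= 0):
            raise ValueError(f"subject {self.subject_id!r}: duplicate assessment days")
        if not np.all(np.isfinite(sod)) or np.any(sod < 0):
            raise ValueError(f"subject {self.subject_id!r}: sod_mm must be finite and >= 0")
        if np.any(sod == 0):
            positive = sod[sod > 0]
            if positive.size == 0:
                raise ValueError(f"subject {self.subject_id!r}: all measurements are 0 mm")
            sod = np.where(sod == 0, 0.5 * positive.min(), sod)
            self.floored = True
        if sod[0] <= 0:
            raise ValueError(f"subject {self.subject_id!r}: baseline sum of diameters must be > 0")
        self.days = days
        self.sod_mm = sod

    @property
    def normalized(self) -> np.ndarray:
        """Burden relative to baseline; element 0 is exactly 1."""
        return self.sod_mm / self.sod_mm[0]

    @property
    def n_post(self) -> int:
        return len(self.days) - 1


@dataclass
class ModelFit:
    """One candidate model's least-squares fit to one trajectory."""

    model: GrowthModel
    params: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    rss: float
    aic: float
    converged: bool
    n_points: int

    def all_significant(self, alpha: float = P_RETAIN) -> bool:
        """True when every fitted parameter is retained (p < alpha)."""
        return all(p < alpha for p in self.pvalues.values())


@dataclass
class SubjectResult:
    """Outcome of fitting and classifying one subject.

    ``g`` is the g-score: the fitted growth rate for gx/gd/gdphi, exactly 0
    for dx, and ``None`` for not-fit or excluded subjects.  ``tdt_days`` is
    ``ln(2)/g`` and exists only when ``g > 0``.
    """

    subject_id: str
    classification: str
    fit: ModelFit | None = None
    g: float | None = None
    d: float | None = None
    phi: float | None = None
    tdt_days: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def modeled(self) -> bool:
        return self.classification in ("dx", "gx", "gd", "gdphi")


def _default_starts(model: GrowthModel) -> list[np.ndarray]:
    grids = {"g": _RATE_STARTS, "d": _RATE_STARTS, "phi": _PHI_STARTS}
    axes = [grids[name] for name in model.param_names]
    mesh = np.meshgrid(*axes, indexing="ij")
    return [np.array(p) for p in zip(*(m.ravel() for m in mesh))]


def fit_single_model(
    traj: TumorTrajectory,
    model: GrowthModel | str,
    *,
    log_scale: bool = False,
    aicc: bool = False,
    starts: Sequence[np.ndarray] | None = None,
) -> ModelFit:
    """Bounded least-squares fit of one model class to one trajectory.

    Residuals are taken over post-baseline points only; the baseline is
    structural.  Raises :class:`InsufficientDataError` when the trajectory
    has fewer post-baseline points than the model has parameters.
    """
    model = GrowthModel(model)
    t = traj.days[1:]
    y = traj.normalized[1:]
    n, k = len(t), model.n_params
    if n < k:
        raise InsufficientDataError(
            f"subject {traj.subject_id!r}: {n} post-baseline point(s) cannot "
            f"support the {k}-parameter {model.value} model"
        )

    log_y = np.log(y) if log_scale else None

    def residuals(theta: np.ndarray) -> np.ndarray:
        # clamp so exploratory steps at extreme rates stay finite
        f = np.minimum(evaluate_vector(model, theta, t), 1e100)
        if log_scale:
            return np.log(np.maximum(f, 1e-300)) - log_y
        return f - y

    def jacobian(theta: np.ndarray) -> np.ndarray:
        J = np.clip(model_jacobian(model, theta, t), -1e100, 1e100)
        if log_scale:
            f = np.minimum(evaluate_vector(model, theta, t), 1e100)
            J = J / np.maximum(f, 1e-300)[:, None]
        return J

    lower = np.array([0.0 if p in ("g", "d") else 0.0 for p in model.param_names])
    upper = np.array([_RATE_UPPER if p in ("g", "d") else 1.0 for p in model.param_names])

    if starts is not None:
        candidates = [np.asarray(s, dtype=float) for s in starts]
    else:
        # screen the full multi-start grid by initial RSS and polish only the
        # most promising starts; the grid stays the exploration device, the
        # screening just avoids optimizer runs that cannot win
        candidates = _default_starts(model)
        if len(candidates) > _N_POLISH[model]:
            rss0 = [float(np.sum(residuals(np.clip(c, lower, upper)) ** 2))
                    for c in candidates]
            order = np.argsort(rss0, kind="stable")[: _N_POLISH[model]]
            candidates = [candidates[i] for i in order]

    best = None
    for theta0 in candidates:
        theta0 = np.clip(np.asarray(theta0, dtype=float), lower, upper)
        try:
            res = optimize.least_squares(
                residuals,
                theta0,
                jac=jacobian,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-12,
                max_nfev=300,
            )
        except Exception:  # pragma: no cover - defensive against optimizer blowups
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost * 2 < 1e-22:  # numerically exact; later starts cannot improve
            break

    if best is None:
        nan = {p: math.nan for p in model.param_names}
        return ModelFit(model, dict(nan), dict(nan), {p: 1.0 for p in model.param_names},
                        math.nan, math.nan, False, n)

    theta = best.x
    rss = float(2.0 * best.cost)
    dof = n - k
    names = model.param_names

    se = {}
    pvalues = {}
    if n == 1:
        # Single post-baseline assessment: the one-parameter fit interpolates
        # the point exactly, so "detected" simply means the rate is nonzero.
        # (The <20% single-scan gate, when enabled, screens these upstream.)
        for name, value in zip(names, theta):
            se[name] = 0.0
            pvalues[name] = 0.0 if value > _BOUND_EPS else 1.0
    elif rss < _EXACT_RSS and dof > 0:
        # Numerically exact fit of an overdetermined model: a parameter
        # pinned at its lower bound was "not detected"; interior parameters
        # are unambiguously supported.
        for name, value in zip(names, theta):
            se[name] = 0.0
            pvalues[name] = 0.0 if value > _BOUND_EPS else 1.0
    elif dof > 0:
        J = jacobian(theta)
        jtj = J.T @ J
        # A truncating pseudo-inverse would hide ill-conditioning (e.g. the
        # gdphi corner phi -> 1 where g is unidentified) and report spuriously
        # small errors; near-singular information means the parameters are
        # not jointly identified, so their errors blow up honestly.
        try:
            cond = np.linalg.cond(jtj)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError
            cov = rss / dof * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.inf)
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        for i, name in enumerate(names):
            se[name] = float(diag[i])
            if diag[i] == 0.0:
                pvalues[name] = 0.0 if theta[i] > _BOUND_EPS else 1.0
            else:
                tstat = theta[i] / diag[i]
                pvalues[name] = float(2.0 * stats.norm.sf(abs(tstat)))
    else:
        # Saturated multi-parameter fit (k == n >= 2): it interpolates any
        # data, perfectly fitting the noise, so its parameters carry no
        # evidence and are treated as unsupported.
        for name in names:
            se[name] = math.nan
            pvalues[name] = 1.0

    aic = n * math.log(max(rss, _RSS_FLOOR) / n) + 2 * k
    if aicc and n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)

    params = {name: float(v) for name, v in zip(names, theta)}
    return ModelFit(model, params, se, pvalues, rss, aic, True, n)


def select_model(fits: Iterable[ModelFit], *, alpha: float = P_RETAIN) -> ModelFit | None:
    """AIC model selection with the p < 0.1 parameter-retention rule.

    Among converged fits whose every parameter is significant, returns the
    smallest-AIC fit (exact ties resolved toward fewer parameters); returns
    ``None`` when no candidate qualifies — the ``not_fit`` outcome.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_model requires at least one candidate fit")
    admissible = [f for f in fits if f.converged and math.isfinite(f.aic)
                  and f.all_significant(alpha)]
    if not admissible:
        return None
    best_aic = min(f.aic for f in admissible)
    tied = [f for f in admissible if f.aic <= best_aic + _AIC_TIE]
    tied.sort(key=lambda f: (f.model.n_params, f.aic))
    return tied[0]


def classify_subject(
    traj: TumorTrajectory,
    *,
    apply_20pct_rule: bool = True,
    log_scale: bool = False,
    aicc: bool = False,
    alpha: float = P_RETAIN,
) -> SubjectResult:
    """Fit all admissible models and classify one subject.

    A subject with exactly one post-baseline assessment whose burden changed
    by less than 20% from baseline is excluded (``single_scan_small_change``)
    when the rule is enabled; with a >= 20% change the single scan supports a
    pure growth or pure decay fit only.
    """
    flags = ("baseline_floored",) if traj.floored else ()
    if (
        apply_20pct_rule
        and traj.n_post == 1
        and abs(traj.normalized[1] - 1.0) < _SINGLE_SCAN_CHANGE_THRESHOLD
    ):
        return SubjectResult(traj.subject_id, SINGLE_SCAN_SMALL_CHANGE, flags=flags)

    fits = []
    for model in GrowthModel:
        if traj.n_post >= model.n_params:
            fits.append(fit_single_model(traj, model, log_scale=log_scale, aicc=aicc))
    selected = select_model(fits, alpha=alpha)
    if selected is None:
        return SubjectResult(traj.subject_id, NOT_FIT, flags=flags)

    cls = selected.model.value
    g = 0.0 if cls == "dx" else selected.params["g"]
    d = selected.params.get("d")
    phi = selected.params.get("phi")
    tdt = LN2 / g if g > 0 else None
    return SubjectResult(traj.subject_id, cls, selected, g, d, phi, tdt, flags)


def fit_cohort(
    trajectories: Sequence[TumorTrajectory],
    survival=None,
    **options,
) -> list[SubjectResult]:
    """Vectorized :func:`classify_subject` over a cohort.

    Subjects without any post-baseline assessment cannot become trajectories
    and are therefore never passed here; they are reported as non-evaluable
    by the reader.  Duplicate subject ids are rejected.  ``survival`` is
    accepted for interface symmetry with the analysis stage and is unused.
    """
    ids = [t.subject_id for t in trajectories]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    return [classify_subject(t, **options) for t in trajectories]


def results_to_frame(results: Sequence[SubjectResult]):
    """Tabulate subject results as a DataFrame (one row per subject)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject_id,
                "classification": r.classification,
                "g_per_day": r.g,
                "d_per_day": r.d,
                "phi": r.phi,
                "tdt_days": r.tdt_days,
                "aic": r.fit.aic if r.fit else None,
                "n_points": r.fit.n_points if r.fit else None,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "classification", "g_per_day", "d_per_day",
            "phi", "tdt_days", "aic", "n_points", "flags",
        ],
    )
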