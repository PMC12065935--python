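"""Bi-exponential tumor-burden kinetics.

A patient's radiographic tumor burden (RECIST sum of target-lesion
diameters), normalized to its baseline value so that ``f(0) = 1``, is
described by the simultaneous action of two first-order processes: exponential
regression (decay) of the treatment-sensitive tumor at rate ``d`` per day and
exponential growth or regrowth at rate ``g`` per day.  Four nested candidate
models cover the trajectories seen in practice:

========  =====================================  ==========================
label     f(t)                                   free parameters
========  =====================================  ==========================
``dx``    ``exp(-d t)``                          d          (pure regression)
``gx``    ``exp(g t)``                           g          (pure growth)
``gd``    ``exp(-d t) + exp(g t) - 1``           g, d       (additive mixture)
``gdphi`` ``phi exp(-d t) + (1-phi) exp(g t)``   g, d, phi  (convex mixture)
========  =====================================  ==========================

``phi`` is the fraction of the tumor sensitive to treatment; ``1 - phi`` is
the (absolutely or relatively) resistant fraction that regrows at rate ``g``.
The convex-mixture form is needed for trajectories with a prolonged nadir
before regrowth.  The growth rate ``g`` is the *g-score*; subjects whose data
show only regression (``dx``) have, by convention, a g-score of exactly 0.
``g`` maps to a tumor doubling time of ``ln(2)/g`` days.

All functions here are pure; time is measured in days from the baseline scan.
"""

from __future__ import annotations

import enum
import math
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GrowthModel",
    "MissingParameterError",
    "UndefinedDoublingTimeError",
    "GScoreUnavailableError",
    "evaluate",
    "evaluate_vector",
    "model_jacobian",
    "doubling_time",
    "gscore_of",
    "LN2",
]

LN2 = math.log(2.0)

#: classifications that carry a selected model (and hence a g-score)
MODELED_CLASSES = ("dx", "gx", "gd", "gdphi")


class MissingParameterError(ValueError):
    """A parameter required by the model class was not supplied."""


class UndefinedDoublingTimeError(ValueError):
    """Doubling time is only defined for a strictly positive growth rate."""


class GScoreUnavailableError(ValueError):
    """The subject was not fit to any model, so no g-score exists."""


class GrowthModel(str, enum.Enum):
    """The four candidate tumor-burden models."""

    DX = "dx"
    GX = "gx"
    GD = "gd"
    GDPHI = "gdphi"

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self]

    @property
    def n_params(self) -> int:
        return len(_PARAM_NAMES[self])


_PARAM_NAMES: dict[GrowthModel, tuple[str, ...]] = {
    GrowthModel.DX: ("d",),
    GrowthModel.GX: ("g",),
    GrowthModel.GD: ("g", "d"),
    GrowthModel.GDPHI: ("g", "d", "phi"),
}


def _require(model: GrowthModel, **given: float | None) -> dict[str, float]:
    params = {}
    for name in model.param_names:
        value = given.get(name)
        if value is None:
            raise MissingParameterError(
                f"model {model.value!r} requires parameter {name!r}"
            )
        params[name] = float(value)
    g = params.get("g")
    d = params.get("d")
    phi = params.get("phi")
    if g is not None and g < 0:
        raise ValueError(f"growth rate g must be >= 0, got {g}")
    if d is not None and d < 0:
        raise ValueError(f"decay rate d must be >= 0, got {d}")
    if phi is not None and not (0.0 <= phi <= 1.0):
        raise ValueError(f"sensitive fraction phi must be in [0, 1], got {phi}")
    return params


def evaluate(
    model: GrowthModel | str,
    t: float | Sequence[float] | np.ndarray,
    *,
    g: float | None = None,
    d: float | None = None,
    phi: float | None = None,
) -> np.ndarray | float:
    """Normalized tumor burden ``f(t)`` under one of the four models.

    Parameters
    ----------
    model
        Model class (``"dx"``, ``"gx"``, ``"gd"`` or ``"gdphi"``).
    t
        Time(s) in days since the baseline scan; must be >= 0.
    g, d, phi
        Kinetic parameters; only those used by `model` are required, and
        extras used by other classes are ignored only if ``None``.

    Returns
    -------
    Burden relative to baseline; ``f(0) == 1`` for every model.
    """
    model = GrowthModel(model)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0 (days since baseline)")
    p = _require(model, g=g, d=d, phi=phi)
    out = _evaluate_arr(model, t_arr, p)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _evaluate_arr(model: GrowthModel, t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    if model is GrowthModel.DX:
        return np.exp(-p["d"] * t)
    if model is GrowthModel.GX:
        return np.exp(p["g"] * t)
    if model is GrowthModel.GD:
        return np.exp(-p["d"] * t) + np.exp(p["g"] * t) - 1.0
    # gdphi
    phi = p["phi"]
    return phi * np.exp(-p["d"] * t) + (1.0 - phi) * np.exp(p["g"] * t)


def evaluate_vector(model: GrowthModel, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """`evaluate` with parameters packed in the model's canonical order.

    Used by the fitting machinery; performs no validation.
    """
    p = dict(zip(model.param_names, theta))
    return _evaluate_arr(model, t, p)


def model_jacobian(model: GrowthModel, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Analytic Jacobian ``df/dtheta`` evaluated at times ``t``.

    Shape ``(len(t), n_params)``, columns in ``model.param_names`` order.
    """
    if model is GrowthModel.DX:
        (d,) = theta
        return (-t * np.exp(-d * t))[:, None]
    if model is GrowthModel.GX:
        (g,) = theta
        return (t * np.exp(g * t))[:, None]
    if model is GrowthModel.GD:
        g, d = theta
        return np.column_stack([t * np.exp(g * t), -t * np.exp(-d * t)])
    g, d, phi = theta
    eg = np.exp(g * t)
    ed = np.exp(-d * t)
    return np.column_stack([(1.0 - phi) * t * eg, -phi * t * ed, ed - eg])


def doubling_time(g: float) -> float:
    """Tumor doubling time ``ln(2)/g`` in days, defined for ``g > 0``.

    Subjects best described by the regression-only ``dx`` model have g = 0
    and therefore no doubling time; passing ``g <= 0`` raises
    :class:`UndefinedDoublingTimeError`.
    """
    if g <= 0:
        raise UndefinedDoublingTimeError(
            f"doubling time ln(2)/g requires g > 0, got g={g}"
        )
    return LN2 / g


def gscore_of(result) -> float:
    """Extract the g-score from a classified subject.

    ``dx`` subjects receive exactly 0.0; growth-bearing classes return the
    fitted ``g``.  Subjects who were not fit to a model (or were excluded for
    having a single small-change scan) have no g-score and raise
    :class:`GScoreUnavailableError`.

    Accepts any object with ``classification`` and ``g`` attributes
    (e.g. :class:`tumorkinetics.fitting.SubjectResult`).
    """
    cls = getattr(result, "classification", None)
    if cls == "dx":
        return 0.0
    if cls in ("gx", "gd", "gdphi"):
        return float(result.g)
    raise GScoreUnavailableError(
        f"no g-score for classification {cls!r}"
    )
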