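"""Weibull survival curves and their calibration.

All efficacy evidence in the model is carried by two-parameter Weibull
survival functions

    S(t) = exp(-(t / scale) ** shape),        t in months,

one curve per (endpoint, arm).  Curves are obtained either in closed form
from a published landmark survival fraction (optionally shifted to the
other arm through a proportional-hazards ratio), or by least squares on a
digitized Kaplan-Meier point series in the complementary-log-log
linearization ``ln(-ln S) = shape * ln t - shape * ln scale``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    InsufficientDataError,
    ValidationError,
)

ENDPOINT_LABELS = ("OS", "clinical_PFS", "PSA_PFS")
ARM_LABELS = ("enzalutamide", "standard_care")

__all__ = [
    "ENDPOINT_LABELS",
    "ARM_LABELS",
    "WeibullCurve",
    "DigitizedSeries",
    "survival_at",
    "calibrate_from_landmark",
    "apply_hazard_ratio",
    "fit_to_points",
    "cycle_transition_probability",
    "cycle_transition_probabilities",
]


def _check_label(value: str, allowed: tuple[str, ...], what: str) -> None:
    if value not in allowed:
        raise ValidationError(f"{what} must be one of {allowed}, got {value!r}")


@dataclass(frozen=True)
class WeibullCurve:
    """A two-parameter Weibull survival curve for one endpoint and arm.

    Parameters
    ----------
    shape
        Dimensionless Weibull shape ``k`` (> 0).  ``k == 1`` is the
        exponential (constant-hazard) special case; ``k > 1`` means the
        hazard rises with time.
    scale
        Weibull scale ``lambda`` in months (> 0); the time at which
        survival has fallen to ``exp(-1)``.
    endpoint_label, arm_label
        What the curve describes: overall survival or one of the two
        progression-free survival definitions, for one treatment arm.
    calibration
        Provenance tag: how the parameters were obtained.
    fit_r_squared
        R-squared of the complementary-log-log linear fit when the curve
        came from :func:`fit_to_points`; ``None`` otherwise.
    """

    shape: float
    scale: float
    endpoint_label: str = "OS"
    arm_label: str = "standard_care"
    calibration: str = "direct"
    fit_r_squared: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValidationError(f"shape must be finite and > 0, got {self.shape}")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValidationError(f"scale must be finite and > 0, got {self.scale}")
        _check_label(self.endpoint_label, ENDPOINT_LABELS, "endpoint_label")
        _check_label(self.arm_label, ARM_LABELS, "arm_label")

    # -- evaluation ---------------------------------------------------

    def cumulative_hazard(self, t):
        """H(t) = (t/scale)**shape for t >= 0 (scalar or array)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValidationError("time must be non-negative")
        out = (t_arr / self.scale) ** self.shape
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def survival(self, t):
        """S(t) = exp(-(t/scale)**shape); exactly 1 at t = 0."""
        h = self.cumulative_hazard(t)
        return math.exp(-h) if isinstance(h, float) else np.exp(-h)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "shape": self.shape,
            "scale": self.scale,
            "endpoint_label": self.endpoint_label,
            "arm_label": self.arm_label,
            "calibration": self.calibration,
        }
        if self.fit_r_squared is not None:
            d["fit_r_squared"] = self.fit_r_squared
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullCurve":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "WeibullCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def survival_at(curve: WeibullCurve, t) -> float:
    """Survival fraction of ``curve`` at time ``t`` (months, >= 0)."""
    return curve.survival(t)


def calibrate_from_landmark(
    survival_at_t: float,
    t: float,
    assumed_shape: float = 1.0,
    *,
    endpoint_label: str = "OS",
    arm_label: str = "standard_care",
) -> WeibullCurve:
    """Closed-form Weibull through a single landmark survival fraction.

    Solves ``exp(-(t/scale)**shape) == survival_at_t`` for the scale with
    the shape held fixed:  ``scale = t / (-ln S)**(1/shape)``.  One
    landmark determines only one parameter, so the shape must be assumed;
    the conventional default is 1 (exponential).
    """
    if not (0.0 < survival_at_t < 1.0):
        raise CalibrationError(
            f"landmark survival must lie strictly in (0, 1); got {survival_at_t}"
            " (no finite Weibull passes through 0 or 1 at positive time)"
        )
    if not t > 0:
        raise ValidationError(f"landmark time must be > 0, got {t}")
    if not assumed_shape > 0:
        raise ValidationError(f"assumed_shape must be > 0, got {assumed_shape}")
    scale = t / (-math.log(survival_at_t)) ** (1.0 / assumed_shape)
    return WeibullCurve(
        shape=assumed_shape,
        scale=scale,
        endpoint_label=endpoint_label,
        arm_label=arm_label,
        calibration="landmark",
    )


def apply_hazard_ratio(
    reference: WeibullCurve, hr: float, *, arm_label: str | None = None
) -> WeibullCurve:
    """Shift a curve by a proportional-hazards ratio.

    Under proportional hazards on a Weibull the shape is preserved and
    ``S_new(t) = S_ref(t) ** hr`` for all t, i.e.
    ``scale_new = scale_ref * hr ** (-1/shape)``.
    """
    if not (hr > 0 and math.isfinite(hr)):
        raise ValidationError(f"hazard ratio must be finite and > 0, got {hr}")
    return replace(
        reference,
        scale=reference.scale * hr ** (-1.0 / reference.shape),
        arm_label=arm_label if arm_label is not None else reference.arm_label,
        calibration=f"{reference.calibration}+hr",
        fit_r_squared=None,
    )


@dataclass(frozen=True)
class DigitizedSeries:
    """A digitized Kaplan-Meier curve: (time, survival-fraction) points.

    Times are strictly increasing and non-negative; survival fractions
    lie in (0, 1] and never increase (a survival curve cannot rise).
    """

    times: np.ndarray
    survival: np.ndarray
    endpoint_label: str = "OS"
    arm_label: str = "standard_care"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)
        if times.ndim != 1 or surv.ndim != 1 or times.size != surv.size:
            raise ValidationError("times and survival must be 1-D and equal length")
        if times.size and times[0] < 0:
            raise ValidationError("times must start at or after 0")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(surv <= 0) or np.any(surv > 1):
            raise ValidationError("survival fractions must lie in (0, 1]")
        if np.any(np.diff(surv) > 0):
            raise ValidationError("survival must be non-increasing over time")
        _check_label(self.endpoint_label, ENDPOINT_LABELS, "endpoint_label")
        _check_label(self.arm_label, ARM_LABELS, "arm_label")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        *,
        endpoint_label: str = "OS",
        arm_label: str = "standard_care",
    ) -> "DigitizedSeries":
        df = pd.read_csv(path)
        missing = {"time_months", "survival"} - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            times=df["time_months"].to_numpy(float),
            survival=df["survival"].to_numpy(float),
            endpoint_label=endpoint_label,
            arm_label=arm_label,
        )


def fit_to_points(series: DigitizedSeries) -> WeibullCurve:
    """Least-squares Weibull fit to a digitized survival point series.

    Points with ``S == 1`` or ``t == 0`` carry no information in the
    complementary-log-log transform and are excluded.  The fit is
    ordinary least squares of ``ln(-ln S)`` on ``ln t``; the slope is the
    shape and the intercept ``-shape * ln(scale)``.  The R-squared of
    this linear fit is attached to the returned curve.
    """
    mask = (series.survival > 0) & (series.survival < 1) & (series.times > 0)
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"need at least 3 points with 0 < S < 1 and t > 0, got {int(mask.sum())}"
        )
    x = np.log(series.times[mask])
    y = np.log(-np.log(series.survival[mask]))
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    if slope <= 0:
        raise CalibrationError(
            "fitted shape is non-positive; the series does not decay with time"
        )
    resid = y - design @ np.array([slope, intercept])
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return WeibullCurve(
        shape=float(slope),
        scale=float(np.exp(-intercept / slope)),
        endpoint_label=series.endpoint_label,
        arm_label=series.arm_label,
        calibration="digitized_fit",
        fit_r_squared=r2,
    )


def cycle_transition_probability(
    curve: WeibullCurve, cycle_index: int, cycle_length: float
) -> float:
    """Conditional probability of leaving the curve's state during a cycle.

    ``p_i = 1 - S((i+1)c) / S(ic)``, computed via the cumulative hazard
    so the ratio stays accurate when S is very small.  For shape 1 the
    result is the same for every cycle (memorylessness).
    """
    if cycle_index < 0 or int(cycle_index) != cycle_index:
        raise ValidationError("cycle_index must be a non-negative integer")
    if not cycle_length > 0:
        raise ValidationError("cycle_length must be > 0")
    h0 = curve.cumulative_hazard(cycle_index * cycle_length)
    h1 = curve.cumulative_hazard((cycle_index + 1) * cycle_length)
    return float(-math.expm1(h0 - h1))


def cycle_transition_probabilities(
    curve: WeibullCurve, n_cycles: int, cycle_length: float
) -> np.ndarray:
    """Vector of per-cycle exit probabilities for cycles 0 .. n_cycles-1."""
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    if not cycle_length > 0:
        raise ValidationError("cycle_length must be > 0")
    bounds = np.arange(n_cycles + 1, dtype=float) * cycle_length
    h = curve.cumulative_hazard(bounds)
    return -np.expm1(h[:-1] - h[1:])
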