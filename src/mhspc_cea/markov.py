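"""Three-state cohort trace and discounted accumulation.

The model has three health states — progression-free (PFS), progressed
disease (PD) and death — with monthly cycles over a 20-year horizon in
the base case.  Occupancy is *curve-tracking* (partitioned-survival
consistent): at every cycle boundary

    pfs = S_pfs(t),    dead = 1 - S_os(t),    pd = S_os(t) - S_pfs(t),

so the trace reproduces both fitted survival curves exactly and no
post-progression hazard has to be invented.  The equivalent per-cycle
transition probabilities are derivable for audit via
:func:`mhspc_cea.survival.cycle_transition_probability`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StructuralInconsistencyError, ValidationError
from .survival import WeibullCurve, cycle_transition_probabilities

__all__ = [
    "ModelSettings",
    "CohortTrace",
    "run_trace",
    "monthly_discount_factor",
    "accumulate_qalys",
    "accumulate_costs",
    "derive_transition_probabilities",
]

_SUM_TOL = 1e-10


@dataclass(frozen=True)
class ModelSettings:
    """Structural constants of one model run.

    Defaults are the base case: 1-month cycles, 240 cycles (20 years).
    The annual discount rate is 3.5%/year for the US perspective and
    3%/year for China; the half-cycle correction is off by default.
    """

    cycle_length_months: float = 1.0
    n_cycles: int = 240
    annual_discount_rate: float = 0.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not self.cycle_length_months > 0:
            raise ValidationError("cycle_length_months must be > 0")
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError("annual_discount_rate must lie in [0, 1)")

    @property
    def horizon_months(self) -> float:
        return self.cycle_length_months * self.n_cycles


def monthly_discount_factor(annual_rate: float, cycle_index) -> float | np.ndarray:
    """Compound-equivalent discount factor ``(1 + r)**(-i/12)``.

    ``cycle_index`` is measured in months from model entry (equal to the
    cycle number when cycles are one month long).  Accepts scalars or
    arrays.
    """
    if not 0.0 <= annual_rate < 1.0:
        raise ValidationError("annual_rate must lie in [0, 1)")
    i = np.asarray(cycle_index, dtype=float)
    if np.any(i < 0):
        raise ValidationError("cycle_index must be non-negative")
    out = (1.0 + annual_rate) ** (-i / 12.0)
    return float(out) if np.isscalar(cycle_index) or i.ndim == 0 else out


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state-occupancy fractions at cycle boundaries 0..n."""

    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    cycle_length_months: float = 1.0

    def __post_init__(self) -> None:
        pfs = np.asarray(self.pfs, float)
        pd_ = np.asarray(self.pd, float)
        dead = np.asarray(self.dead, float)
        object.__setattr__(self, "pfs", pfs)
        object.__setattr__(self, "pd", pd_)
        object.__setattr__(self, "dead", dead)
        if not (pfs.shape == pd_.shape == dead.shape) or pfs.ndim != 1:
            raise ValidationError("occupancy arrays must be 1-D and equal length")
        if abs(pfs[0] - 1.0) > _SUM_TOL or abs(pd_[0]) > _SUM_TOL:
            raise ValidationError("cohort must enter entirely in the PFS state")
        total = pfs + pd_ + dead
        if np.max(np.abs(total - 1.0)) > _SUM_TOL:
            raise ValidationError("state occupancies must sum to 1 at every cycle")
        if np.any((pfs < -_SUM_TOL) | (pd_ < -_SUM_TOL) | (dead < -_SUM_TOL)):
            raise ValidationError("occupancies must be non-negative")
        if np.any(np.diff(dead) < -_SUM_TOL):
            raise ValidationError("death occupancy must be non-decreasing")
        if np.any(np.diff(pfs) > _SUM_TOL):
            raise ValidationError("PFS occupancy must be non-increasing")

    @property
    def n_cycles(self) -> int:
        return int(self.pfs.size - 1)

    def to_frame(self, annual_discount_rate: float = 0.0) -> pd.DataFrame:
        months = np.arange(self.pfs.size) * self.cycle_length_months
        return pd.DataFrame(
            {
                "cycle": np.arange(self.pfs.size),
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
                "discount_factor": monthly_discount_factor(
                    annual_discount_rate, months
                ),
            }
        )

    def to_csv(self, path: str | Path, annual_discount_rate: float = 0.0) -> None:
        self.to_frame(annual_discount_rate).to_csv(path, index=False)


def run_trace(
    os_curve: WeibullCurve, pfs_curve: WeibullCurve, settings: ModelSettings
) -> CohortTrace:
    """Build the curve-tracking cohort trace for one arm.

    Raises :class:`StructuralInconsistencyError` (naming the first
    offending cycle) if the PFS curve ever sits above the OS curve at a
    cycle boundary — a sign of incompatible calibration inputs.
    """
    if os_curve.arm_label != pfs_curve.arm_label:
        raise ValidationError(
            "OS and PFS curves must describe the same arm, got "
            f"{os_curve.arm_label!r} vs {pfs_curve.arm_label!r}"
        )
    t = np.arange(settings.n_cycles + 1, dtype=float) * settings.cycle_length_months
    s_os = os_curve.survival(t)
    s_pfs = pfs_curve.survival(t)
    bad = np.nonzero(s_os < s_pfs - 1e-12)[0]
    if bad.size:
        raise StructuralInconsistencyError(
            f"OS survival falls below PFS survival at cycle {int(bad[0])} "
            f"(t = {t[bad[0]]:g} months): S_os = {s_os[bad[0]]:.6f} < "
            f"S_pfs = {s_pfs[bad[0]]:.6f}; calibration inputs are incompatible"
        )
    return CohortTrace(
        pfs=s_pfs,
        pd=np.clip(s_os - s_pfs, 0.0, None),
        dead=1.0 - s_os,
        cycle_length_months=settings.cycle_length_months,
    )


def derive_transition_probabilities(
    os_curve: WeibullCurve, pfs_curve: WeibullCurve, settings: ModelSettings
) -> pd.DataFrame:
    """Per-cycle exit probabilities implied by the two curves (audit aid).

    ``p_leave_pfs`` is the conditional probability of leaving PFS during
    the cycle; ``p_die`` the conditional probability of dying (from any
    alive state, since death tracks the OS curve).
    """
    c = settings.cycle_length_months
    return pd.DataFrame(
        {
            "cycle": np.arange(settings.n_cycles),
            "p_leave_pfs": cycle_transition_probabilities(
                pfs_curve, settings.n_cycles, c
            ),
            "p_die": cycle_transition_probabilities(os_curve, settings.n_cycles, c),
        }
    )


def _state_weights(trace: CohortTrace, settings: ModelSettings):
    """Occupancy weights for each of the n cycles.

    Start-of-cycle membership by default; averages of adjacent
    boundaries when the half-cycle correction is on.
    """
    if trace.n_cycles != settings.n_cycles:
        raise ValidationError("trace length does not match settings.n_cycles")
    if settings.half_cycle_correction:
        w_pfs = 0.5 * (trace.pfs[:-1] + trace.pfs[1:])
        w_pd = 0.5 * (trace.pd[:-1] + trace.pd[1:])
    else:
        w_pfs = trace.pfs[:-1]
        w_pd = trace.pd[:-1]
    months = np.arange(settings.n_cycles) * settings.cycle_length_months
    df = monthly_discount_factor(settings.annual_discount_rate, months)
    return w_pfs, w_pd, df


def accumulate_qalys(
    trace: CohortTrace,
    utility_pfs: float,
    utility_pd: float,
    settings: ModelSettings,
) -> float:
    """Discounted quality-adjusted life-years over the trace.

    Each cycle contributes ``discount * (pfs*u_pfs + pd*u_pd) * c/12``;
    the dead state contributes nothing.  Utilities are health-state
    weights in [0, 1], assumed constant over time.
    """
    for name, u in (("utility_pfs", utility_pfs), ("utility_pd", utility_pd)):
        if not 0.0 <= u <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {u}")
    w_pfs, w_pd, df = _state_weights(trace, settings)
    years_per_cycle = settings.cycle_length_months / 12.0
    return float(np.sum(df * (w_pfs * utility_pfs + w_pd * utility_pd)) * years_per_cycle)


def accumulate_costs(
    trace: CohortTrace,
    pfs_cost_per_cycle: float,
    pd_cost_per_cycle: float,
    one_off_costs: float,
    settings: ModelSettings,
) -> float:
    """Discounted total cost over the trace.

    One-off costs are charged undiscounted at model entry (cycle 0);
    per-cycle state costs are weighted by occupancy and discounted with
    the same factors as QALYs.
    """
    for name, c in (
        ("pfs_cost_per_cycle", pfs_cost_per_cycle),
        ("pd_cost_per_cycle", pd_cost_per_cycle),
        ("one_off_costs", one_off_costs),
    ):
        if c < 0:
            raise ValidationError(f"{name} must be non-negative, got {c}")
    w_pfs, w_pd, df = _state_weights(trace, settings)
    running = np.sum(df * (w_pfs * pfs_cost_per_cycle + w_pd * pd_cost_per_cycle))
    return float(one_off_costs + running)
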