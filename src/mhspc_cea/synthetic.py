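"""Synthetic model inputs with known ground truth.

The published analysis fitted Weibull curves to Kaplan-Meier curves
digitized from trial figures; those point series are not public.  This
module generates equivalent series from known Weibull parameters with
additive digitization-like noise, so the curve-fitting path is testable
end to end, plus randomized-but-valid cost tables for property tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .costs import CostItem, CostTable
from .datasets import load_cost_table
from .errors import ValidationError
from .survival import DigitizedSeries, WeibullCurve

__all__ = ["GeneratorSpec", "generate_digitized_series", "write_series", "generate_cost_fixture"]

_SURVIVAL_FLOOR = 1e-6  # digitized fractions stay strictly positive


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth and noise model for one digitized series.

    Noise is additive Gaussian on the survival-fraction scale
    (default sd 0.01, the order of pixel-level digitization error),
    clamped to (0, 1] and then monotonized by cumulative minimum —
    a digitized survival curve never rises.
    """

    shape: float
    scale: float
    endpoint_label: str = "OS"
    arm_label: str = "standard_care"
    n_points: int = 10
    t_start: float = 6.0
    t_end: float = 60.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("n_points must be >= 3")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 < self.t_start < self.t_end:
            raise ValidationError("need 0 < t_start < t_end")
        # constructing the truth curve validates shape/scale/labels
        self.truth  # noqa: B018

    @property
    def truth(self) -> WeibullCurve:
        """The generating curve (the fit target)."""
        return WeibullCurve(
            shape=self.shape,
            scale=self.scale,
            endpoint_label=self.endpoint_label,
            arm_label=self.arm_label,
            calibration="synthetic_truth",
        )


def generate_digitized_series(spec: GeneratorSpec) -> DigitizedSeries:
    """Evenly spaced noisy points from the spec's true Weibull curve."""
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(spec.t_start, spec.t_end, spec.n_points)
    surv = spec.truth.survival(times)
    if spec.noise_sd > 0:
        surv = surv + rng.normal(0.0, spec.noise_sd, size=times.size)
    surv = np.clip(surv, _SURVIVAL_FLOOR, 1.0)
    surv = np.minimum.accumulate(surv)
    return DigitizedSeries(
        times=times,
        survival=surv,
        endpoint_label=spec.endpoint_label,
        arm_label=spec.arm_label,
    )


def write_series(series: DigitizedSeries, path: str | Path, spec: GeneratorSpec | None = None) -> None:
    """Write the CSV the calibration path consumes, plus a ground-truth sidecar."""
    path = Path(path)
    series.to_csv(path)
    if spec is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(
            json.dumps(
                {
                    "shape": spec.shape,
                    "scale": spec.scale,
                    "endpoint_label": spec.endpoint_label,
                    "arm_label": spec.arm_label,
                    "noise_sd": spec.noise_sd,
                    "seed": spec.seed,
                },
                indent=2,
            )
            + "\n"
        )


def generate_cost_fixture(seed: int = 0) -> CostTable:
    """A randomized but structurally valid cost table.

    Same item set as the bundled tables, positive prices drawn
    log-uniformly near each item's real magnitude, ranges exactly
    0.8x/1.2x.  Distinct from the published data; for property tests.
    """
    rng = np.random.default_rng(seed)
    reference = load_cost_table("US")
    items: dict[str, CostItem] = {}
    for name, entry in reference.items().items():
        anchor = entry.base if entry.base else 100.0
        base = float(anchor * np.exp(rng.uniform(-0.5, 0.5)))
        items[name] = CostItem(
            unit=entry.unit, base=base, low=0.8 * base, high=1.2 * base
        )
    return CostTable(items, country="synthetic")
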