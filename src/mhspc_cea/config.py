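"""Model configuration: every tunable the base case resolves.

All modelling choices the published evidence leaves open live here
with documented defaults so a run is
reproducible bit-for-bit from its audit log: the assumed Weibull shape,
which progression endpoint drives the model, resource-use frequencies,
the docetaxel fraction, and the ADT backbone mix.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

from .costs import ORAL_UNITS_PER_DAY, MonitoringSchedule, RegimenConfig
from .errors import ValidationError
from .markov import ModelSettings

__all__ = ["ModelConfig", "ClinicalEvidence"]


@dataclass(frozen=True)
class ModelConfig:
    """Structural and costing choices shared by both arms.

    Attributes
    ----------
    weibull_shape
        Shape assumed under landmark calibration (one landmark cannot
        identify two parameters).  Default 1.0 = exponential.
    pfs_endpoint
        Which progression definition drives the PFS state:
        ``clinical_PFS`` (default) or ``PSA_PFS``.
    calibration_mode
        ``landmark_hr`` (closed form from published landmarks and hazard
        ratios; default) or ``digitized`` (least-squares fit to point
        series supplied by the caller).
    antiandrogen
        Conventional non-steroidal antiandrogen costed in the
        standard-care arm.
    lhrh_mix
        Weights over ADT backbone agents (must sum to 1); default 100%
        goserelin monthly depot.
    docetaxel_fraction
        Fraction of the cohort receiving an early docetaxel course,
        applied identically in both arms.
    """

    weibull_shape: float = 1.0
    pfs_endpoint: str = "clinical_PFS"
    calibration_mode: str = "landmark_hr"
    antiandrogen: str = "bicalutamide"
    lhrh_mix: Mapping[str, float] = field(
        default_factory=lambda: {"goserelin": 1.0}
    )
    docetaxel_fraction: float = 0.45
    n_chemo_cycles: int = 6
    days_per_cycle: float = 365.25 / 12.0
    schedule_pfs: MonitoringSchedule = field(default_factory=MonitoringSchedule)
    schedule_pd: MonitoringSchedule = field(default_factory=MonitoringSchedule)
    cycle_length_months: float = 1.0
    horizon_cycles: int = 240
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.pfs_endpoint not in ("clinical_PFS", "PSA_PFS"):
            raise ValidationError(
                f"pfs_endpoint must be 'clinical_PFS' or 'PSA_PFS', got {self.pfs_endpoint!r}"
            )
        if self.calibration_mode not in ("landmark_hr", "digitized"):
            raise ValidationError(
                f"calibration_mode must be 'landmark_hr' or 'digitized', got {self.calibration_mode!r}"
            )
        if self.antiandrogen not in ORAL_UNITS_PER_DAY:
            raise ValidationError(f"unknown antiandrogen {self.antiandrogen!r}")
        if not self.weibull_shape > 0:
            raise ValidationError("weibull_shape must be > 0")
        if not 0.0 <= self.docetaxel_fraction <= 1.0:
            raise ValidationError("docetaxel_fraction must lie in [0, 1]")
        object.__setattr__(self, "lhrh_mix", dict(self.lhrh_mix))

    def regimen(self, arm: str) -> RegimenConfig:
        """Per-arm regimen: enzalutamide replaces the antiandrogen."""
        if arm == "enzalutamide":
            oral = "enzalutamide"
        elif arm == "standard_care":
            oral = self.antiandrogen
        else:
            raise ValidationError(f"unknown arm {arm!r}")
        return RegimenConfig(
            arm=arm,
            oral_agent=oral,
            oral_units_per_day=ORAL_UNITS_PER_DAY[oral],
            lhrh_mix=self.lhrh_mix,
            docetaxel_fraction=self.docetaxel_fraction,
            n_chemo_cycles=self.n_chemo_cycles,
            days_per_cycle=self.days_per_cycle,
            schedule_pfs=self.schedule_pfs,
            schedule_pd=self.schedule_pd,
        )

    def settings(self, annual_discount_rate: float) -> ModelSettings:
        return ModelSettings(
            cycle_length_months=self.cycle_length_months,
            n_cycles=self.horizon_cycles,
            annual_discount_rate=annual_discount_rate,
            half_cycle_correction=self.half_cycle_correction,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form; for the audit log."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class ClinicalEvidence:
    """Published efficacy and safety evidence driving the model.

    ``landmarks[endpoint][arm]`` are survival fractions at
    ``landmark_time_months``; ``hazard_ratios[endpoint]`` compare the
    enzalutamide arm with standard care; ``ae_incidence[arm][event]``
    are cumulative grade 3-4 adverse-event fractions.
    """

    landmark_time_months: float
    landmarks: dict[str, dict[str, float]]
    hazard_ratios: dict[str, float]
    ae_incidence: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if not self.landmark_time_months > 0:
            raise ValidationError("landmark_time_months must be > 0")
        for endpoint, by_arm in self.landmarks.items():
            for arm, frac in by_arm.items():
                if not 0.0 < frac < 1.0:
                    raise ValidationError(
                        f"landmark {endpoint}/{arm} must lie in (0, 1), got {frac}"
                    )
        for endpoint, hr in self.hazard_ratios.items():
            if not hr > 0:
                raise ValidationError(f"hazard ratio for {endpoint} must be > 0")
        for arm, events in self.ae_incidence.items():
            for event, inc in events.items():
                if not 0.0 <= inc <= 1.0:
                    raise ValidationError(
                        f"AE incidence {arm}/{event} must lie in [0, 1], got {inc}"
                    )

    def copy(self) -> "ClinicalEvidence":
        return copy.deepcopy(self)
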