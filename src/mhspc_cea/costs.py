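"""Per-cycle state costs and one-off costs per arm and perspective.

Costing follows the payer perspective: drug acquisition (oral agent plus
LHRH background therapy), best-supportive care in the progressed state,
routine follow-up, monitoring tests, a docetaxel course for the fraction
of the cohort receiving early chemotherapy, and one-off management costs
for grade 3-4 adverse events weighted by their cumulative incidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import MissingPriceError, ValidationError

__all__ = [
    "Perspective",
    "CostItem",
    "CostTable",
    "MonitoringSchedule",
    "RegimenConfig",
    "ORAL_UNITS_PER_DAY",
    "DEPOTS_PER_CYCLE",
    "AE_ITEMS",
    "drug_cost_per_cycle",
    "docetaxel_course_cost",
    "expected_ae_cost",
    "state_cost_per_cycle",
    "one_off_entry_cost",
]

# Daily unit counts implied by the licensed dosing of each oral agent:
# enzalutamide 160 mg = 4 x 40 mg; bicalutamide 50 mg = 1 x 50 mg;
# nilutamide 150 mg = 1 x 150 mg; flutamide 250 mg three times daily
# = 750 mg/day = 6 x 125 mg.
ORAL_UNITS_PER_DAY: dict[str, float] = {
    "enzalutamide": 4.0,
    "bicalutamide": 1.0,
    "nilutamide": 1.0,
    "flutamide": 6.0,
}

# Depot administrations per monthly cycle.  The histrelin implant lasts
# twelve months, hence 1/12 per cycle.  Orchiectomy is surgical
# castration, a one-off procedure handled at model entry, not here.
DEPOTS_PER_CYCLE: dict[str, float] = {
    "goserelin": 1.0,
    "leuprolide": 1.0,
    "triptorelin": 1.0,
    "degarelix": 1.0,
    "histrelin": 1.0 / 12.0,
}

AE_ITEMS = (
    "febrile_neutropenia",
    "hypertension",
    "neutrophil_count_decreased",
    "fatigue",
)

DOCETAXEL_DOSE_MG_PER_M2 = 75.0
DOCETAXEL_VIAL_MG = 20.0
MAX_CHEMO_CYCLES = 6


@dataclass(frozen=True)
class Perspective:
    """Country-specific payer constants: discounting, WTP, utilities, BSA."""

    country: str
    annual_discount_rate: float
    wtp_per_qaly: float
    utility_pfs: float
    utility_pd: float
    bsa: float

    def __post_init__(self) -> None:
        if not self.wtp_per_qaly > 0:
            raise ValidationError("wtp_per_qaly must be > 0")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError("annual_discount_rate must lie in [0, 1)")
        for name in ("utility_pfs", "utility_pd"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {u}")
        if not self.bsa > 0:
            raise ValidationError("bsa must be > 0")


@dataclass
class CostItem:
    """One priced resource: unit description, base price, low/high range."""

    unit: str
    base: float | None
    low: float | None = None
    high: float | None = None


class CostTable:
    """Unit prices with their sensitivity ranges for one country.

    Missing prices (a resource not marketed in that country) are carried
    as ``None`` and raise :class:`MissingPriceError` when requested —
    never a silent zero.
    """

    def __init__(self, items: Mapping[str, CostItem], country: str | None = None):
        self._items: dict[str, CostItem] = {
            k: replace(v) for k, v in items.items()
        }
        self.country = country
        for name, it in self._items.items():
            if it.base is not None and it.base < 0:
                raise ValidationError(f"price for {name!r} must be >= 0")

    # -- access --------------------------------------------------------

    def __contains__(self, item: str) -> bool:
        return item in self._items

    def items(self) -> dict[str, CostItem]:
        return dict(self._items)

    def has_price(self, item: str) -> bool:
        return item in self._items and self._items[item].base is not None

    def _get(self, item: str) -> CostItem:
        where = f" ({self.country})" if self.country else ""
        if item not in self._items:
            raise MissingPriceError(f"no cost entry for {item!r}{where}")
        entry = self._items[item]
        if entry.base is None:
            raise MissingPriceError(f"{item!r} has no unit price{where}")
        return entry

    def price(self, item: str) -> float:
        return float(self._get(item).base)

    def bounds(self, item: str) -> tuple[float, float]:
        entry = self._get(item)
        if entry.low is None or entry.high is None:
            return 0.8 * entry.base, 1.2 * entry.base
        return float(entry.low), float(entry.high)

    # -- mutation (sensitivity analyses work on copies) ----------------

    def set_price(self, item: str, base: float) -> None:
        if base < 0:
            raise ValidationError("price must be >= 0")
        self._get(item)  # raises if the item is unpriced
        self._items[item].base = float(base)

    def copy(self) -> "CostTable":
        return CostTable(self._items, country=self.country)

    def scaled(self, alpha: float) -> "CostTable":
        """All prices (and ranges) multiplied by ``alpha``; for tests."""
        if alpha < 0:
            raise ValidationError("alpha must be >= 0")
        scaled = {
            k: CostItem(
                unit=v.unit,
                base=None if v.base is None else v.base * alpha,
                low=None if v.low is None else v.low * alpha,
                high=None if v.high is None else v.high * alpha,
            )
            for k, v in self._items.items()
        }
        return CostTable(scaled, country=self.country)

    def validate_ranges(self, tol: float = 0.01) -> None:
        """Check low/high are 0.8x/1.2x the base price within ``tol``."""
        for name, it in self._items.items():
            if it.base is None:
                continue
            if it.low is None or it.high is None:
                raise ValidationError(f"{name!r} has a price but no range")
            if abs(it.low - 0.8 * it.base) > tol or abs(it.high - 1.2 * it.base) > tol:
                raise ValidationError(
                    f"{name!r}: range ({it.low}, {it.high}) is not +/-20% of {it.base}"
                )

    # -- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"item": k, "unit": v.unit, "base": v.base, "low": v.low, "high": v.high}
                for k, v in self._items.items()
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, country: str | None = None) -> "CostTable":
        required = {"item", "unit", "base", "low", "high"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"cost table missing columns {sorted(missing)}")
        items = {}
        for row in df.itertuples(index=False):
            items[row.item] = CostItem(
                unit=str(row.unit),
                base=None if pd.isna(row.base) else float(row.base),
                low=None if pd.isna(row.low) else float(row.low),
                high=None if pd.isna(row.high) else float(row.high),
            )
        return cls(items, country=country)

    @classmethod
    def from_csv(cls, path: str | Path, country: str | None = None) -> "CostTable":
        return cls.from_frame(pd.read_csv(path), country=country)


@dataclass(frozen=True)
class MonitoringSchedule:
    """Resource-use frequencies per monthly cycle.

    The unit prices are published but the frequencies are a modelling
    choice: follow-up, laboratory panel and PSA test every cycle; CT and
    bone scan every third cycle.
    """

    follow_up: float = 1.0
    laboratory: float = 1.0
    psa_test: float = 1.0
    ct: float = 1.0 / 3.0
    bone_scan: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("follow_up", "laboratory", "psa_test", "ct", "bone_scan"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} frequency must be >= 0")


@dataclass(frozen=True)
class RegimenConfig:
    """Everything needed to cost one arm's treatment strategy."""

    arm: str
    oral_agent: str
    oral_units_per_day: float
    lhrh_mix: Mapping[str, float] = field(
        default_factory=lambda: {"goserelin": 1.0}
    )
    docetaxel_fraction: float = 0.45
    n_chemo_cycles: int = MAX_CHEMO_CYCLES
    days_per_cycle: float = 365.25 / 12.0
    schedule_pfs: MonitoringSchedule = field(default_factory=MonitoringSchedule)
    schedule_pd: MonitoringSchedule = field(default_factory=MonitoringSchedule)

    def __post_init__(self) -> None:
        if self.arm not in ("enzalutamide", "standard_care"):
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.oral_units_per_day < 0:
            raise ValidationError("oral_units_per_day must be >= 0")
        if not 0.0 <= self.docetaxel_fraction <= 1.0:
            raise ValidationError("docetaxel_fraction must lie in [0, 1]")
        weights = dict(self.lhrh_mix)
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValidationError("lhrh_mix weights must sum to 1")
        for agent, w in weights.items():
            if w < 0:
                raise ValidationError(f"lhrh_mix weight for {agent!r} must be >= 0")
            if agent not in DEPOTS_PER_CYCLE and agent != "orchiectomy":
                raise ValidationError(f"unknown ADT backbone agent {agent!r}")
        object.__setattr__(self, "lhrh_mix", weights)
        if not self.days_per_cycle > 0:
            raise ValidationError("days_per_cycle must be > 0")
        if not 0 <= self.n_chemo_cycles <= MAX_CHEMO_CYCLES:
            raise ValidationError(
                f"n_chemo_cycles must lie in [0, {MAX_CHEMO_CYCLES}]"
            )


def drug_cost_per_cycle(
    regimen: RegimenConfig,
    prices: CostTable,
    perspective: Perspective | None = None,
    *,
    breakdown: bool = False,
):
    """On-treatment drug acquisition cost per monthly cycle.

    Oral agent: daily units x days per cycle x unit price.  ADT
    backbone: mix-weighted depot cost per cycle (orchiectomy weight
    contributes at entry instead, see :func:`one_off_entry_cost`).
    """
    oral = (
        regimen.oral_units_per_day
        * regimen.days_per_cycle
        * prices.price(regimen.oral_agent)
    )
    lhrh = sum(
        w * DEPOTS_PER_CYCLE[agent] * prices.price(agent)
        for agent, w in regimen.lhrh_mix.items()
        if agent != "orchiectomy" and w > 0
    )
    if breakdown:
        return {"oral": oral, "lhrh": lhrh, "total": oral + lhrh}
    return oral + lhrh


def docetaxel_course_cost(
    perspective: Perspective,
    prices: CostTable,
    n_chemo_cycles: int = MAX_CHEMO_CYCLES,
) -> float:
    """One-off cost of a docetaxel course at 75 mg/m2 every 3 weeks.

    Whole-vial wastage: the per-administration dose is rounded up to
    whole 20 mg vials.
    """
    if not 0 <= n_chemo_cycles <= MAX_CHEMO_CYCLES:
        raise ValidationError(f"n_chemo_cycles must lie in [0, {MAX_CHEMO_CYCLES}]")
    if n_chemo_cycles == 0:
        return 0.0
    dose_mg = DOCETAXEL_DOSE_MG_PER_M2 * perspective.bsa
    vials = math.ceil(dose_mg / DOCETAXEL_VIAL_MG)
    return vials * prices.price("docetaxel") * n_chemo_cycles


def expected_ae_cost(
    ae_incidences: Mapping[str, float],
    ae_unit_costs: CostTable,
    perspective: Perspective | None = None,
) -> float:
    """Expected adverse-event management cost, applied once at entry.

    Sum over events of cumulative incidence x management cost.  An event
    with an incidence but no price raises :class:`MissingPriceError`.
    """
    total = 0.0
    for event, incidence in ae_incidences.items():
        if not 0.0 <= incidence <= 1.0:
            raise ValidationError(f"incidence for {event!r} must lie in [0, 1]")
        total += incidence * ae_unit_costs.price(event)
    return total


def _monitoring_cost(schedule: MonitoringSchedule, prices: CostTable) -> float:
    return (
        schedule.laboratory * prices.price("laboratory_tests")
        + schedule.psa_test * prices.price("psa_test")
        + schedule.ct * prices.price("ct")
        + schedule.bone_scan * prices.price("bone_scan")
    )


def state_cost_per_cycle(
    state: str,
    regimen: RegimenConfig,
    prices: CostTable,
    perspective: Perspective | None = None,
) -> float:
    """Per-cycle cost of occupying one health state.

    PFS: on-treatment drugs + monitoring tests + follow-up.
    PD: best-supportive care + follow-up + monitoring (drug acquisition
    stops at progression).
    """
    if state == "PFS":
        sched = regimen.schedule_pfs
        return (
            drug_cost_per_cycle(regimen, prices, perspective)
            + _monitoring_cost(sched, prices)
            + sched.follow_up * prices.price("follow_up")
        )
    if state == "PD":
        sched = regimen.schedule_pd
        return (
            prices.price("bsc_per_cycle")
            + sched.follow_up * prices.price("follow_up")
            + _monitoring_cost(sched, prices)
        )
    raise ValidationError(f"state must be 'PFS' or 'PD', got {state!r}")


def one_off_entry_cost(
    regimen: RegimenConfig,
    ae_incidences: Mapping[str, float],
    prices: CostTable,
    perspective: Perspective,
    *,
    breakdown: bool = False,
):
    """Costs charged once at model entry.

    Docetaxel course for the configured cohort fraction, surgical
    castration for any orchiectomy weight in the ADT mix, and expected
    adverse-event management costs.
    """
    docetaxel = regimen.docetaxel_fraction * docetaxel_course_cost(
        perspective, prices, regimen.n_chemo_cycles
    )
    orchiectomy_w = regimen.lhrh_mix.get("orchiectomy", 0.0)
    orchiectomy = orchiectomy_w * prices.price("orchiectomy") if orchiectomy_w else 0.0
    ae = expected_ae_cost(ae_incidences, prices, perspective)
    if breakdown:
        return {
            "docetaxel": docetaxel,
            "orchiectomy": orchiectomy,
            "adverse_events": ae,
            "total": docetaxel + orchiectomy + ae,
        }
    return docetaxel + orchiectomy + ae
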