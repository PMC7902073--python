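"""One-way (tornado) and probabilistic sensitivity analysis.

Every uncertain input is wrapped as a :class:`Parameter` with a base
value, low/high bounds (the published +/-20% ranges for costs; +/-20%
capped at 1 for utilities; +/-20% on the logit scale for survival
landmarks) and a pure ``apply`` function that writes a candidate value
into a copy of the model inputs.  The tornado re-runs the base case at
each bound; the PSA draws all parameters jointly from conventional
distributions (beta for probabilities/utilities, gamma for costs,
log-normal for hazard ratios), with a uniform-over-range fallback that
stays strictly inside the published ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .economics import BaseCaseResult, ModelInputs, run_base_case
from .errors import StructuralInconsistencyError, ValidationError

__all__ = [
    "Parameter",
    "TornadoEntry",
    "PsaSample",
    "PsaResult",
    "default_parameters",
    "degenerate_parameters",
    "one_way_sa",
    "tornado_frame",
    "probabilistic_sa",
    "ceac",
    "ceac_frame",
]

_SQRT12 = math.sqrt(12.0)


@dataclass(frozen=True)
class Parameter:
    """One uncertain input with bounds and a setter into ModelInputs.

    ``kind`` selects the PSA distribution family: ``cost`` -> gamma,
    ``utility``/``landmark`` -> beta, ``hazard_ratio`` -> log-normal,
    ``discount_rate`` -> varied in the tornado only.
    """

    name: str
    base: float
    low: float
    high: float
    kind: str
    apply: Callable[[ModelInputs, float], None] = field(compare=False)

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValidationError(
                f"{self.name}: bounds ({self.low}, {self.high}) must bracket "
                f"the base value {self.base}"
            )


def _set_cost(item: str) -> Callable[[ModelInputs, float], None]:
    def apply(inputs: ModelInputs, value: float) -> None:
        inputs.cost_table.set_price(item, value)

    return apply


def _set_utility(attr: str) -> Callable[[ModelInputs, float], None]:
    def apply(inputs: ModelInputs, value: float) -> None:
        inputs.perspective = replace(inputs.perspective, **{attr: value})

    return apply


def _set_discount(inputs: ModelInputs, value: float) -> None:
    inputs.perspective = replace(inputs.perspective, annual_discount_rate=value)


def _set_hr(endpoint: str) -> Callable[[ModelInputs, float], None]:
    def apply(inputs: ModelInputs, value: float) -> None:
        inputs.evidence.hazard_ratios[endpoint] = value

    return apply


def _set_landmark(endpoint: str, arm: str) -> Callable[[ModelInputs, float], None]:
    def apply(inputs: ModelInputs, value: float) -> None:
        inputs.evidence.landmarks[endpoint][arm] = value

    return apply


def _logit_bounds(p: float, rel: float = 0.2) -> tuple[float, float]:
    """+/-rel variation of logit(p), mapped back to (0, 1) and sorted."""
    logit = math.log(p / (1.0 - p))
    a = 1.0 / (1.0 + math.exp(-(1.0 - rel) * logit))
    b = 1.0 / (1.0 + math.exp(-(1.0 + rel) * logit))
    return (a, b) if a <= b else (b, a)


def default_parameters(inputs: ModelInputs) -> list[Parameter]:
    """The standard uncertain-parameter set for the given inputs.

    Covers every cost item the default regimens touch, both utilities,
    the discount rate, the standard-care survival landmarks (logit
    scale) and the two hazard ratios.
    """
    cfg = inputs.config
    persp = inputs.perspective
    evidence = inputs.evidence
    params: list[Parameter] = []

    cost_items: list[str] = ["enzalutamide", cfg.antiandrogen]
    cost_items += [a for a in cfg.lhrh_mix if cfg.lhrh_mix[a] > 0]
    if cfg.docetaxel_fraction > 0:
        cost_items.append("docetaxel")
    cost_items += [
        "laboratory_tests",
        "psa_test",
        "ct",
        "bone_scan",
        "bsc_per_cycle",
        "follow_up",
        "febrile_neutropenia",
        "hypertension",
        "neutrophil_count_decreased",
        "fatigue",
    ]
    for item in cost_items:
        base = inputs.cost_table.price(item)
        low, high = inputs.cost_table.bounds(item)
        params.append(
            Parameter(
                name=f"cost_{item}",
                base=base,
                low=low,
                high=high,
                kind="cost",
                apply=_set_cost(item),
            )
        )

    for attr in ("utility_pfs", "utility_pd"):
        u = getattr(persp, attr)
        params.append(
            Parameter(
                name=attr,
                base=u,
                low=0.8 * u,
                high=min(1.0, 1.2 * u),
                kind="utility",
                apply=_set_utility(attr),
            )
        )

    r = persp.annual_discount_rate
    params.append(
        Parameter(
            name="discount_rate",
            base=r,
            low=0.8 * r,
            high=1.2 * r,
            kind="discount_rate",
            apply=_set_discount,
        )
    )

    for endpoint in ("OS", cfg.pfs_endpoint):
        p = evidence.landmarks[endpoint]["standard_care"]
        low, high = _logit_bounds(p)
        params.append(
            Parameter(
                name=f"landmark_{endpoint}_standard_care",
                base=p,
                low=low,
                high=high,
                kind="landmark",
                apply=_set_landmark(endpoint, "standard_care"),
            )
        )
        hr = evidence.hazard_ratios[endpoint]
        params.append(
            Parameter(
                name=f"hr_{endpoint}",
                base=hr,
                low=0.8 * hr,
                high=1.2 * hr,
                kind="hazard_ratio",
                apply=_set_hr(endpoint),
            )
        )
    return params


def degenerate_parameters(parameters: Iterable[Parameter]) -> list[Parameter]:
    """Collapse every parameter's range onto its base value (for tests)."""
    return [replace(p, low=p.base, high=p.base) for p in parameters]


# ---------------------------------------------------------------------
# One-way sensitivity analysis (tornado)
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    """ICERs at one parameter's bounds; the swing orders the tornado."""

    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_value(result: BaseCaseResult) -> float:
    """Numeric ICER for ordering; dominance mapped to signed infinity."""
    if result.icer.is_ratio:
        return float(result.icer.value)
    if result.icer.flag == "dominant":
        return -math.inf
    if result.icer.flag == "dominated":
        return math.inf
    return math.nan


def one_way_sa(
    inputs: ModelInputs,
    parameters: Sequence[Parameter] | None = None,
    names: Sequence[str] | None = None,
) -> list[TornadoEntry]:
    """Re-run the base case at each parameter's low and high bound.

    The default set is utilities, unit costs, the discount rate and the
    standard-care survival landmarks; hazard ratios are sampled in the
    PSA instead.  ``names`` restricts the analysis to a subset of the
    default parameters (unknown names raise).  Each re-run is pure: it
    works on a fresh copy of the inputs with a single parameter
    displaced, so entries are order-independent.  Returned sorted by
    swing, largest first (tornado order).
    """
    if parameters is None:
        parameters = [
            p for p in default_parameters(inputs) if p.kind != "hazard_ratio"
        ]
    if names is not None:
        by_name = {p.name: p for p in parameters}
        unknown = [n for n in names if n not in by_name]
        if unknown:
            raise ValidationError(f"unknown parameter name(s): {unknown}")
        parameters = [by_name[n] for n in names]
    entries = []
    for param in parameters:
        icers = {}
        for bound in ("low", "high"):
            candidate = inputs.copy()
            param.apply(candidate, getattr(param, bound))
            icers[bound] = _icer_value(run_base_case(candidate))
        entries.append(
            TornadoEntry(
                parameter=param.name,
                low=param.low,
                high=param.high,
                icer_at_low=icers["low"],
                icer_at_high=icers["high"],
            )
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PsaSample:
    """One Monte Carlo iteration: sampled inputs and increments."""

    iteration: int
    parameters: dict[str, float]
    delta_cost: float
    delta_qalys: float

    def cost_effective(self, wtp: float) -> bool:
        """Strictly positive incremental net monetary benefit."""
        return wtp * self.delta_qalys - self.delta_cost > 0


def _make_sampler(param: Parameter, family: str) -> Callable[[np.random.Generator], float]:
    """Build and validate one parameter's sampling function up front."""
    base, low, high = param.base, param.low, param.high
    if high == low:
        return lambda rng: base
    if family == "uniform":
        return lambda rng: rng.uniform(low, high)
    if family != "conventional":
        raise ValidationError(f"unknown distribution family {family!r}")

    sd = (high - low) / _SQRT12  # moment-matched to a uniform over the range
    if param.kind == "cost":
        if base <= 0:
            return lambda rng: base
        shape = (base / sd) ** 2
        scale = sd**2 / base
        return lambda rng: rng.gamma(shape, scale)
    if param.kind in ("utility", "landmark"):
        var = sd**2
        if var >= base * (1.0 - base):
            raise ValidationError(
                f"{param.name}: variance too large for a beta distribution"
            )
        nu = base * (1.0 - base) / var - 1.0
        return lambda rng: rng.beta(base * nu, (1.0 - base) * nu)
    if param.kind == "hazard_ratio":
        sigma = (math.log(high) - math.log(low)) / _SQRT12
        mu = math.log(base)
        return lambda rng: rng.lognormal(mu, sigma)
    raise ValidationError(
        f"{param.name}: kind {param.kind!r} has no PSA distribution"
    )


@dataclass
class PsaResult:
    """All PSA samples plus bookkeeping."""

    samples: list[PsaSample]
    wtp_per_qaly: float
    seed: int
    n_rejected: int = 0

    def fraction_cost_effective(self, wtp: float | None = None) -> float:
        if not self.samples:
            raise ValidationError("no PSA samples")
        wtp = self.wtp_per_qaly if wtp is None else wtp
        return float(np.mean([s.cost_effective(wtp) for s in self.samples]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iter": s.iteration,
                    "delta_cost": s.delta_cost,
                    "delta_qalys": s.delta_qalys,
                }
                for s in self.samples
            ]
        )


def probabilistic_sa(
    inputs: ModelInputs,
    n_iterations: int = 1000,
    seed: int = 0,
    parameters: Sequence[Parameter] | None = None,
    family: str = "conventional",
    max_rejections: int = 1000,
) -> PsaResult:
    """Monte Carlo PSA: joint parameter draws, full model re-run each.

    The discount rate is held at its base value (structural, not
    sampled).  Draws that make the PFS curve cross above the OS curve —
    structurally impossible occupancy — are rejected and redrawn; the
    count is reported.  Identical (seed, inputs) give identical samples.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if parameters is None:
        parameters = default_parameters(inputs)
    sampled = [p for p in parameters if p.kind != "discount_rate"]
    samplers = [(p, _make_sampler(p, family)) for p in sampled]  # validates now

    rng = np.random.default_rng(seed)
    samples: list[PsaSample] = []
    n_rejected = 0
    for it in range(n_iterations):
        while True:
            draw = {p.name: float(fn(rng)) for p, fn in samplers}
            candidate = inputs.copy()
            for p, _ in samplers:
                p.apply(candidate, draw[p.name])
            try:
                result = run_base_case(candidate)
            except StructuralInconsistencyError:
                n_rejected += 1
                if n_rejected > max_rejections:
                    raise
                continue
            break
        samples.append(
            PsaSample(
                iteration=it,
                parameters=draw,
                delta_cost=result.incremental_cost,
                delta_qalys=result.incremental_qalys,
            )
        )
    return PsaResult(
        samples=samples,
        wtp_per_qaly=inputs.perspective.wtp_per_qaly,
        seed=seed,
        n_rejected=n_rejected,
    )


def ceac(samples: Sequence[PsaSample], wtp_grid) -> np.ndarray:
    """Probability cost-effective at each WTP (strict NMB > 0 rule)."""
    if len(samples) == 0:
        raise ValidationError("ceac requires at least one PSA sample")
    wtp = np.asarray(wtp_grid, dtype=float)
    if np.any(wtp < 0):
        raise ValidationError("wtp values must be >= 0")
    d_cost = np.array([s.delta_cost for s in samples])
    d_eff = np.array([s.delta_qalys for s in samples])
    nmb = wtp[:, None] * d_eff[None, :] - d_cost[None, :]
    return (nmb > 0).mean(axis=1)


def ceac_frame(samples: Sequence[PsaSample], wtp_grid) -> pd.DataFrame:
    return pd.DataFrame(
        {"wtp": np.asarray(wtp_grid, float), "probability": ceac(samples, wtp_grid)}
    )
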