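"""Loaders for the bundled model inputs.

The package ships the published unit-cost tables (one CSV per country)
and the clinical evidence / perspective constants (one YAML file).  All
loaders accept a path override so users can substitute their own data
in the same dialect.
"""

from __future__ import annotations

from functools import lru_cache
from importlib.resources import files
from pathlib import Path

import yaml

from .config import ClinicalEvidence
from .costs import CostTable, Perspective
from .errors import ValidationError

__all__ = [
    "COUNTRIES",
    "load_cost_table",
    "load_clinical_inputs",
    "get_perspective",
    "get_clinical_evidence",
]

COUNTRIES = ("US", "China")

_COST_FILES = {"US": "costs_us.csv", "China": "costs_china.csv"}


def _normalize_country(country: str) -> str:
    for name in COUNTRIES:
        if country.lower() == name.lower():
            return name
    raise ValidationError(f"unknown country {country!r}; expected one of {COUNTRIES}")


def load_cost_table(country: str = "US", path: str | Path | None = None) -> CostTable:
    """The unit-cost table for one country (or from a user CSV)."""
    if path is not None:
        return CostTable.from_csv(path, country=country)
    country = _normalize_country(country)
    resource = files("mhspc_cea.data") / _COST_FILES[country]
    with resource.open("r") as fh:
        import pandas as pd

        return CostTable.from_frame(pd.read_csv(fh), country=country)


@lru_cache(maxsize=1)
def load_clinical_inputs() -> dict:
    """Raw clinical-inputs mapping (landmarks, HRs, AEs, perspectives)."""
    resource = files("mhspc_cea.data") / "clinical_inputs.yaml"
    with resource.open("r") as fh:
        return yaml.safe_load(fh)


def get_perspective(country: str = "US") -> Perspective:
    country = _normalize_country(country)
    raw = load_clinical_inputs()["perspectives"][country]
    return Perspective(country=country, **raw)


def get_clinical_evidence() -> ClinicalEvidence:
    raw = load_clinical_inputs()
    return ClinicalEvidence(
        landmark_time_months=raw["landmark_time_months"],
        landmarks={k: dict(v) for k, v in raw["landmarks"].items()},
        hazard_ratios=dict(raw["hazard_ratios"]),
        ae_incidence={k: dict(v) for k, v in raw["ae_incidence"].items()},
    )
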