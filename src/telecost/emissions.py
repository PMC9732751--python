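"""Avoided-travel emission accounting and environmental costs.

Car emission factors are grams per passenger-kilometer (pkm), already
normalized to an average occupancy of 1.4 passengers by the issuing agency —
no further division by occupancy is performed; the occupancy is stored as
provenance metadata only.

The environmental cost rate (euros per pkm) is an independent agency figure,
not derived here from carbon price × greenhouse-gas factor: the per-pkm rate
covers damage beyond CO2-equivalents.  Two linked presets are bundled — the
base valuation discounting future welfare (€195/t CO2e ↔ €0.05045/pkm) and
the equal-generational-welfare valuation (€680/t CO2e ↔ €0.12885/pkm).
Overriding one member of a preset pair without the other is flagged with a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

#: pollutant keys in reporting order
POLLUTANTS = (
    "greenhouse_gases",
    "carbon_monoxide",
    "volatile_hydrocarbons",
    "nitrogen_oxides",
    "particulates",
)

#: g/pkm for an average German car fleet at occupancy 1.4
DEFAULT_FACTORS_G_PER_PKM: Dict[str, float] = {
    "greenhouse_gases": 152.0,
    "carbon_monoxide": 0.94,
    "volatile_hydrocarbons": 0.15,
    "nitrogen_oxides": 0.38,
    "particulates": 0.006,
}

#: linked (carbon price €/t CO2e → environmental cost €/pkm) presets
CARBON_PRICE_PRESETS: Dict[float, float] = {195.0: 0.05045, 680.0: 0.12885}


class EmissionModel(BaseModel):
    """Per-pollutant emission factors plus environmental cost valuation."""

    model_config = ConfigDict(frozen=True)

    factors_g_per_pkm: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FACTORS_G_PER_PKM)
    )
    car_occupancy: float = Field(default=1.4, gt=0)
    env_cost_per_pkm: float = Field(default=0.05045, gt=0)
    carbon_price_eur_per_tonne: float = Field(default=195.0, gt=0)

    @field_validator("factors_g_per_pkm")
    @classmethod
    def _known_positive_factors(cls, factors: Mapping[str, float]) -> Dict[str, float]:
        unknown = set(factors) - set(POLLUTANTS)
        if unknown:
            raise ValueError(
                f"unknown pollutant keys {sorted(unknown)}; valid: {list(POLLUTANTS)}"
            )
        bad = {k: v for k, v in factors.items() if v <= 0}
        if bad:
            raise ValueError(f"emission factors must be positive: {bad}")
        return dict(factors)

    @model_validator(mode="after")
    def _warn_on_broken_preset(self) -> "EmissionModel":
        expected = CARBON_PRICE_PRESETS.get(self.carbon_price_eur_per_tonne)
        if expected is not None and abs(self.env_cost_per_pkm - expected) > 1e-12:
            logger.warning(
                "carbon price %s €/t is a preset paired with %s €/pkm but "
                "env_cost_per_pkm=%s — the two valuations are inconsistent",
                self.carbon_price_eur_per_tonne,
                expected,
                self.env_cost_per_pkm,
            )
        return self

    @classmethod
    def equal_welfare(cls) -> "EmissionModel":
        """Preset giving equal weight to present and future generations."""
        return cls(env_cost_per_pkm=0.12885, carbon_price_eur_per_tonne=680.0)


@dataclass(frozen=True)
class EmissionsResult:
    """Avoided emissions (kg per pollutant) and environmental cost (euros)."""

    pkm: float
    masses_kg: Dict[str, float]
    env_cost_eur: float
    basis: str  # per_patient | cohort_total | annual_scenario

    def scaled(self, factor: float, basis: Optional[str] = None) -> "EmissionsResult":
        return EmissionsResult(
            pkm=self.pkm * factor,
            masses_kg={k: v * factor for k, v in self.masses_kg.items()},
            env_cost_eur=self.env_cost_eur * factor,
            basis=basis or self.basis,
        )


class ExtrapolationScenario(BaseModel):
    """Annual volume scenario: weekly video consultations replacing clinic visits."""

    model_config = ConfigDict(frozen=True)

    patients_per_week: int = Field(default=8, ge=0)
    weeks_per_year: int = Field(default=48, ge=1)
    mean_one_way_distance_km: float = Field(ge=0)

    @property
    def annual_patients(self) -> int:
        return self.patients_per_week * self.weeks_per_year


def avoided_pkm(one_way_distance_km: float) -> float:
    """Passenger-kilometers avoided by one video consultation (round trip)."""
    if one_way_distance_km < 0:
        raise ValueError("distance must be non-negative")
    return 2.0 * one_way_distance_km


def emissions_saved(
    pkm: float, model: EmissionModel, *, basis: str = "per_patient"
) -> EmissionsResult:
    """Mass saved per pollutant: factor [g/pkm] × pkm / 1000 → kilograms."""
    if pkm < 0:
        raise ValueError("pkm must be non-negative")
    masses = {k: f * pkm / 1000.0 for k, f in model.factors_g_per_pkm.items()}
    return EmissionsResult(
        pkm=pkm,
        masses_kg=masses,
        env_cost_eur=environmental_cost(pkm, model),
        basis=basis,
    )


def environmental_cost(pkm: float, model: EmissionModel) -> float:
    """Environmental damage cost of the avoided travel: €/pkm × pkm."""
    if pkm < 0:
        raise ValueError("pkm must be non-negative")
    return model.env_cost_per_pkm * pkm


def annual_extrapolation(
    scenario: ExtrapolationScenario, model: EmissionModel
) -> EmissionsResult:
    """Annual savings if the scenario's weekly patient volume goes virtual.

    Annual pkm = patients/week × weeks/year × 2 × mean one-way distance.
    A zero-patient scenario returns zeros with a warning.
    """
    if scenario.patients_per_week == 0:
        logger.warning("annual extrapolation with zero patients per week: zero result")
    pkm = scenario.annual_patients * avoided_pkm(scenario.mean_one_way_distance_km)
    return emissions_saved(pkm, model, basis="annual_scenario")
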