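"""Societal-perspective cost model: travel costs, time costs, production losses.

All costs are linear in their inputs, so the cost of an arm-mean input equals
the arm-mean of per-patient costs; both a patient-level route
(:func:`summarize_records`) and an aggregate route
(:func:`summarize_aggregate`) are provided and must agree.

Composition of per-patient totals: travel-time and waiting-time costs are
reported but NOT added into totals — the valued "total time spent on the
appointment" already contains travelling and waiting, and adding them again
would double count.  So

    total (unemployed basis) = travel cost + total-time cost
    total (employed basis)   = above + mean production loss per employed

The telemedicine arm's actual travel and travel-time costs are zero (no trip
takes place); the counterfactual costs of the avoided trip are computed and
reported alongside but never enter totals.

The public API keeps full floating precision.  Published cost tables round
each component to cents before summing, so totals helpers expose a
``rounded`` flag that reproduces that convention (the discrepancy is below
one cent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .types import Arm, ArmAggregate, CostParameters, PatientRecord

__all__ = [
    "CostWithCounterfactual",
    "PatientCosts",
    "ArmCostSummary",
    "CostDifference",
    "travel_cost",
    "time_cost",
    "production_loss_per_absence",
    "arm_production_loss",
    "patient_costs",
    "summarize_records",
    "summarize_aggregate",
    "total_cost_per_patient",
    "cost_difference",
]


@dataclass(frozen=True)
class CostWithCounterfactual:
    """An actual cost plus the cost the avoided alternative would have had."""

    actual: float
    counterfactual: float


def travel_cost(
    one_way_distance_km: Optional[float], params: CostParameters, arm: Arm
) -> Optional[CostWithCounterfactual]:
    """Round-trip car travel cost: cost_per_km × 2 × one-way distance.

    Control arm: the trip happened, actual == counterfactual.  Telemedicine
    arm: actual cost is 0; the counterfactual is what the avoided trip would
    have cost.  A missing distance propagates as ``None``.
    """
    if one_way_distance_km is None:
        return None
    if one_way_distance_km < 0:
        raise ValueError("distance must be non-negative")
    round_trip = params.cost_per_km * 2.0 * one_way_distance_km
    if Arm(arm) is Arm.TELEMEDICINE:
        return CostWithCounterfactual(actual=0.0, counterfactual=round_trip)
    return CostWithCounterfactual(actual=round_trip, counterfactual=round_trip)


def time_cost(duration_min: Optional[float], params: CostParameters) -> Optional[float]:
    """Monetary value of unpaid/leisure time: hourly rate × minutes / 60."""
    if duration_min is None:
        return None
    if duration_min < 0:
        raise ValueError("duration must be non-negative")
    return params.time_value_per_hour * duration_min / 60.0


def production_loss_per_absence(params: CostParameters) -> float:
    """Value of one lost workday: gross hourly wage × working hours per day."""
    return params.gross_hourly_wage * params.working_hours_per_day


def arm_production_loss(
    n_absent: int, n_employed: int, params: CostParameters
) -> tuple[float, float]:
    """Total and per-employed-patient production loss for one arm.

    Each absent patient is valued at one full average workday; the mean is
    taken over all employed patients (absent or not).
    """
    if not 0 <= n_absent <= n_employed:
        raise ValueError("need 0 <= n_absent <= n_employed")
    if n_employed == 0:
        raise ValueError("mean production loss undefined with no employed patients")
    total = n_absent * production_loss_per_absence(params)
    return total, total / n_employed


def production_loss_sd(n_absent: int, n_employed: int, params: CostParameters) -> float:
    """Sample SD of per-patient production loss across employed patients.

    Employed patients incur either one full workday's loss or nothing, so the
    SD has the closed form of a scaled binary sample.
    """
    if n_employed < 2:
        return 0.0
    loss = production_loss_per_absence(params)
    p = n_absent / n_employed
    return loss * math.sqrt(n_absent * (1.0 - p) / (n_employed - 1))


@dataclass(frozen=True)
class PatientCosts:
    """Cost components for a single patient; ``None`` where an input is missing."""

    travel: Optional[CostWithCounterfactual]
    travel_time: Optional[CostWithCounterfactual]
    waiting_time_cost: Optional[float]
    total_time_cost: Optional[float]
    production_loss: Optional[float]  # None when employment status is missing

    def total(self, basis: Literal["employed", "unemployed"]) -> Optional[float]:
        if self.travel is None or self.total_time_cost is None:
            return None
        base = self.travel.actual + self.total_time_cost
        if basis == "unemployed":
            return base
        if self.production_loss is None:
            return None
        return base + self.production_loss


def patient_costs(record: PatientRecord, params: CostParameters) -> PatientCosts:
    """Per-patient cost components (travel time valued round trip)."""
    tc = travel_cost(record.one_way_distance_km, params, record.arm)
    if record.travel_time_min is None:
        tt = None
    else:
        round_trip_cost = time_cost(2.0 * record.travel_time_min, params)
        if record.arm is Arm.TELEMEDICINE:
            tt = CostWithCounterfactual(actual=0.0, counterfactual=round_trip_cost)
        else:
            tt = CostWithCounterfactual(actual=round_trip_cost, counterfactual=round_trip_cost)
    if record.employed is None:
        loss = None
    elif record.employed and record.absent_from_work:
        loss = production_loss_per_absence(params)
    else:
        loss = 0.0
    return PatientCosts(
        travel=tc,
        travel_time=tt,
        waiting_time_cost=time_cost(record.waiting_time_min, params),
        total_time_cost=time_cost(record.total_time_min, params),
        production_loss=loss,
    )


@dataclass(frozen=True)
class ComponentSummary:
    mean: float
    sd: float


@dataclass(frozen=True)
class ArmCostSummary:
    """Arm-level cost components (euros), full precision.

    Counterfactual travel and travel-time costs are informative only — they
    describe the trip the telemedicine arm avoided (for the control arm they
    equal the actual costs).
    """

    arm: Arm
    params: CostParameters
    travel: ComponentSummary
    travel_counterfactual: ComponentSummary
    travel_time: ComponentSummary
    travel_time_counterfactual: ComponentSummary
    waiting_time: ComponentSummary
    total_time: ComponentSummary
    n_employed: int
    n_absent: int
    production_loss_total: float
    production_loss_mean_per_employed: float
    production_loss_sd_per_employed: float

    def total_per_patient(
        self, basis: Literal["employed", "unemployed"], *, rounded: bool = False
    ) -> float:
        """Mean total cost per patient on the given employment basis.

        ``rounded=True`` sums the cent-rounded component means, the convention
        of published cost tables; the default keeps full precision.
        """
        parts = [self.travel.mean, self.total_time.mean]
        if basis == "employed":
            parts.append(self.production_loss_mean_per_employed)
        elif basis != "unemployed":
            raise ValueError(f"unknown employment basis {basis!r}")
        if rounded:
            parts = [round(p, 2) for p in parts]
        return sum(parts)


def _scale(stats, factor: float) -> ComponentSummary:
    return ComponentSummary(mean=stats.mean * factor, sd=stats.sd * abs(factor))


def summarize_aggregate(agg: ArmAggregate, params: CostParameters) -> ArmCostSummary:
    """Cost summary from arm-level statistics, by linear scaling.

    Every component cost is a fixed multiple of its input variable, so means
    and SDs carry over by the same factor (SD scale equivariance).
    """
    km_factor = params.cost_per_km * 2.0
    per_min = params.time_value_per_hour / 60.0
    travel_cf = _scale(agg.one_way_distance, km_factor)
    travel_time_cf = _scale(agg.travel_time, 2.0 * per_min)
    zero = ComponentSummary(mean=0.0, sd=0.0)
    is_tele = agg.arm is Arm.TELEMEDICINE
    total, mean_pl = arm_production_loss(agg.n_absent, agg.n_employed, params)
    return ArmCostSummary(
        arm=agg.arm,
        params=params,
        travel=zero if is_tele else travel_cf,
        travel_counterfactual=travel_cf,
        travel_time=zero if is_tele else travel_time_cf,
        travel_time_counterfactual=travel_time_cf,
        waiting_time=_scale(agg.waiting_time, per_min),
        total_time=_scale(agg.total_time, per_min),
        n_employed=agg.n_employed,
        n_absent=agg.n_absent,
        production_loss_total=total,
        production_loss_mean_per_employed=mean_pl,
        production_loss_sd_per_employed=production_loss_sd(
            agg.n_absent, agg.n_employed, params
        ),
    )


def summarize_records(
    records: Iterable[PatientRecord], arm: Arm, params: CostParameters
) -> ArmCostSummary:
    """Cost summary from patient-level records (per-variable missing exclusion)."""
    from .cohort import aggregate_arm  # cycle-free: cohort does not import costs

    return summarize_aggregate(aggregate_arm(records, arm), params)


def total_cost_per_patient(
    summary: ArmCostSummary,
    basis: Literal["employed", "unemployed"],
    *,
    rounded: bool = False,
) -> float:
    """Convenience wrapper around :meth:`ArmCostSummary.total_per_patient`."""
    return summary.total_per_patient(basis, rounded=rounded)


@dataclass(frozen=True)
class CostDifference:
    """Control-minus-telemedicine savings per video consultation (euros)."""

    travel: float
    travel_time: float
    waiting_time: float
    total_time: float
    production_loss_total: float
    production_loss_mean_per_employed: float
    total_employed: float
    total_unemployed: float


def cost_difference(
    tele: ArmCostSummary, control: ArmCostSummary, *, rounded: bool = False
) -> CostDifference:
    """Per-component and total savings of telemedicine over in-clinic care.

    Both summaries must have been computed under identical cost parameters.
    ``rounded`` applies the cent-rounding reporting convention to the totals.
    """
    if tele.params != control.params:
        raise ValueError("cost summaries were computed under different parameters")

    def diff(a: ComponentSummary, b: ComponentSummary) -> float:
        return b.mean - a.mean

    return CostDifference(
        travel=diff(tele.travel, control.travel),
        travel_time=diff(tele.travel_time, control.travel_time),
        waiting_time=diff(tele.waiting_time, control.waiting_time),
        total_time=diff(tele.total_time, control.total_time),
        production_loss_total=control.production_loss_total - tele.production_loss_total,
        production_loss_mean_per_employed=(
            control.production_loss_mean_per_employed
            - tele.production_loss_mean_per_employed
        ),
        total_employed=(
            control.total_per_patient("employed", rounded=rounded)
            - tele.total_per_patient("employed", rounded=rounded)
        ),
        total_unemployed=(
            control.total_per_patient("unemployed", rounded=rounded)
            - tele.total_per_patient("unemployed", rounded=rounded)
        ),
    )
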