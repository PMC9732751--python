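"""Pipeline driver: base-case analysis and deterministic sensitivity scenarios.

The base case runs the two-step societal analysis — cost model then
environmental model — on either a patient-level cohort or a pair of
arm-level aggregates, producing the four report tables (demographics, cost
input variables, cost summary with differences, emission savings) plus the
annual extrapolation.

Sensitivity scenarios substitute alternative fixed parameter values
(full-time 8.2 h or part-time 3.9 h workdays, the equal-generational-welfare
carbon valuation, a doubled weekly patient volume) and re-run only the
affected stage; the base case is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .cohort import aggregate_arm, pooled_mean_distance
from .costs import ArmCostSummary, CostDifference, cost_difference, summarize_aggregate
from .emissions import (
    CARBON_PRICE_PRESETS,
    EmissionModel,
    EmissionsResult,
    ExtrapolationScenario,
    annual_extrapolation,
    avoided_pkm,
    emissions_saved,
)
from .stats import TestResult, fisher_exact, fisher_exact_2xk, mann_whitney
from .types import (
    AGGREGATE_FIELD_FOR,
    Arm,
    ArmAggregate,
    CONTINUOUS_VARIABLES,
    CostParameters,
    PatientRecord,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "AnalysisReport",
    "run_base_case",
    "run_scenarios",
    "standard_scenarios",
]


def _valid_keys(model_cls) -> set[str]:
    return set(model_cls.model_fields)


class Scenario(BaseModel):
    """One named set of parameter overrides for a sensitivity run."""

    model_config = ConfigDict(frozen=True)

    name: str
    cost_overrides: dict = Field(default_factory=dict)
    emission_overrides: dict = Field(default_factory=dict)
    extrapolation_overrides: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _known_keys_only(self) -> "Scenario":
        for overrides, model_cls, label in (
            (self.cost_overrides, CostParameters, "cost"),
            (self.emission_overrides, EmissionModel, "emission"),
            (self.extrapolation_overrides, ExtrapolationScenario, "extrapolation"),
        ):
            unknown = set(overrides) - _valid_keys(model_cls)
            if unknown:
                raise ValueError(
                    f"scenario {self.name!r}: unknown {label} override keys "
                    f"{sorted(unknown)}; valid keys: {sorted(_valid_keys(model_cls))}"
                )
        return self


def standard_scenarios() -> list[Scenario]:
    """The deterministic sensitivity set of the base analysis."""
    return [
        Scenario(name="full_time", cost_overrides={"working_hours_per_day": 8.2}),
        Scenario(name="part_time", cost_overrides={"working_hours_per_day": 3.9}),
        Scenario(
            name="equal_welfare_carbon",
            emission_overrides={
                "carbon_price_eur_per_tonne": 680.0,
                "env_cost_per_pkm": CARBON_PRICE_PRESETS[680.0],
            },
        ),
        Scenario(
            name="sixteen_per_week", extrapolation_overrides={"patients_per_week": 16}
        ),
    ]


@dataclass(frozen=True)
class AnalysisReport:
    """Complete base-case output: aggregates, cost tables, emission tables."""

    telemedicine: ArmAggregate
    control: ArmAggregate
    params: CostParameters
    emission_model: EmissionModel
    extrapolation: ExtrapolationScenario
    cost_summary_tele: ArmCostSummary
    cost_summary_control: ArmCostSummary
    difference: CostDifference  # full precision
    difference_rounded: CostDifference  # cent-rounded reporting convention
    emissions_per_patient: EmissionsResult
    emissions_cohort_total: EmissionsResult
    annual: EmissionsResult
    variable_tests: dict[str, TestResult] = field(default_factory=dict)
    demographic_tests: dict[str, TestResult] = field(default_factory=dict)
    #: {characteristic: {level: (telemedicine count, control count)}}
    demographics: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def savings_employed(self) -> float:
        """Headline saving per video consultation, employed patient (euros,
        cent-rounded reporting convention)."""
        return self.difference_rounded.total_employed


@dataclass(frozen=True)
class ScenarioResult:
    """Output of one sensitivity scenario (only affected stages recomputed)."""

    name: str
    scenario: Scenario
    params: CostParameters
    emission_model: EmissionModel
    extrapolation: ExtrapolationScenario
    cost_summary_tele: Optional[ArmCostSummary] = None
    cost_summary_control: Optional[ArmCostSummary] = None
    difference_rounded: Optional[CostDifference] = None
    emissions_per_patient: Optional[EmissionsResult] = None
    emissions_cohort_total: Optional[EmissionsResult] = None
    annual: Optional[EmissionsResult] = None

    def total_employed(self, arm: Arm) -> float:
        summary = (
            self.cost_summary_tele if Arm(arm) is Arm.TELEMEDICINE else self.cost_summary_control
        )
        if summary is None:
            raise ValueError(f"scenario {self.name!r} did not recompute the cost stage")
        return summary.total_per_patient("employed", rounded=True)


def _record_tests(records: Sequence[PatientRecord]) -> tuple[dict, dict]:
    tele = [r for r in records if r.arm is Arm.TELEMEDICINE]
    control = [r for r in records if r.arm is Arm.CONTROL]
    variable_tests = {}
    for var in CONTINUOUS_VARIABLES:
        x = [getattr(r, var) for r in tele if getattr(r, var) is not None]
        y = [getattr(r, var) for r in control if getattr(r, var) is not None]
        if x and y:
            variable_tests[AGGREGATE_FIELD_FOR[var]] = mann_whitney(x, y)

    def count(arm_records, pred):
        return sum(1 for r in arm_records if pred(r))

    demo: dict[str, TestResult] = {}
    demo["indication"] = fisher_exact(
        [
            [count(tele, lambda r: r.indication.value == "knee"),
             count(tele, lambda r: r.indication.value != "knee")],
            [count(control, lambda r: r.indication.value == "knee"),
             count(control, lambda r: r.indication.value != "knee")],
        ]
    )
    demo["sex"] = fisher_exact(
        [
            [count(tele, lambda r: r.sex.value == "female"),
             count(tele, lambda r: r.sex.value != "female")],
            [count(control, lambda r: r.sex.value == "female"),
             count(control, lambda r: r.sex.value != "female")],
        ]
    )
    demo["age_band"] = fisher_exact_2xk(
        [
            [count(tele, lambda r: r.age_band.value == b) for b in ("18-40", "41-60", ">60")],
            [count(control, lambda r: r.age_band.value == b) for b in ("18-40", "41-60", ">60")],
        ]
    )
    demo["employed"] = fisher_exact(
        [
            [count(tele, lambda r: r.employed is True),
             count(tele, lambda r: r.employed is False)],
            [count(control, lambda r: r.employed is True),
             count(control, lambda r: r.employed is False)],
        ]
    )
    demo["absent_from_work"] = fisher_exact(
        [
            [count(tele, lambda r: r.employed is True and r.absent_from_work is True),
             count(tele, lambda r: r.employed is True and not r.absent_from_work)],
            [count(control, lambda r: r.employed is True and r.absent_from_work is True),
             count(control, lambda r: r.employed is True and not r.absent_from_work)],
        ]
    )
    counts = {
        "indication": {
            level: (
                count(tele, lambda r: r.indication.value == level),
                count(control, lambda r: r.indication.value == level),
            )
            for level in ("knee", "shoulder")
        },
        "age_band": {
            level: (
                count(tele, lambda r: r.age_band.value == level),
                count(control, lambda r: r.age_band.value == level),
            )
            for level in ("18-40", "41-60", ">60")
        },
        "sex": {
            level: (
                count(tele, lambda r: r.sex.value == level),
                count(control, lambda r: r.sex.value == level),
            )
            for level in ("female", "male")
        },
        "employed": {
            "yes": (
                count(tele, lambda r: r.employed is True),
                count(control, lambda r: r.employed is True),
            ),
            "no": (
                count(tele, lambda r: r.employed is False),
                count(control, lambda r: r.employed is False),
            ),
        },
    }
    return variable_tests, demo, counts


def run_base_case(
    cohort: Union[Sequence[PatientRecord], tuple[ArmAggregate, ArmAggregate]],
    params: Optional[CostParameters] = None,
    emission_model: Optional[EmissionModel] = None,
    extrapolation: Optional[ExtrapolationScenario] = None,
    *,
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Run the full two-step societal analysis.

    ``cohort`` is either a list of patient records (both arms required;
    between-arm tests are then computed on the raw values) or a
    (telemedicine, control) pair of arm aggregates (linear models only).
    The annual extrapolation defaults to 8 patients/week × 48 weeks at the
    n-weighted mean of the two arms' distance means.
    """
    params = params or CostParameters()
    emission_model = emission_model or EmissionModel()

    variable_tests: dict = {}
    demographic_tests: dict = {}
    demographics: dict = {}
    if (
        isinstance(cohort, tuple)
        and len(cohort) == 2
        and all(isinstance(a, ArmAggregate) for a in cohort)
    ):
        tele_agg, control_agg = cohort
        if tele_agg.arm is not Arm.TELEMEDICINE or control_agg.arm is not Arm.CONTROL:
            raise ValueError("aggregate pair must be (telemedicine, control)")
    else:
        records = list(cohort)
        arms = {r.arm for r in records}
        if arms != {Arm.TELEMEDICINE, Arm.CONTROL}:
            raise ValueError("cohort must contain records from both arms")
        tele_agg = aggregate_arm(records, Arm.TELEMEDICINE)
        control_agg = aggregate_arm(records, Arm.CONTROL)
        variable_tests, demographic_tests, demographics = _record_tests(records)

    if extrapolation is None:
        extrapolation = ExtrapolationScenario(
            mean_one_way_distance_km=pooled_mean_distance(tele_agg, control_agg)
        )

    summary_tele = summarize_aggregate(tele_agg, params)
    summary_control = summarize_aggregate(control_agg, params)

    per_patient_pkm = avoided_pkm(tele_agg.one_way_distance.mean)
    per_patient = emissions_saved(per_patient_pkm, emission_model, basis="per_patient")
    cohort_total = per_patient.scaled(tele_agg.n_records, basis="cohort_total")

    return AnalysisReport(
        telemedicine=tele_agg,
        control=control_agg,
        params=params,
        emission_model=emission_model,
        extrapolation=extrapolation,
        cost_summary_tele=summary_tele,
        cost_summary_control=summary_control,
        difference=cost_difference(summary_tele, summary_control),
        difference_rounded=cost_difference(summary_tele, summary_control, rounded=True),
        emissions_per_patient=per_patient,
        emissions_cohort_total=cohort_total,
        annual=annual_extrapolation(extrapolation, emission_model),
        variable_tests=variable_tests,
        demographic_tests=demographic_tests,
        demographics=demographics,
        metadata={
            "version": __version__,
            "seed": seed,
            "params": params.model_dump(),
            "emission_model": emission_model.model_dump(),
            "extrapolation": extrapolation.model_dump(),
        },
    )


def run_scenarios(
    report: AnalysisReport, scenarios: Iterable[Scenario]
) -> list[ScenarioResult]:
    """Re-run each scenario's affected stage with overridden parameters.

    A cost-parameter scenario leaves the emission tables untouched and vice
    versa; the base-case report is never modified.
    """
    results: list[ScenarioResult] = []
    for scenario in scenarios:
        params = report.params
        emodel = report.emission_model
        extrap = report.extrapolation
        kwargs: dict = {}

        if scenario.cost_overrides:
            params = CostParameters(
                **{**report.params.model_dump(), **scenario.cost_overrides}
            )
            tele = summarize_aggregate(report.telemedicine, params)
            control = summarize_aggregate(report.control, params)
            kwargs.update(
                cost_summary_tele=tele,
                cost_summary_control=control,
                difference_rounded=cost_difference(tele, control, rounded=True),
            )
        if scenario.emission_overrides:
            emodel = EmissionModel(
                **{**report.emission_model.model_dump(), **scenario.emission_overrides}
            )
        if scenario.extrapolation_overrides:
            extrap = ExtrapolationScenario(
                **{**report.extrapolation.model_dump(), **scenario.extrapolation_overrides}
            )
        if scenario.emission_overrides or scenario.extrapolation_overrides:
            per_patient = emissions_saved(
                report.emissions_per_patient.pkm, emodel, basis="per_patient"
            )
            kwargs.update(
                emissions_per_patient=per_patient,
                emissions_cohort_total=per_patient.scaled(
                    report.telemedicine.n_records, basis="cohort_total"
                ),
                annual=annual_extrapolation(extrap, emodel),
            )

        results.append(
            ScenarioResult(
                name=scenario.name,
                scenario=scenario,
                params=params,
                emission_model=emodel,
                extrapolation=extrap,
                **kwargs,
            )
        )
    return results
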