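"""Report rendering: the four analysis tables plus scenario and metadata files.

Two layers are written per run: human-facing tables at the reporting
precision of clinical cost studies (euros to cents, emission masses to three
decimals — four for the sub-gram per-patient particulate figure) and a
machine-readable full-precision JSON.  Rendering is deterministic: the same
report always produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd

from .costs import ArmCostSummary
from .emissions import POLLUTANTS, EmissionsResult
from .scenarios import AnalysisReport, ScenarioResult
from .stats import format_p
from .types import AGGREGATE_FIELD_FOR

_POLLUTANT_LABELS = {
    "greenhouse_gases": "Greenhouse gases (kg)",
    "carbon_monoxide": "Carbon monoxide (kg)",
    "volatile_hydrocarbons": "Volatile hydrocarbons (kg)",
    "nitrogen_oxides": "Nitrogen oxides (kg)",
    "particulates": "Particulates (kg)",
}

_VARIABLE_LABELS = {
    "treatment_duration": "Treatment duration (minutes)",
    "one_way_distance": "Travel distance (kilometers)",
    "travel_time": "Actual and potential travel time (minutes)",
    "waiting_time": "Waiting time (minutes)",
    "total_time": "Total time spent on appointment (minutes)",
}


def _kg(mass: float, *, fine: bool = False) -> str:
    return f"{mass:.4f}" if fine else f"{mass:.3f}"


def _eur(x: float) -> str:
    return f"{x:.2f}"


def _mean_sd(mean: float, sd: float) -> str:
    return f"{_eur(mean)} ({_eur(sd)})"


def demographics_table(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for characteristic, levels in report.demographics.items():
        test = report.demographic_tests.get(characteristic)
        p = format_p(test.p_value) if test else ""
        for i, (level, (n_tele, n_control)) in enumerate(levels.items()):
            rows.append(
                {
                    "characteristic": characteristic,
                    "level": level,
                    "telemedicine_n": n_tele,
                    "control_n": n_control,
                    "p_value": p if i == 0 else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["characteristic", "level", "telemedicine_n", "control_n", "p_value"],
    )


def cost_inputs_table(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for key, label in _VARIABLE_LABELS.items():
        tele = getattr(report.telemedicine, key)
        control = getattr(report.control, key)
        test = report.variable_tests.get(key)
        rows.append(
            {
                "variable": label,
                "telemedicine_n": tele.n,
                "telemedicine_mean_sd": _mean_sd(tele.mean, tele.sd),
                "telemedicine_median_iqr": f"{tele.median:.2f} ({tele.q1:g}-{tele.q3:g})",
                "control_n": control.n,
                "control_mean_sd": _mean_sd(control.mean, control.sd),
                "control_median_iqr": f"{control.median:.2f} ({control.q1:g}-{control.q3:g})",
                "p_value": format_p(test.p_value) if test else "",
            }
        )
    return pd.DataFrame(rows)


def costs_table(report: AnalysisReport) -> pd.DataFrame:
    tele, control = report.cost_summary_tele, report.cost_summary_control
    diff = report.difference_rounded
    usd = report.params.eur_to_usd

    def component_row(label: str, t, c, d: float) -> dict:
        return {
            "component": label,
            "telemedicine": _mean_sd(t.mean, t.sd),
            "control": _mean_sd(c.mean, c.sd),
            "difference_eur": _eur(d),
            "difference_usd": _eur(d * usd),
        }

    rows = [
        component_row("Travel costs (EUR), mean (SD)", tele.travel, control.travel, diff.travel),
        component_row(
            "Travel time costs (EUR), mean (SD)",
            tele.travel_time,
            control.travel_time,
            diff.travel_time,
        ),
        component_row(
            "Waiting time costs (EUR), mean (SD)",
            tele.waiting_time,
            control.waiting_time,
            diff.waiting_time,
        ),
        component_row(
            "Total time costs (EUR), mean (SD)",
            tele.total_time,
            control.total_time,
            diff.total_time,
        ),
        {
            "component": "Production loss (EUR)",
            "telemedicine": _eur(tele.production_loss_total),
            "control": _eur(control.production_loss_total),
            "difference_eur": _eur(diff.production_loss_total),
            "difference_usd": _eur(diff.production_loss_total * usd),
        },
        {
            "component": "Counterfactual travel costs (EUR), mean",
            "telemedicine": _eur(tele.travel_counterfactual.mean),
            "control": _eur(control.travel_counterfactual.mean),
            "difference_eur": "",
            "difference_usd": "",
        },
        {
            "component": "Total costs, employed patient (EUR)",
            "telemedicine": _eur(tele.total_per_patient("employed", rounded=True)),
            "control": _eur(control.total_per_patient("employed", rounded=True)),
            "difference_eur": _eur(diff.total_employed),
            "difference_usd": _eur(diff.total_employed * usd),
        },
        {
            "component": "Total costs, unemployed patient (EUR)",
            "telemedicine": _eur(tele.total_per_patient("unemployed", rounded=True)),
            "control": _eur(control.total_per_patient("unemployed", rounded=True)),
            "difference_eur": _eur(diff.total_unemployed),
            "difference_usd": _eur(diff.total_unemployed * usd),
        },
    ]
    return pd.DataFrame(rows)


def emissions_table(report: AnalysisReport) -> pd.DataFrame:
    per, total = report.emissions_per_patient, report.emissions_cohort_total
    rows = [
        {
            "quantity": _POLLUTANT_LABELS[p],
            "per_patient": _kg(per.masses_kg[p], fine=(p == "particulates")),
            "total": _kg(total.masses_kg[p]),
        }
        for p in POLLUTANTS
    ]
    rows.append(
        {
            "quantity": "Environmental costs (EUR)",
            "per_patient": _eur(per.env_cost_eur),
            "total": _eur(total.env_cost_eur),
        }
    )
    return pd.DataFrame(rows)


def annual_table(report: AnalysisReport, annual: Optional[EmissionsResult] = None) -> pd.DataFrame:
    annual = annual or report.annual
    rows = [
        {"quantity": _POLLUTANT_LABELS[p], "annual_saving": f"{annual.masses_kg[p]:.2f}"}
        for p in POLLUTANTS
    ]
    rows.append(
        {"quantity": "Environmental costs (EUR)", "annual_saving": _eur(annual.env_cost_eur)}
    )
    rows.append({"quantity": "Passenger-kilometers avoided", "annual_saving": f"{annual.pkm:.2f}"})
    return pd.DataFrame(rows)


def scenarios_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row: dict = {"scenario": res.name}
        if res.cost_summary_tele is not None:
            row["total_employed_telemedicine"] = _eur(res.total_employed("telemedicine"))
            row["total_employed_control"] = _eur(res.total_employed("control"))
            row["saving_employed"] = _eur(res.difference_rounded.total_employed)
            row["production_loss_total_telemedicine"] = _eur(
                res.cost_summary_tele.production_loss_total
            )
            row["production_loss_total_control"] = _eur(
                res.cost_summary_control.production_loss_total
            )
        if res.emissions_per_patient is not None:
            row["env_cost_per_patient"] = _eur(res.emissions_per_patient.env_cost_eur)
            row["env_cost_cohort_total"] = _eur(res.emissions_cohort_total.env_cost_eur)
        if res.annual is not None:
            row["annual_ghg_kg"] = f"{res.annual.masses_kg['greenhouse_gases']:.2f}"
            row["annual_env_cost"] = _eur(res.annual.env_cost_eur)
        rows.append(row)
    columns = [
        "scenario",
        "total_employed_telemedicine",
        "total_employed_control",
        "saving_employed",
        "production_loss_total_telemedicine",
        "production_loss_total_control",
        "env_cost_per_patient",
        "env_cost_cohort_total",
        "annual_ghg_kg",
        "annual_env_cost",
    ]
    return pd.DataFrame(rows).reindex(columns=columns).fillna("")


def _full_precision_payload(
    report: AnalysisReport, scenario_results: Sequence[ScenarioResult]
) -> dict:
    def summary(s: ArmCostSummary) -> dict:
        return {
            "travel": vars(s.travel),
            "travel_counterfactual": vars(s.travel_counterfactual),
            "travel_time": vars(s.travel_time),
            "travel_time_counterfactual": vars(s.travel_time_counterfactual),
            "waiting_time": vars(s.waiting_time),
            "total_time": vars(s.total_time),
            "production_loss_total": s.production_loss_total,
            "production_loss_mean_per_employed": s.production_loss_mean_per_employed,
            "production_loss_sd_per_employed": s.production_loss_sd_per_employed,
            "total_employed": s.total_per_patient("employed"),
            "total_unemployed": s.total_per_patient("unemployed"),
        }

    def emissions(e: EmissionsResult) -> dict:
        return {
            "pkm": e.pkm,
            "masses_kg": e.masses_kg,
            "env_cost_eur": e.env_cost_eur,
            "basis": e.basis,
        }

    return {
        "metadata": report.metadata,
        "costs": {
            "telemedicine": summary(report.cost_summary_tele),
            "control": summary(report.cost_summary_control),
            "difference": vars(report.difference),
            "difference_rounded": vars(report.difference_rounded),
        },
        "emissions": {
            "per_patient": emissions(report.emissions_per_patient),
            "cohort_total": emissions(report.emissions_cohort_total),
            "annual": emissions(report.annual),
        },
        "tests": {
            name: {"p_value": t.p_value, "statistic": t.statistic, "method": t.method}
            for name, t in {**report.variable_tests, **report.demographic_tests}.items()
        },
        "scenarios": {
            res.name: {
                "costs": (
                    {
                        "telemedicine": summary(res.cost_summary_tele),
                        "control": summary(res.cost_summary_control),
                    }
                    if res.cost_summary_tele is not None
                    else None
                ),
                "emissions": (
                    {
                        "per_patient": emissions(res.emissions_per_patient),
                        "cohort_total": emissions(res.emissions_cohort_total),
                        "annual": emissions(res.annual),
                    }
                    if res.emissions_per_patient is not None or res.annual is not None
                    else None
                ),
            }
            for res in scenario_results
        },
    }


def _write_markdown(frame: pd.DataFrame, path: Path) -> None:
    cols = [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def render_report(
    report: AnalysisReport,
    out_dir: Union[str, Path],
    *,
    format: Literal["csv", "markdown"] = "csv",
    scenario_results: Iterable[ScenarioResult] = (),
) -> list[Path]:
    """Write all report tables plus metadata to ``out_dir``; returns the paths.

    Tables: demographics (when patient-level data were analysed), cost input
    variables, cost summary, emission savings, annual extrapolation, and one
    scenario table when sensitivity results are supplied.  A full-precision
    ``report.json`` is always written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario_results = list(scenario_results)

    tables: dict[str, pd.DataFrame] = {}
    if report.demographics:
        tables["demographics"] = demographics_table(report)
    tables["cost_inputs"] = cost_inputs_table(report)
    tables["costs"] = costs_table(report)
    tables["emissions"] = emissions_table(report)
    tables["annual"] = annual_table(report)
    if scenario_results:
        tables["scenarios"] = scenarios_table(scenario_results)

    written: list[Path] = []
    for name, frame in tables.items():
        if format == "csv":
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        else:
            path = out / f"{name}.md"
            _write_markdown(frame, path)
        written.append(path)

    json_path = out / "report.json"
    json_path.write_text(
        json.dumps(
            _full_precision_payload(report, scenario_results), indent=2, sort_keys=True
        )
        + "\n",
        encoding="utf-8",
    )
    written.append(json_path)
    return written
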