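"""End-to-end pipeline: base case, sensitivity scenarios, report rendering."""

import hashlib
import json

import pytest
from pydantic import ValidationError

from telecost import (
    Arm,
    Scenario,
    default_config,
    generate_cohort,
    reference_aggregates,
    render_report,
    run_base_case,
    run_scenarios,
    standard_scenarios,
)
from telecost.io import load_settings


@pytest.fixture(scope="module")
def base_report():
    return run_base_case(reference_aggregates())


@pytest.fixture(scope="module")
def scenario_results(base_report):
    return {r.name: r for r in run_scenarios(base_report, standard_scenarios())}


class TestBaseCase:
    def test_headline_saving(self, base_report):
        assert base_report.savings_employed == pytest.approx(76.52, abs=0.005)

    def test_per_patient_ghg_saving(self, base_report):
        assert base_report.emissions_per_patient.masses_kg[
            "greenhouse_gases"
        ] == pytest.approx(11.248, abs=0.0005)

    def test_record_level_cohort_runs_with_tests(self, small_cohort):
        report = run_base_case(small_cohort, seed=7)
        assert set(report.variable_tests) == {
            "treatment_duration",
            "one_way_distance",
            "travel_time",
            "waiting_time",
            "total_time",
        }
        assert all(0 <= t.p_value <= 1 for t in report.variable_tests.values())
        assert set(report.demographics) == {"indication", "age_band", "sex", "employed"}

    def test_identical_arms_zero_differences(self):
        tele, control = reference_aggregates()
        mirrored = control.model_copy(update={"arm": Arm.TELEMEDICINE})
        report = run_base_case((mirrored, control))
        # same inputs on both sides: only the structural telemedicine zeroing
        # of travel costs remains
        assert report.difference.total_time == 0.0
        assert report.difference.production_loss_total == 0.0

    def test_single_arm_cohort_rejected(self, small_cohort):
        control_only = [r for r in small_cohort if r.arm is Arm.CONTROL]
        with pytest.raises(ValueError, match="both arms"):
            run_base_case(control_only)


class TestScenarios:
    def test_full_time_totals(self, scenario_results):
        res = scenario_results["full_time"]
        assert res.total_employed(Arm.CONTROL) == pytest.approx(98.40, abs=0.005)
        assert res.total_employed(Arm.TELEMEDICINE) == pytest.approx(17.94, abs=0.005)
        assert res.cost_summary_tele.production_loss_total == pytest.approx(241.74, abs=0.005)
        assert res.cost_summary_control.production_loss_total == pytest.approx(725.21, abs=0.005)

    def test_part_time_totals(self, scenario_results):
        res = scenario_results["part_time"]
        assert res.total_employed(Arm.TELEMEDICINE) == pytest.approx(11.60, abs=0.005)
        assert res.total_employed(Arm.CONTROL) == pytest.approx(78.38, abs=0.005)
        assert res.cost_summary_tele.production_loss_total == pytest.approx(114.97, abs=0.005)
        assert res.cost_summary_control.production_loss_total == pytest.approx(344.92, abs=0.005)

    def test_savings_range_across_employment_scenarios(self, base_report, scenario_results):
        savings = [
            base_report.savings_employed,
            scenario_results["full_time"].difference_rounded.total_employed,
            scenario_results["part_time"].difference_rounded.total_employed,
        ]
        assert min(savings) == pytest.approx(66.78, abs=0.005)
        assert max(savings) == pytest.approx(80.46, abs=0.005)

    def test_carbon_scenario_reproduces_high_valuation(self, scenario_results):
        res = scenario_results["equal_welfare_carbon"]
        assert res.emissions_per_patient.env_cost_eur == pytest.approx(9.53, abs=0.005)
        assert res.emissions_cohort_total.env_cost_eur == pytest.approx(247.91, abs=0.005)

    def test_sixteen_per_week_doubles_annual(self, base_report, scenario_results):
        res = scenario_results["sixteen_per_week"]
        for p, mass in base_report.annual.masses_kg.items():
            assert res.annual.masses_kg[p] == 2 * mass
        assert res.annual.env_cost_eur == 2 * base_report.annual.env_cost_eur

    def test_cost_scenario_leaves_emissions_untouched(self, scenario_results):
        res = scenario_results["full_time"]
        assert res.emissions_per_patient is None and res.annual is None

    def test_emission_scenario_leaves_costs_untouched(self, scenario_results):
        res = scenario_results["equal_welfare_carbon"]
        assert res.cost_summary_tele is None
        assert res.annual.masses_kg["greenhouse_gases"] == pytest.approx(
            scenario_results["sixteen_per_week"].annual.masses_kg["greenhouse_gases"] / 2
        )

    def test_employment_scenarios_change_only_production_cells(
        self, base_report, scenario_results
    ):
        res = scenario_results["full_time"]
        assert res.cost_summary_control.travel == base_report.cost_summary_control.travel
        assert (
            res.cost_summary_control.total_time
            == base_report.cost_summary_control.total_time
        )
        assert (
            res.cost_summary_control.production_loss_total
            != base_report.cost_summary_control.production_loss_total
        )

    def test_empty_scenario_list(self, base_report):
        assert run_scenarios(base_report, []) == []

    def test_unknown_override_key_lists_valid_keys(self):
        with pytest.raises(ValidationError, match="valid keys"):
            Scenario(name="bad", cost_overrides={"wage_per_minute": 1.0})

    def test_base_report_is_not_mutated(self, base_report):
        before = base_report.params.model_dump()
        run_scenarios(base_report, standard_scenarios())
        assert base_report.params.model_dump() == before


class TestRendering:
    def _checksums(self, paths):
        return {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in paths}

    def test_rendering_twice_is_byte_identical(self, base_report, tmp_path):
        results = run_scenarios(base_report, standard_scenarios())
        a = render_report(base_report, tmp_path / "a", scenario_results=results)
        b = render_report(base_report, tmp_path / "b", scenario_results=results)
        assert self._checksums(a) == self._checksums(b)

    def test_cost_table_contains_published_difference(self, base_report, tmp_path):
        render_report(base_report, tmp_path)
        text = (tmp_path / "costs.csv").read_text()
        assert "Travel costs" in text and "18.95" in text
        assert "76.52" in text

    def test_markdown_format(self, base_report, tmp_path):
        paths = render_report(base_report, tmp_path, format="markdown")
        emissions = (tmp_path / "emissions.md").read_text()
        assert emissions.startswith("|")
        assert "Greenhouse gases (kg)" in emissions
        assert any(p.suffix == ".md" for p in paths)

    def test_full_precision_json_round_trips(self, base_report, tmp_path):
        render_report(base_report, tmp_path)
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["costs"]["control"]["total_employed"] == pytest.approx(
            92.62, abs=0.005
        )
        assert payload["metadata"]["version"]

    def test_end_to_end_cohort_determinism(self, tmp_path):
        """Same cohort file + same config produce byte-identical reports."""
        from telecost.cohort import read_cohort, write_cohort

        cohort_path = tmp_path / "cohort.csv"
        write_cohort(generate_cohort(default_config(seed=13)), cohort_path)
        sums = []
        for sub in ("r1", "r2"):
            records = read_cohort(cohort_path)
            report = run_base_case(records, seed=13)
            paths = render_report(report, tmp_path / sub)
            sums.append(self._checksums(paths))
        assert sums[0] == sums[1]


class TestSettingsFile:
    def test_empty_config_runs_base_case(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        settings = load_settings(path)
        assert settings.params.cost_per_km == 0.30
        assert settings.emission_model.env_cost_per_pkm == 0.05045
        assert settings.scenarios == []

    def test_overrides_and_scenarios_parsed(self, tmp_path):
        path = tmp_path / "conf.yaml"
        path.write_text(
            "costs:\n  cost_per_km: 0.35\n"
            "scenarios:\n  - name: cheap_fuel\n    cost_overrides:\n      cost_per_km: 0.25\n"
        )
        settings = load_settings(path)
        assert settings.params.cost_per_km == 0.35
        assert settings.scenarios[0].name == "cheap_fuel"

    def test_unknown_block_rejected(self, tmp_path):
        path = tmp_path / "conf.yaml"
        path.write_text("costz: {}\n")
        with pytest.raises(ValueError, match="unknown configuration blocks"):
            load_settings(path)
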