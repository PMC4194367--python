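"""Scenario runs, budget-impact comparison and one-way sensitivity."""

from __future__ import annotations

import numpy as np
import pytest

import renalbudget as rb
from renalbudget.budget import ScenarioResult, compare, one_way_sensitivity
from renalbudget.costs import COMPONENTS, CostLedger
from renalbudget.states import State


def _toy_result(sid: str, per_cycle_totals: list[float]) -> ScenarioResult:
    """A hand-built result whose treatment component carries all cost."""
    ledger = CostLedger(n_cycles=len(per_cycle_totals))
    for j, amount in enumerate(per_cycle_totals, start=1):
        ledger.add(j, "treatment", amount)
    ledger.patient_years = 1.0
    return ScenarioResult(
        scenario_id=sid,
        ledger=ledger,
        occupancy_history=np.zeros((len(per_cycle_totals), 1, 1, 1, 1)),
        entry_cycles=(0,),
        patient_years=1.0,
        entrant_patient_years=1.0,
        total_entrants=1.0,
        inputs_hash="toy",
        metadata={},
    )


class TestCompare:
    def test_two_cycle_arithmetic(self):
        """Reference £100+£100 vs scenario £90+£120: +£10 difference, +5%."""
        report = compare(_toy_result("ref", [100, 100]), _toy_result("scen", [90, 120]))
        assert report.total_difference == pytest.approx(10.0)
        assert report.total_relative == pytest.approx(0.05)

    def test_self_comparison_is_null(self, reference_result):
        report = compare(reference_result, reference_result)
        assert report.total_difference == 0.0
        assert all(v == 0.0 for v in report.difference.values())
        assert all(v == 0.0 for v in report.relative.values())

    def test_component_differences_sum_to_total(self, all_results):
        report = compare(all_results["reference"], all_results["s4"])
        assert sum(report.difference.values()) == pytest.approx(
            report.total_difference, rel=1e-9
        )

    def test_relative_recomputes_from_absolute(self, all_results):
        report = compare(all_results["reference"], all_results["s3"])
        for comp, rel in report.relative.items():
            ref = report.reference_components[comp]
            if ref != 0:
                assert rel == pytest.approx(report.difference[comp] / ref, abs=1e-12)
        assert report.total_relative == pytest.approx(
            report.total_difference / report.reference_total, abs=1e-12
        )

    def test_mismatched_horizons_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            compare(_toy_result("a", [1, 2]), _toy_result("b", [1, 2, 3]))

    def test_report_frame_has_total_row(self, all_results):
        frame = compare(all_results["reference"], all_results["s1"]).to_frame()
        assert frame.iloc[-1]["component"] == "total"
        assert frame.iloc[-1]["difference_gbp"] == pytest.approx(
            frame.iloc[:-1]["difference_gbp"].sum()
        )


class TestDeterminism:
    def test_identical_runs_bit_identical(self, inputs, curves):
        scen = inputs.scenarios["reference"]
        a = rb.run_scenario(scen, inputs, curves)
        b = rb.run_scenario(scen, inputs, curves)
        assert np.array_equal(a.ledger.per_cycle, b.ledger.per_cycle)
        assert np.array_equal(a.occupancy_history, b.occupancy_history)


class TestTariffStructuralIdentity:
    def test_s1_s2_trajectories_bit_identical(self, all_results):
        """s1 and s2 differ only in the high-dose home-HD tariff, which does
        not touch the dynamics."""
        assert np.array_equal(
            all_results["s1"].occupancy_history, all_results["s2"].occupancy_history
        )

    def test_tariff_linearity(self, all_results):
        """s2 − s1 total = (575 − 456) × 4 weeks × high-dose-home patient-cycles."""
        diff = all_results["s2"].ledger.total() - all_results["s1"].ledger.total()
        cycles = all_results["s1"].patient_cycles(State.HOME_HD_HIGH_DOSE)
        assert diff == pytest.approx((575 - 456) * 4 * cycles, rel=1e-9)

    def test_treatment_increasing_in_tariff(self, inputs, curves):
        base = rb.run_scenario(inputs.scenarios["s1"], inputs, curves)
        assert base.patient_cycles(State.HOME_HD_HIGH_DOSE) > 0
        bumped = rb.run_scenario(inputs.scenarios["s2"], inputs, curves)
        assert (
            bumped.ledger.component_totals()["treatment"]
            > base.ledger.component_totals()["treatment"]
        )


class TestSensitivity:
    def test_point_bound_reproduces_base_case(self, inputs, all_results):
        sweep = one_way_sensitivity("costs.home_hd_weekly", scenario_id="s1", inputs=inputs)
        base = compare(all_results["reference"], all_results["s1"])
        assert sweep["bounds"]["point"]["total_difference"] == pytest.approx(
            base.total_difference
        )

    def test_high_dose_tariff_sweep_monotone(self, inputs, curves, all_results):
        """The scenario-vs-reference cost difference is monotone increasing
        in the high-dose home-HD weekly tariff (the reference scenario has
        no high-dose home-HD occupancy, so only the scenario run moves)."""
        import dataclasses

        ref_total = all_results["reference"].ledger.total()
        diffs = []
        for tariff in (456.0, 500.0, 575.0):
            scen = dataclasses.replace(
                inputs.scenarios["s1"], home_hd_high_dose_weekly_tariff=tariff
            )
            diffs.append(rb.run_scenario(scen, inputs, curves).ledger.total() - ref_total)
        assert diffs[0] < diffs[1] < diffs[2]

    def test_hospitalisation_high_bound_raises_complications(self, inputs, all_results):
        sweep = one_way_sensitivity(
            "hospitalisation.year1.pd", scenario_id="s4", inputs=inputs
        )
        hi = sweep["bounds"]["high"]
        pt = sweep["bounds"]["point"]
        # more frequent PD hospitalisation raises complication spending in
        # every run that has PD patients
        assert hi["reference_total"] > pt["reference_total"]
        assert hi["scenario_total"] > pt["scenario_total"]

    def test_unknown_parameter_rejected(self, inputs):
        with pytest.raises(KeyError):
            one_way_sensitivity("costs.nonexistent", inputs=inputs)


class TestPerPatientYear:
    def test_both_denominators_reported(self, all_results):
        report = compare(all_results["reference"], all_results["s1"])
        assert set(report.per_patient_year) == {"years_lived", "entrants"}
        ref = all_results["reference"]
        assert report.per_patient_year["years_lived"]["reference"] == pytest.approx(
            ref.ledger.total() / ref.patient_years
        )

    def test_entrant_years_arithmetic(self, reference_result):
        # 22,993 + cumulative 5,395 per year from year 2: 22,993×5 + 5,395×(4+3+2+1)
        assert reference_result.entrant_patient_years == 22993 * 5 + 5395 * 10
        assert reference_result.total_entrants == 22993 + 4 * 5395
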