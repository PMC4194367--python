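"""Cost engine: per-cycle accrual arithmetic, event costs, ledger identities."""

from __future__ import annotations

import numpy as np
import pytest

import renalbudget as rb
from renalbudget.config import load_inputs
from renalbudget.costs import TariffSchedule, cycle_cost_matrix
from renalbudget.states import State, YearBand

from conftest import zeroed_costs_dict


@pytest.fixture(scope="module")
def tariffs(inputs):
    return TariffSchedule.from_inputs(inputs, inputs.scenarios["reference"])


@pytest.fixture(scope="module")
def tariffs_575(inputs):
    return TariffSchedule.from_inputs(inputs, inputs.scenarios["s2"])


class TestTreatment:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (State.ICHD_CONVENTIONAL, 147 * 3 * 4),      # £1,764
            (State.ICHD_HIGH_DOSE, 147 * 5 * 4),         # £2,940
            (State.HOME_HD_CONVENTIONAL, 456 * 4),       # £1,824
            (State.HOME_HD_HIGH_DOSE, 456 * 4),          # current tariff
            (State.PD, (0.5 * 52 + 0.5 * 46) * 28),      # £1,372
            (State.TRANSPLANT, 0.0),
            (State.DEAD, 0.0),
        ],
    )
    def test_per_cycle_amounts(self, tariffs, state, expected):
        assert rb.treatment_cost_per_cycle(state, tariffs) == pytest.approx(expected)

    def test_increased_home_hd_tariff(self, tariffs_575):
        assert rb.treatment_cost_per_cycle(State.HOME_HD_HIGH_DOSE, tariffs_575) == 2300


class TestEsa:
    def test_hd_dose(self, inputs):
        expected = 6.705 * 5.09 * 4
        for s in (State.ICHD_CONVENTIONAL, State.HOME_HD_HIGH_DOSE):
            assert rb.esa_cost_per_cycle(s, inputs) == pytest.approx(expected)
        assert round(expected, 2) == 136.51

    def test_pd_dose(self, inputs):
        got = rb.esa_cost_per_cycle(State.PD, inputs)
        assert got == pytest.approx(3.7 * 5.09 * 4)
        assert round(got, 2) == 75.33

    def test_zero_dose(self, inputs):
        zeroed = inputs.with_parameter("costs.esa_dose_pd_units_per_week", 0.0)
        assert rb.esa_cost_per_cycle(State.PD, zeroed) == 0.0


class TestMonitoring:
    def test_weighted_visit_cost(self, inputs):
        assert inputs.costs.monitoring_weighted == 190

    def test_prorated_per_cycle(self, inputs):
        got = rb.monitoring_cost_per_cycle(inputs)
        assert got == pytest.approx(2 * 190 / 13)
        assert round(got, 2) == 29.23


class TestHospitalisation:
    def test_followup_year_probability(self, inputs):
        """Year-2+ rate is 0.69 × year-1, rounded at printed precision."""
        pv = inputs.hospitalisation.year2_plus("ichd_conventional")
        assert pv.point == 4.86
        assert inputs.hospitalisation.year2_plus("home_hd_conventional").point == 3.69
        assert inputs.hospitalisation.year2_plus("hd_high_dose").point == 4.89
        # PD identical across year bands
        assert inputs.hospitalisation.year2_plus("pd").point == 6.69

    def test_expected_cost_year_one(self, inputs):
        got = rb.hospitalisation_cost_per_cycle(State.ICHD_CONVENTIONAL, YearBand.YEAR_1, inputs)
        assert got == pytest.approx(0.0705 * 1904)
        assert round(got, 2) == 134.23

    def test_pd_uses_pd_event_cost(self, inputs):
        got = rb.hospitalisation_cost_per_cycle(State.PD, YearBand.YEAR_2_PLUS, inputs)
        assert got == pytest.approx(0.0669 * 1596)

    def test_non_dialysis_states_cost_nothing(self, inputs):
        assert rb.hospitalisation_cost_per_cycle(State.POST_TRANSPLANT, YearBand.YEAR_1, inputs) == 0.0


class TestTransport:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (State.ICHD_CONVENTIONAL, 46 * 3 * 4),   # £552
            (State.ICHD_HIGH_DOSE, 46 * 5 * 4),      # £920
            (State.HOME_HD_CONVENTIONAL, 0.0),
            (State.PD, 0.0),
            (State.POST_TRANSPLANT, 0.0),
        ],
    )
    def test_in_centre_only(self, inputs, state, expected):
        assert rb.transport_cost_per_cycle(state, inputs) == expected


class TestAccessEvents:
    @pytest.mark.parametrize(
        "prev, new, expected",
        [
            (None, State.PD, 1233),                                    # model entry to PD
            (None, State.ICHD_CONVENTIONAL, 1287),                     # model entry to HD
            (State.ICHD_CONVENTIONAL, State.HOME_HD_CONVENTIONAL, 0),  # same access type
            (State.HOME_HD_CONVENTIONAL, State.HOME_HD_HIGH_DOSE, 0),
            (State.ICHD_CONVENTIONAL, State.PD, 1233),
            (State.PD, State.ICHD_CONVENTIONAL, 1287),
            (State.POST_TRANSPLANT, State.PD, 1233),                   # graft-failure return
            (State.POST_TRANSPLANT, State.HOME_HD_CONVENTIONAL, 1287),
            (State.PD, State.TRANSPLANT, 0),
        ],
    )
    def test_charging_rules(self, inputs, prev, new, expected):
        assert rb.access_event_cost(prev, new, inputs) == expected


class TestTransplantEvents:
    def test_procedure_and_medication(self, inputs):
        assert rb.transplant_event_costs(State.TRANSPLANT, inputs) == 18579
        med = rb.transplant_event_costs(State.POST_TRANSPLANT, inputs)
        assert med == pytest.approx(11137 / 13)
        assert round(med, 2) == 856.69
        assert rb.transplant_event_costs(State.PD, inputs) == 0.0


class TestLedgerIdentities:
    def test_components_partition_total(self, reference_result):
        ledger = reference_result.ledger
        assert sum(ledger.component_totals().values()) == pytest.approx(
            ledger.total(), rel=1e-12
        )
        assert sum(ledger.report_totals().values()) == pytest.approx(
            ledger.total(), rel=1e-12
        )

    def test_cumulative_is_prefix_sum(self, reference_result):
        ledger = reference_result.ledger
        cum = ledger.cumulative()
        assert np.allclose(cum[-1], ledger.per_cycle.sum(axis=0))
        assert np.all(np.diff(cum, axis=0) >= -1e-9)

    def test_zero_unit_costs_zero_ledger(self, inputs, curves):
        free = load_inputs(zeroed_costs_dict(inputs))
        result = rb.run_scenario(free.scenarios["reference"], free, curves)
        assert result.ledger.total() == 0.0

    def test_tidy_export_matches_totals(self, reference_result):
        frame = reference_result.ledger.to_frame("reference")
        assert set(frame.columns) == {"cycle", "component", "scenario", "gbp"}
        assert frame["gbp"].sum() == pytest.approx(reference_result.ledger.total())


def test_cost_matrix_consistent_with_scalar_ops(inputs):
    """The vectorised matrix the engines use agrees with the scalar operations."""
    scen = inputs.scenarios["s2"]
    mat = cycle_cost_matrix(inputs, scen)
    tariffs = TariffSchedule.from_inputs(inputs, scen)
    for s in (State.PD, State.ICHD_CONVENTIONAL, State.HOME_HD_HIGH_DOSE):
        for yb in YearBand:
            assert mat[s, yb, 1] == rb.treatment_cost_per_cycle(s, tariffs, 0.5)
            assert mat[s, yb, 2] == rb.esa_cost_per_cycle(s, inputs)
            assert mat[s, yb, 4] == rb.hospitalisation_cost_per_cycle(s, yb, inputs)
            assert mat[s, yb, 5] == rb.transport_cost_per_cycle(s, inputs)
    assert mat[State.TRANSPLANT, 0, 6] == 18579
    assert mat[State.POST_TRANSPLANT, 0, 7] == pytest.approx(11137 / 13)
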