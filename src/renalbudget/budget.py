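"""Scenario runs, budget-impact comparisons and one-way sensitivity sweeps.

The headline pipeline is fully deterministic: a cohort run over 65 cycles
(five 13-cycle model years) accrues costs by component; scenarios differ
only in their baseline modality distributions and the high-dose home-HD
weekly tariff.  Budget impact is the component-wise difference of a
scenario's cumulative costs against the reference scenario, in absolute
pounds and relative to the reference value, plus average per-patient/year
costs under two denominators (patient-years actually lived in the model,
and cumulative patients entered).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortState, advance, enter_incident, initialize_cohort
from .config import ModelInputs, ScenarioSpec, default_inputs
from .costs import (
    COMPONENTS,
    REPORT_COMPONENTS,
    CostLedger,
    access_event_cost,
    cycle_cost_matrix,
)
from .states import CYCLE_YEARS, MODALITY_ORDER, N_STATES, State
from .survival import SurvivalCurve, make_default_curves

__all__ = [
    "ScenarioResult",
    "BudgetImpactReport",
    "run_scenario",
    "compare",
    "one_way_sensitivity",
    "run_all_scenarios",
]


def _inputs_hash(inputs: ModelInputs) -> str:
    blob = json.dumps(inputs.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScenarioResult:
    """Deterministic outcome of one scenario run."""

    scenario_id: str
    ledger: CostLedger
    occupancy_history: np.ndarray  # (n_cycles, full occupancy grid) start-of-cycle
    entry_cycles: tuple[int, ...]
    patient_years: float
    entrant_patient_years: float
    total_entrants: float
    inputs_hash: str
    metadata: dict

    def state_occupancy(self) -> np.ndarray:
        """Start-of-cycle mass per state, shape (n_cycles, N_STATES)."""
        return self.occupancy_history.sum(axis=(2, 3, 4))

    def patient_cycles(self, state: State) -> float:
        """Total patient-cycles spent in ``state`` over the run."""
        return float(self.state_occupancy()[:, int(state)].sum())

    def occupancy_frame(self) -> pd.DataFrame:
        occ = self.state_occupancy()
        rows = []
        for j in range(occ.shape[0]):
            for s in State:
                rows.append({"cycle": j + 1, "state": s.name, "mass": occ[j, s]})
        return pd.DataFrame(rows)


def _baseline_access(cohort: CohortState, inputs: ModelInputs, newly_added: np.ndarray) -> float:
    """Access establishment cost for a vector of per-state entrant masses."""
    total = 0.0
    for s in MODALITY_ORDER:
        mass = newly_added[int(s)]
        if mass > 0:
            total += mass * access_event_cost(None, s, inputs)
    return total


def run_scenario(
    scenario: ScenarioSpec,
    inputs: ModelInputs | None = None,
    curves: dict[str, SurvivalCurve] | None = None,
) -> ScenarioResult:
    """Run the cohort and cost engines for one scenario over the horizon.

    The run is RNG-free; identical inputs give bit-identical ledgers.
    """
    inputs = inputs if inputs is not None else default_inputs()
    curves = curves if curves is not None else make_default_curves(inputs.survival)
    n_cycles = inputs.model.horizon_cycles
    cpy = inputs.model.cycles_per_year

    cohort = initialize_cohort(scenario, inputs)
    ledger = CostLedger(n_cycles=n_cycles)
    costs_mat = cycle_cost_matrix(inputs, scenario)  # (state, yearband, comp)

    history = np.zeros((n_cycles,) + cohort.occupancy.shape)

    if inputs.flags.charge_prevalent_baseline_access:
        ledger.add(
            1, "access", _baseline_access(cohort, inputs, cohort.state_totals())
        )

    for j in range(1, n_cycles + 1):
        model_year = (j - 1) // cpy + 1
        if (j - 1) % cpy == 0 and model_year in inputs.population.incident_entry_years:
            before = cohort.state_totals()
            cohort = enter_incident(cohort, model_year, scenario, inputs)
            added = cohort.state_totals() - before
            ledger.add(j, "access", _baseline_access(cohort, inputs, added))

        history[j - 1] = cohort.occupancy

        # state costs on start-of-cycle occupancy
        masses = cohort.masses_by_state_yearband(
            inputs.flags.prevalent_hospitalisation_year1
        )  # (state, yearband)
        per_component = np.einsum("sy,syc->c", masses, costs_mat)
        ledger.add_vector(j, per_component)
        alive = cohort.alive_mass()
        ledger.alive_mass_by_cycle[j - 1] = alive
        ledger.patient_years += alive * CYCLE_YEARS

        cohort, flows = advance(cohort, inputs, curves, scenario)
        ledger.add(j, "access", flows.hd_to_pd * inputs.costs.peritoneal_access.point)
        ledger.add(j, "access", flows.pd_to_hd * inputs.costs.vascular_access.point)
        ledger.add(j, "access", flows.graft_to_pd * inputs.costs.peritoneal_access.point)
        ledger.add(j, "access", flows.graft_to_hd * inputs.costs.vascular_access.point)

    # entrants-based denominator: cumulative patients entered, summed per year
    n_years = inputs.model.horizon_years
    entered = 0.0
    entrant_years = 0.0
    for y in range(1, n_years + 1):
        if y == 1:
            entered += inputs.population.prevalent
        if y in inputs.population.incident_entry_years:
            entered += inputs.population.incident_per_year
        entrant_years += entered

    return ScenarioResult(
        scenario_id=scenario.id,
        ledger=ledger,
        occupancy_history=history,
        entry_cycles=cohort.entry_cycles,
        patient_years=ledger.patient_years,
        entrant_patient_years=entrant_years,
        total_entrants=entered,
        inputs_hash=_inputs_hash(inputs),
        metadata={
            "scenario": scenario.to_dict(),
            "survival": {k: c.to_dict() for k, c in curves.items()},
            "survival_source": inputs.survival.source,
            "flags": {
                "charge_prevalent_baseline_access": inputs.flags.charge_prevalent_baseline_access,
                "monitor_post_transplant": inputs.flags.monitor_post_transplant,
                "prevalent_hospitalisation_year1": inputs.flags.prevalent_hospitalisation_year1,
                "apd_share": inputs.flags.apd_share,
                "per_patient_denominator": inputs.flags.per_patient_denominator,
            },
        },
    )


@dataclass
class BudgetImpactReport:
    """Component-wise cumulative budget impact of a scenario vs reference."""

    reference_id: str
    scenario_id: str
    reference_components: dict[str, float]
    scenario_components: dict[str, float]
    difference: dict[str, float]
    relative: dict[str, float]
    reference_total: float
    scenario_total: float
    total_difference: float
    total_relative: float
    per_patient_year: dict[str, dict[str, float]]  # denominator -> {reference, scenario, difference}
    metadata: dict

    def to_frame(self) -> pd.DataFrame:
        """Budget-table-style component matrix."""
        rows = []
        for comp in REPORT_COMPONENTS:
            rows.append(
                {
                    "component": comp,
                    "reference_gbp": self.reference_components[comp],
                    "scenario_gbp": self.scenario_components[comp],
                    "difference_gbp": self.difference[comp],
                    "relative": self.relative[comp],
                }
            )
        rows.append(
            {
                "component": "total",
                "reference_gbp": self.reference_total,
                "scenario_gbp": self.scenario_total,
                "difference_gbp": self.total_difference,
                "relative": self.total_relative,
            }
        )
        return pd.DataFrame(rows)


def compare(reference: ScenarioResult, scenario: ScenarioResult) -> BudgetImpactReport:
    """Component-wise budget impact of ``scenario`` against ``reference``."""
    if reference.ledger.n_cycles != scenario.ledger.n_cycles:
        raise ValueError(
            f"mismatched horizons: {reference.ledger.n_cycles} vs {scenario.ledger.n_cycles}"
        )
    if reference.inputs_hash != scenario.inputs_hash:
        raise ValueError("results were produced from different model inputs")

    ref_c = reference.ledger.report_totals()
    scen_c = scenario.ledger.report_totals()
    diff = {k: scen_c[k] - ref_c[k] for k in ref_c}
    rel = {k: (diff[k] / ref_c[k] if ref_c[k] != 0 else 0.0) for k in ref_c}
    ref_total = reference.ledger.total()
    scen_total = scenario.ledger.total()

    ppy = {}
    for denom_name, ref_d, scen_d in (
        ("years_lived", reference.patient_years, scenario.patient_years),
        ("entrants", reference.entrant_patient_years, scenario.entrant_patient_years),
    ):
        ref_ppy = ref_total / ref_d
        scen_ppy = scen_total / scen_d
        ppy[denom_name] = {
            "reference": ref_ppy,
            "scenario": scen_ppy,
            "difference": scen_ppy - ref_ppy,
            "relative": (scen_ppy - ref_ppy) / ref_ppy,
        }

    return BudgetImpactReport(
        reference_id=reference.scenario_id,
        scenario_id=scenario.scenario_id,
        reference_components=ref_c,
        scenario_components=scen_c,
        difference=diff,
        relative=rel,
        reference_total=ref_total,
        scenario_total=scen_total,
        total_difference=scen_total - ref_total,
        total_relative=(scen_total - ref_total) / ref_total,
        per_patient_year=ppy,
        metadata={
            "inputs_hash": reference.inputs_hash,
            "reference": reference.metadata,
            "scenario": scenario.metadata,
        },
    )


def run_all_scenarios(
    inputs: ModelInputs | None = None,
    curves: dict[str, SurvivalCurve] | None = None,
    scenario_ids: tuple[str, ...] | None = None,
) -> dict[str, ScenarioResult]:
    """Run the reference and every configured scenario once."""
    inputs = inputs if inputs is not None else default_inputs()
    curves = curves if curves is not None else make_default_curves(inputs.survival)
    ids = scenario_ids if scenario_ids is not None else tuple(inputs.scenarios)
    return {sid: run_scenario(inputs.scenarios[sid], inputs, curves) for sid in ids}


def one_way_sensitivity(
    param_id: str,
    scenario_id: str = "s2",
    reference_id: str = "reference",
    inputs: ModelInputs | None = None,
) -> dict:
    """Re-run a scenario pair with one parameter at its low and high bounds.

    All other parameters stay at their point values.  Returns the total
    budget difference (scenario − reference) at the low bound, point and
    high bound.
    """
    inputs = inputs if inputs is not None else default_inputs()
    pv = inputs.parameter(param_id)  # raises KeyError on unknown id

    out: dict[str, dict] = {"parameter": param_id, "bounds": {}}
    for which, value in (("low", pv.low), ("point", pv.point), ("high", pv.high)):
        mod = inputs if which == "point" else inputs.with_parameter(param_id, value)
        curves = make_default_curves(mod.survival)
        ref = run_scenario(mod.scenarios[reference_id], mod, curves)
        scen = run_scenario(mod.scenarios[scenario_id], mod, curves)
        report = compare(ref, scen)
        out["bounds"][which] = {
            "value": value,
            "reference_total": report.reference_total,
            "scenario_total": report.scenario_total,
            "total_difference": report.total_difference,
            "components_difference": dict(report.difference),
        }
    return out
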