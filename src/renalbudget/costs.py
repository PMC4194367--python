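"""Per-cycle cost accrual by component, plus event-triggered costs.

Components mirror the budget report rows: access establishment, dialysis
treatment (tariffs), erythropoiesis-stimulating agents (ESA), patient
monitoring, complications (all-cause hospitalisation), transportation, plus
transplant procedure and post-transplant medication, which are folded into
the treatment row for report-style summaries but kept separate internally.

Conventions: a cycle is 28 days = 4 weeks.  In-centre HD is charged per
session (sessions/week × 4 weeks); home HD is a fixed weekly tariff
(× 4 weeks) regardless of session count; PD is charged per day (× 28),
weighting the APD and CAPD daily tariffs by the configured APD share.
Transport applies to in-centre sessions only — home-based modalities incur
no clinic travel.  Annual quantities (monitoring visits, post-transplant
medication) are prorated over the 13 cycles of a model year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelInputs, ScenarioSpec
from .states import (
    DIALYSIS_STATES,
    HD_STATES,
    HOME_HD_STATES,
    ICHD_STATES,
    N_STATES,
    State,
    YearBand,
)

__all__ = [
    "COMPONENTS",
    "TariffSchedule",
    "CostLedger",
    "treatment_cost_per_cycle",
    "esa_cost_per_cycle",
    "monitoring_cost_per_cycle",
    "hospitalisation_cost_per_cycle",
    "transport_cost_per_cycle",
    "access_event_cost",
    "transplant_event_costs",
    "cycle_cost_matrix",
]

WEEKS_PER_CYCLE = 4
DAYS_PER_CYCLE = 28

COMPONENTS = (
    "access",
    "treatment",
    "esa",
    "monitoring",
    "complications",
    "transportation",
    "transplant_procedure",
    "post_transplant_medication",
)

#: components as reported in budget summaries: transplant-related costs are
#: folded into "treatment" (the published component rows carry no separate
#: transplant line).
REPORT_COMPONENTS = (
    "access",
    "treatment",
    "esa",
    "monitoring",
    "complications",
    "transportation",
)


@dataclass(frozen=True)
class TariffSchedule:
    """Dialysis service tariffs in effect for one scenario."""

    ichd_per_session: float
    home_hd_weekly: float
    home_hd_high_dose_weekly: float
    apd_per_day: float
    capd_per_day: float
    sessions_per_week_conventional: int = 3
    sessions_per_week_high_dose: int = 5

    def __post_init__(self) -> None:
        if min(
            self.ichd_per_session,
            self.home_hd_weekly,
            self.home_hd_high_dose_weekly,
            self.apd_per_day,
            self.capd_per_day,
        ) < 0:
            raise ValueError("tariffs must be non-negative")

    @classmethod
    def from_inputs(cls, inputs: ModelInputs, scenario: ScenarioSpec) -> "TariffSchedule":
        c = inputs.costs
        return cls(
            ichd_per_session=c.ichd_session_weighted.point,
            home_hd_weekly=c.home_hd_weekly.point,
            home_hd_high_dose_weekly=scenario.home_hd_high_dose_weekly_tariff,
            apd_per_day=c.apd_daily.point,
            capd_per_day=c.capd_daily.point,
            sessions_per_week_conventional=c.sessions_per_week_conventional,
            sessions_per_week_high_dose=c.sessions_per_week_high_dose,
        )


def treatment_cost_per_cycle(
    state: State, tariffs: TariffSchedule, apd_share: float = 0.5
) -> float:
    """Dialysis service cost for one 28-day cycle in the given state.

    Non-dialysis states cost zero here by contract (transplant costs are
    event costs, see :func:`transplant_event_costs`).
    """
    state = State(state)
    if state is State.ICHD_CONVENTIONAL:
        return tariffs.ichd_per_session * tariffs.sessions_per_week_conventional * WEEKS_PER_CYCLE
    if state is State.ICHD_HIGH_DOSE:
        return tariffs.ichd_per_session * tariffs.sessions_per_week_high_dose * WEEKS_PER_CYCLE
    if state is State.HOME_HD_CONVENTIONAL:
        return tariffs.home_hd_weekly * WEEKS_PER_CYCLE
    if state is State.HOME_HD_HIGH_DOSE:
        return tariffs.home_hd_high_dose_weekly * WEEKS_PER_CYCLE
    if state is State.PD:
        per_day = apd_share * tariffs.apd_per_day + (1 - apd_share) * tariffs.capd_per_day
        return per_day * DAYS_PER_CYCLE
    return 0.0


def esa_cost_per_cycle(state: State, inputs: ModelInputs) -> float:
    """Erythropoiesis-stimulating agent cost per cycle (dose × unit price)."""
    state = State(state)
    c = inputs.costs
    if state in HD_STATES:
        dose = c.esa_dose_hd_units_per_week.point
    elif state is State.PD:
        dose = c.esa_dose_pd_units_per_week.point
    else:
        return 0.0
    return (dose / 1000.0) * c.esa_per_1000_units.point * WEEKS_PER_CYCLE


def monitoring_cost_per_cycle(inputs: ModelInputs) -> float:
    """Prorated monitoring cost: visits/year × weighted visit tariff / 13."""
    c = inputs.costs
    return c.monitoring_visits_per_year * c.monitoring_weighted / inputs.model.cycles_per_year


def hospitalisation_cost_per_cycle(
    state: State, year_band: YearBand, inputs: ModelInputs, which: str = "point"
) -> float:
    """Expected all-cause hospitalisation cost per cycle for a dialysis state."""
    state = State(state)
    if state not in DIALYSIS_STATES:
        return 0.0
    prob = inputs.hospitalisation.probability(state, year_band, which)
    return prob * inputs.hospitalisation.event_cost(state).point


def transport_cost_per_cycle(state: State, inputs: ModelInputs) -> float:
    """Clinic transport: in-centre sessions only; home-based care travels free."""
    state = State(state)
    c = inputs.costs
    if state is State.ICHD_CONVENTIONAL:
        sessions = c.sessions_per_week_conventional
    elif state is State.ICHD_HIGH_DOSE:
        sessions = c.sessions_per_week_high_dose
    else:
        return 0.0
    return c.transport_per_ichd_session.point * sessions * WEEKS_PER_CYCLE


def _access_group(state: State | None) -> str | None:
    if state is None:
        return None
    state = State(state)
    if state in HD_STATES:
        return "vascular"
    if state is State.PD:
        return "peritoneal"
    return None


def access_event_cost(
    previous_state: State | None, new_state: State, inputs: ModelInputs
) -> float:
    """Access establishment charged at entry and on access-type changes.

    Entering any HD state (from outside HD, including model entry and
    graft-failure return) costs the vascular access tariff; entering PD
    costs the peritoneal access tariff.  Switches within HD (setting or
    intensity changes) keep the access and cost nothing.
    """
    new_group = _access_group(new_state)
    if new_group is None:
        return 0.0
    if _access_group(previous_state) == new_group:
        return 0.0
    if new_group == "vascular":
        return inputs.costs.vascular_access.point
    return inputs.costs.peritoneal_access.point


def transplant_event_costs(state: State, inputs: ModelInputs) -> float:
    """Transplant procedure (single transplant cycle) and prorated
    post-transplant medication."""
    state = State(state)
    if state is State.TRANSPLANT:
        return inputs.costs.transplant_procedure.point
    if state is State.POST_TRANSPLANT:
        return (
            inputs.costs.post_transplant_medication_annual.point
            / inputs.model.cycles_per_year
        )
    return 0.0


def cycle_cost_matrix(
    inputs: ModelInputs, scenario: ScenarioSpec
) -> np.ndarray:
    """Per-patient-cycle cost by (state, year band, component).

    Shape ``(N_STATES, 2, len(COMPONENTS))``.  Access is event-driven and
    stays zero here.
    """
    tariffs = TariffSchedule.from_inputs(inputs, scenario)
    out = np.zeros((N_STATES, 2, len(COMPONENTS)))
    comp = {name: i for i, name in enumerate(COMPONENTS)}
    monitoring = monitoring_cost_per_cycle(inputs)
    for s in State:
        for yb in YearBand:
            if s in DIALYSIS_STATES:
                out[s, yb, comp["treatment"]] = treatment_cost_per_cycle(
                    s, tariffs, inputs.flags.apd_share
                )
                out[s, yb, comp["esa"]] = esa_cost_per_cycle(s, inputs)
                out[s, yb, comp["monitoring"]] = monitoring
                out[s, yb, comp["complications"]] = hospitalisation_cost_per_cycle(
                    s, yb, inputs
                )
                out[s, yb, comp["transportation"]] = transport_cost_per_cycle(s, inputs)
            elif s is State.TRANSPLANT:
                out[s, yb, comp["transplant_procedure"]] = transplant_event_costs(s, inputs)
            elif s is State.POST_TRANSPLANT:
                out[s, yb, comp["post_transplant_medication"]] = transplant_event_costs(
                    s, inputs
                )
                if inputs.flags.monitor_post_transplant:
                    out[s, yb, comp["monitoring"]] = monitoring
    return out


@dataclass
class CostLedger:
    """Per-cycle, per-component cost accumulator for one scenario run."""

    n_cycles: int
    per_cycle: np.ndarray = field(init=False)  # (n_cycles, n_components)
    patient_years: float = 0.0
    alive_mass_by_cycle: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.per_cycle = np.zeros((self.n_cycles, len(COMPONENTS)))
        self.alive_mass_by_cycle = np.zeros(self.n_cycles)

    def add(self, cycle: int, component: str, amount: float) -> None:
        if amount < 0:
            raise ValueError(f"negative cost for {component}: {amount}")
        self.per_cycle[cycle - 1, COMPONENTS.index(component)] += amount

    def add_vector(self, cycle: int, amounts: np.ndarray) -> None:
        self.per_cycle[cycle - 1] += amounts

    # -- summaries ----------------------------------------------------------

    def component_totals(self) -> dict[str, float]:
        totals = self.per_cycle.sum(axis=0)
        return {name: float(totals[i]) for i, name in enumerate(COMPONENTS)}

    def report_totals(self) -> dict[str, float]:
        """Component totals with transplant costs folded into treatment."""
        t = self.component_totals()
        folded = {name: t[name] for name in REPORT_COMPONENTS}
        folded["treatment"] += t["transplant_procedure"] + t["post_transplant_medication"]
        return folded

    def total(self) -> float:
        return float(self.per_cycle.sum())

    def cumulative(self) -> np.ndarray:
        return self.per_cycle.cumsum(axis=0)

    def to_frame(self, scenario_id: str = "") -> pd.DataFrame:
        """Tidy export: (cycle, component, scenario, GBP)."""
        rows = []
        for j in range(self.n_cycles):
            for i, name in enumerate(COMPONENTS):
                rows.append(
                    {
                        "cycle": j + 1,
                        "component": name,
                        "scenario": scenario_id,
                        "gbp": self.per_cycle[j, i],
                    }
                )
        return pd.DataFrame(rows)
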