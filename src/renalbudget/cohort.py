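"""Deterministic cohort engine: 28-day-cycle Markov dynamics with tunnel states.

Occupancy mass is tracked on a four-way grid:

- health state (five dialysis modalities, transplant, post-transplant, dead);
- modality tenure in cycles (a tunnel dimension; the month bands that drive
  duration-dependent switch probabilities are a deterministic function of it);
- entry cohort (the prevalent cohort entering at model start, plus one
  incident cohort per entry year) — this fixes each cell's mortality clock
  and its year-1 / year-2+ hospitalisation band exactly;
- entry class (incident vs prevalent), which selects the 0–6-month switch
  probability row; graft-failure returners re-enter dialysis as "prevalent".

Event ordering within a cycle is death → transplant → modality switch, each
applied to the mass remaining after the previous event, so exactly one
movement happens per cycle and every transition row sums to one.
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
    MODALITY_ORDER,
    N_STATES,
    EntryClass,
    State,
    TenureBand,
    YearBand,
    tenure_band,
)
from .survival import SurvivalCurve, cycle_death_probability

__all__ = [
    "CohortState",
    "TransitionRow",
    "transition_row",
    "initialize_cohort",
    "enter_incident",
    "advance",
]

#: hazard-ratio group per state: high-dose states carry the high-dose HR,
#: the home setting itself confers no survival difference.
_HIGH_DOSE = (State.ICHD_HIGH_DOSE, State.HOME_HD_HIGH_DOSE)


def _state_hazard_ratio(state: State, inputs: ModelInputs) -> float:
    hr = 1.0
    if state in _HIGH_DOSE:
        hr *= inputs.mortality.hr_high_dose_hd.point
    if state in HOME_HD_STATES:
        hr *= inputs.mortality.hr_home_hd.point
    return hr


def _band_vector(max_tenure: int) -> np.ndarray:
    """band index for tenure k = 1..max_tenure (index 0 unused)."""
    out = np.zeros(max_tenure + 1, dtype=int)
    for k in range(1, max_tenure + 1):
        out[k] = int(tenure_band(k))
    return out


@dataclass(frozen=True)
class TransitionRow:
    """One row of the transition kernel: destination probabilities plus stay."""

    destinations: dict[str, float]
    stay: float

    def total(self) -> float:
        return self.stay + sum(self.destinations.values())

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.destinations.values()) or self.stay < 0:
            raise ValueError(f"negative transition probability in {self}")
        if abs(self.total() - 1.0) > 1e-12:
            raise ValueError(
                f"transition row sums to {self.total()!r}, not 1: {self}"
            )


def _switch_probs(
    state: State, band: TenureBand, entry_class: EntryClass, inputs: ModelInputs
) -> dict[str, float]:
    """Modality-switch probabilities by destination group (before composition)."""
    t = inputs.transitions
    if state is State.PD:
        return {"hd": t.pd_to_hd.prob(band, entry_class)}
    if state in ICHD_STATES:
        return {
            "pd": t.hd_to_pd.prob(band, entry_class),
            "home_hd": t.ichd_to_home_hd.prob(band),
        }
    if state in HOME_HD_STATES:
        return {
            "pd": t.hd_to_pd.prob(band, entry_class),
            "ichd": t.home_hd_to_ichd.fraction,
        }
    raise ValueError(f"{state!r} has no modality-switch row")


def transition_row(
    state: State,
    band: TenureBand,
    entry_class: EntryClass,
    inputs: ModelInputs,
    curves: dict[str, SurvivalCurve],
    clock: int = 0,
) -> TransitionRow:
    """Compose the one-cycle transition row for a living state.

    ``clock`` is the number of completed cycles on the state's mortality
    clock (time since dialysis/model entry for dialysis states; time since
    transplant for the transplant and post-transplant states).

    Events are composed sequentially — death, then transplant, then modality
    switch — each applied to the mass remaining after the previous one, so
    the row always sums to one.
    """
    state = State(state)
    if state is State.DEAD:
        raise ValueError("dead is absorbing; no transition row")

    if state in (State.TRANSPLANT, State.POST_TRANSPLANT):
        qd = cycle_death_probability(curves["transplant"], clock, 1.0)
        if state is State.TRANSPLANT:
            # single-cycle tunnel: all survivors move on
            return TransitionRow({"dead": qd, "post_transplant": 1.0 - qd}, stay=0.0)
        graft = (1.0 - qd) * inputs.transitions.graft_failure.point
        return TransitionRow(
            {"dead": qd, "dialysis": graft}, stay=1.0 - qd - graft
        )

    qd = cycle_death_probability(
        curves["dialysis"], clock, _state_hazard_ratio(state, inputs)
    )
    tx = (1.0 - qd) * inputs.transitions.transplant_rate.point
    rem = (1.0 - qd) * (1.0 - inputs.transitions.transplant_rate.point)
    switches = {k: rem * p for k, p in _switch_probs(state, band, entry_class, inputs).items()}
    total_moved = qd + tx + sum(switches.values())
    if total_moved > 1.0 + 1e-12:
        raise ValueError(
            f"composed transition probabilities exceed 1 for {state.name}: {total_moved}"
        )
    return TransitionRow({"dead": qd, "transplant": tx, **switches}, stay=1.0 - total_moved)


@dataclass
class CohortState:
    """Occupancy mass on (state × tenure × entry cohort × entry class).

    ``cycle`` counts completed cycles; costs for cycle ``cycle + 1`` are
    accrued on this occupancy before :func:`advance` is applied.
    """

    occupancy: np.ndarray  # (N_STATES, max_tenure+1, n_cohorts, 2); tenure index 0 unused
    cycle: int
    entry_cycles: tuple[int, ...]  # completed cycles at entry, per cohort

    @property
    def n_cohorts(self) -> int:
        return self.occupancy.shape[2]

    def total_mass(self) -> float:
        return float(self.occupancy.sum())

    def alive_mass(self) -> float:
        return float(self.occupancy.sum()) - float(self.occupancy[State.DEAD].sum())

    def state_totals(self) -> np.ndarray:
        """Mass per health state, shape (N_STATES,)."""
        return self.occupancy.sum(axis=(1, 2, 3))

    def dialysis_year_band(self, cohort: int, flags_prevalent_year1: bool = False) -> YearBand:
        """Year-1 vs year-2+ hospitalisation band of a cohort during the
        current cycle (``self.cycle + 1``, 1-based)."""
        j = self.cycle + 1
        e = self.entry_cycles[cohort]
        if e == 0:  # prevalent cohort: already beyond its first dialysis year
            if flags_prevalent_year1 and j <= 13:
                return YearBand.YEAR_1
            return YearBand.YEAR_2_PLUS
        return YearBand.YEAR_1 if (j - e) <= 13 else YearBand.YEAR_2_PLUS

    def masses_by_state_yearband(self, flags_prevalent_year1: bool = False) -> np.ndarray:
        """Mass per (state, year band), shape (N_STATES, 2)."""
        out = np.zeros((N_STATES, 2))
        per_cohort = self.occupancy.sum(axis=(1, 3))  # (states, cohorts)
        for c in range(self.n_cohorts):
            band = self.dialysis_year_band(c, flags_prevalent_year1)
            out[:, int(band)] += per_cohort[:, c]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (cycle, state, tenure band, entry class)."""
        rows = []
        occ = self.occupancy
        for s in State:
            for f in EntryClass:
                mass_by_tenure = occ[s, :, :, f].sum(axis=1)
                band_mass = {b: 0.0 for b in TenureBand}
                for k in range(1, occ.shape[1]):
                    if mass_by_tenure[k] > 0:
                        band_mass[tenure_band(k)] += mass_by_tenure[k]
                for b, m in band_mass.items():
                    if m > 0:
                        rows.append(
                            {
                                "cycle": self.cycle,
                                "state": s.name,
                                "tenure_band": b.name,
                                "entry_class": f.name,
                                "mass": m,
                            }
                        )
        return pd.DataFrame(rows, columns=["cycle", "state", "tenure_band", "entry_class", "mass"])

    def copy(self) -> "CohortState":
        return CohortState(self.occupancy.copy(), self.cycle, self.entry_cycles)


def _entry_cycles(inputs: ModelInputs) -> tuple[int, ...]:
    cpy = inputs.model.cycles_per_year
    return (0,) + tuple(cpy * (y - 1) for y in inputs.population.incident_entry_years)


def initialize_cohort(scenario: ScenarioSpec, inputs: ModelInputs) -> CohortState:
    """Baseline occupancy: the prevalent population at the scenario mix.

    The prevalent cohort starts with modality tenure 1 (its modality clock
    starts at model start, which is what makes the prevalent 0–6-month
    switch rows applicable) but is already in year 2+ of dialysis for
    hospitalisation purposes.
    """
    entries = _entry_cycles(inputs)
    max_tenure = inputs.model.horizon_cycles + 1
    occ = np.zeros((N_STATES, max_tenure + 1, len(entries), 2))
    for state, frac in zip(MODALITY_ORDER, scenario.prevalent_array):
        occ[state, 1, 0, EntryClass.PREVALENT] = inputs.population.prevalent * frac
    return CohortState(occupancy=occ, cycle=0, entry_cycles=entries)


def enter_incident(
    cohort: CohortState, model_year: int, scenario: ScenarioSpec, inputs: ModelInputs
) -> CohortState:
    """Add the incident cohort entering at the first cycle of ``model_year``.

    Years outside the configured entry years (year 1 in the shipped
    configuration) leave the cohort unchanged.
    """
    if not 1 <= model_year <= inputs.model.horizon_years:
        raise ValueError(f"model_year must be in 1..{inputs.model.horizon_years}")
    if model_year not in inputs.population.incident_entry_years:
        return cohort.copy()
    new = cohort.copy()
    c = 1 + inputs.population.incident_entry_years.index(model_year)
    for state, frac in zip(MODALITY_ORDER, scenario.incident_array):
        new.occupancy[state, 1, c, EntryClass.INCIDENT] += (
            inputs.population.incident_per_year * frac
        )
    return new


def _normalised(weights: np.ndarray, fallback_index: int) -> np.ndarray:
    """Weights normalised to sum 1; all mass on ``fallback_index`` if zero."""
    total = weights.sum()
    if total <= 0:
        out = np.zeros_like(weights)
        out[fallback_index] = 1.0
        return out
    return weights / total


@dataclass
class CycleFlows:
    """Masses that moved during one cycle, for event-cost accounting."""

    hd_to_pd: float = 0.0
    pd_to_hd: float = 0.0
    graft_to_pd: float = 0.0
    graft_to_hd: float = 0.0
    deaths: float = 0.0
    transplants: float = 0.0
    extra: dict = field(default_factory=dict)


def advance(
    cohort: CohortState,
    inputs: ModelInputs,
    curves: dict[str, SurvivalCurve],
    scenario: ScenarioSpec,
) -> tuple[CohortState, CycleFlows]:
    """Apply one 28-day cycle of deaths, transplants and modality switches.

    Movers re-enter their destination with tenure 1; stayers' tenure
    increments.  Transplant occupants move to post-transplant after exactly
    one cycle.  Graft failures return to dialysis spread over the scenario's
    prevalent baseline distribution, with entry class reset to prevalent.
    Haemodialysis-destined movers split between conventional and high-dose
    within the destination setting according to the scenario's baseline
    proportions for that setting.
    """
    occ = cohort.occupancy
    n_states, n_ten, n_coh, _ = occ.shape
    new = np.zeros_like(occ)
    flows = CycleFlows()

    prev = scenario.prevalent_array
    # destination splits derived from the scenario baseline
    hd_idx = [int(s) for s in HD_STATES]
    hd_split = _normalised(prev[[MODALITY_ORDER.index(s) for s in HD_STATES]], 0)
    home_idx = [int(s) for s in HOME_HD_STATES]
    home_split = _normalised(
        prev[[MODALITY_ORDER.index(s) for s in HOME_HD_STATES]], 0
    )
    ichd_idx = [int(s) for s in ICHD_STATES]
    ichd_split = _normalised(prev[[MODALITY_ORDER.index(s) for s in ICHD_STATES]], 0)
    dial_idx = [int(s) for s in DIALYSIS_STATES]
    graft_split = prev  # sums to 1 over dialysis states by construction

    band_of = _band_vector(n_ten - 1)
    t_rate = inputs.transitions.transplant_rate.point
    g_rate = inputs.transitions.graft_failure.point

    # carry dead mass through unchanged
    new[State.DEAD] = occ[State.DEAD]

    for c in range(n_coh):
        e = cohort.entry_cycles[c]
        if e > cohort.cycle:
            continue  # cohort not yet entered
        clock = cohort.cycle - e  # completed cycles since dialysis/model entry

        for f in (EntryClass.INCIDENT, EntryClass.PREVALENT):
            # ---- transplant tunnel state: one cycle then move on -----------
            m_tx = occ[State.TRANSPLANT, :, c, f]
            if m_tx.any():
                ks = np.nonzero(m_tx)[0]
                for k in ks:
                    qd = cycle_death_probability(curves["transplant"], int(k) - 1, 1.0)
                    dead = m_tx[k] * qd
                    new[State.DEAD, 1, c, f] += dead
                    flows.deaths += dead
                    new[State.POST_TRANSPLANT, 1, c, f] += m_tx[k] * (1.0 - qd)

            # ---- post-transplant: graft failure or stay --------------------
            m_post = occ[State.POST_TRANSPLANT, :, c, f]
            if m_post.any():
                ks = np.nonzero(m_post)[0]
                for k in ks:
                    qd = cycle_death_probability(curves["transplant"], int(k) - 1, 1.0)
                    m = m_post[k]
                    dead = m * qd
                    new[State.DEAD, 1, c, f] += dead
                    flows.deaths += dead
                    failed = m * (1.0 - qd) * g_rate
                    for s_i, w in zip(dial_idx, graft_split):
                        if w > 0:
                            # returners are re-classified as prevalent
                            new[s_i, 1, c, EntryClass.PREVALENT] += failed * w
                    flows.graft_to_pd += failed * graft_split[MODALITY_ORDER.index(State.PD)]
                    flows.graft_to_hd += failed * (
                        1.0 - graft_split[MODALITY_ORDER.index(State.PD)]
                    )
                    stay = m * (1.0 - qd) * (1.0 - g_rate)
                    if k + 1 < n_ten:
                        new[State.POST_TRANSPLANT, k + 1, c, f] += stay

            # ---- dialysis states ------------------------------------------
            for s in DIALYSIS_STATES:
                m_vec = occ[s, :, c, f]
                if not m_vec.any():
                    continue
                qd = cycle_death_probability(
                    curves["dialysis"], clock, _state_hazard_ratio(s, inputs)
                )
                total = m_vec.sum()
                dead = total * qd
                new[State.DEAD, 1, c, f] += dead
                flows.deaths += dead
                tx = total * (1.0 - qd) * t_rate
                new[State.TRANSPLANT, 1, c, f] += tx
                flows.transplants += tx

                rem_frac = (1.0 - qd) * (1.0 - t_rate)
                # per-tenure switch probabilities via band lookup
                switch = _switch_probs(s, TenureBand.MONTHS_0_6, f, inputs)
                p_by_dest: dict[str, np.ndarray] = {}
                for dest in switch:
                    tab = np.array(
                        [
                            _switch_probs(s, TenureBand(b), f, inputs)[dest]
                            for b in range(4)
                        ]
                    )
                    p_by_dest[dest] = tab[band_of]

                moved_total = np.zeros(n_ten)
                for dest, pvec in p_by_dest.items():
                    moved = m_vec * rem_frac * pvec
                    moved_total += moved
                    amount = moved.sum()
                    if amount <= 0:
                        continue
                    if dest == "pd":
                        new[State.PD, 1, c, f] += amount
                        flows.hd_to_pd += amount
                    elif dest == "hd":
                        for s_i, w in zip(hd_idx, hd_split):
                            if w > 0:
                                new[s_i, 1, c, f] += amount * w
                        flows.pd_to_hd += amount
                    elif dest == "home_hd":
                        for s_i, w in zip(home_idx, home_split):
                            if w > 0:
                                new[s_i, 1, c, f] += amount * w
                    elif dest == "ichd":
                        for s_i, w in zip(ichd_idx, ichd_split):
                            if w > 0:
                                new[s_i, 1, c, f] += amount * w

                stay = m_vec * rem_frac - moved_total
                if np.any(stay < -1e-12 * max(total, 1.0)):
                    raise RuntimeError(
                        f"negative stay mass in state {State(s).name}; invalid inputs"
                    )
                new[s, 2:, c, f] += stay[1:-1]
                # tenure is capped at the array edge (band 19+ regardless)
                new[s, n_ten - 1, c, f] += stay[n_ten - 1]

    if np.any(new < -1e-9):
        raise RuntimeError("negative occupancy mass after update")
    new = np.maximum(new, 0.0)
    return CohortState(new, cohort.cycle + 1, cohort.entry_cycles), flows
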