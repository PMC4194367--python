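"""Individual-patient Monte-Carlo simulator used to cross-validate the
deterministic cohort engine.

Each simulated patient draws its entry cohort, starting modality and one
(death, transplant/graft, switch-destination) uniform triple per cycle from
its own random substream (spawned deterministically from a single global
seed, so earlier patients' histories are unchanged when ``n`` grows).  The
per-cycle event probabilities are exactly the composed transition-row
probabilities the cohort engine uses: death first, then transplant, then
modality switch, at most one movement per cycle, with destination
redistribution driven by the scenario's baseline distribution.

Aggregated occupancies and component costs scale each patient to
``total entrants / n`` and come with Monte-Carlo standard errors, so the
cohort engine's expectations can be checked at a chosen confidence
multiple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelInputs, ScenarioSpec, default_inputs
from .costs import COMPONENTS, access_event_cost, cycle_cost_matrix
from .states import (
    DIALYSIS_STATES,
    HD_STATES,
    HOME_HD_STATES,
    ICHD_STATES,
    MODALITY_ORDER,
    N_STATES,
    EntryClass,
    State,
    tenure_band,
)
from .survival import SurvivalCurve, cycle_death_probability, make_default_curves

__all__ = ["MicrosimResult", "simulate_patients"]

_NOT_ENTERED = -1


@dataclass
class MicrosimResult:
    """Aggregated microsimulation output with Monte-Carlo standard errors."""

    n: int
    seed: int
    total_mass: float
    snapshot_cycles: tuple[int, ...]
    occupancy_mean: dict[int, np.ndarray]  # cycle -> (N_STATES,) expected mass
    occupancy_se: dict[int, np.ndarray]
    cost_mean: dict[str, float]  # component -> expected total GBP
    cost_se: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def report_cost_mean(self) -> dict[str, float]:
        """Component totals with transplant costs folded into treatment."""
        out = {
            k: self.cost_mean[k]
            for k in ("access", "treatment", "esa", "monitoring", "complications", "transportation")
        }
        out["treatment"] += (
            self.cost_mean["transplant_procedure"]
            + self.cost_mean["post_transplant_medication"]
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cyc in self.snapshot_cycles:
            for s in State:
                rows.append(
                    {
                        "kind": "occupancy",
                        "cycle": cyc,
                        "key": s.name,
                        "estimate": self.occupancy_mean[cyc][s],
                        "se": self.occupancy_se[cyc][s],
                    }
                )
        for comp in COMPONENTS:
            rows.append(
                {
                    "kind": "cost",
                    "cycle": None,
                    "key": comp,
                    "estimate": self.cost_mean[comp],
                    "se": self.cost_se[comp],
                }
            )
        return pd.DataFrame(rows)


def _cumulative(weights: np.ndarray) -> np.ndarray:
    c = np.cumsum(weights)
    if c[-1] <= 0:
        raise ValueError("cannot draw from an all-zero distribution")
    return c / c[-1]


def _normalised(weights: np.ndarray, fallback: int) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        out = np.zeros_like(weights)
        out[fallback] = 1.0
        return out
    return weights / total


def simulate_patients(
    n: int,
    seed: int,
    scenario: ScenarioSpec,
    inputs: ModelInputs | None = None,
    curves: dict[str, SurvivalCurve] | None = None,
    snapshot_cycles: tuple[int, ...] = (13, 39, 65),
) -> MicrosimResult:
    """Simulate ``n`` individual patients and aggregate with standard errors.

    The same seed always reproduces the same aggregates bit-for-bit.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1; got {n}")
    inputs = inputs if inputs is not None else default_inputs()
    curves = curves if curves is not None else make_default_curves(inputs.survival)

    n_cycles = inputs.model.horizon_cycles
    cpy = inputs.model.cycles_per_year
    entry_years = inputs.population.incident_entry_years
    entry_cycles = np.array([0] + [cpy * (y - 1) for y in entry_years])
    cohort_sizes = np.array(
        [float(inputs.population.prevalent)]
        + [float(inputs.population.incident_per_year)] * len(entry_years)
    )
    total_mass = cohort_sizes.sum()
    cohort_cum = _cumulative(cohort_sizes)

    # per-patient uniforms from independent substreams: 2 initial draws plus
    # a (death, event, destination) triple per cycle
    m = 2 + 3 * n_cycles
    children = np.random.SeedSequence(seed).spawn(n)
    uni = np.empty((n, m))
    for i, child in enumerate(children):
        uni[i] = np.random.default_rng(child).random(m)

    cohort_ix = np.searchsorted(cohort_cum, uni[:, 0], side="left")
    entry = entry_cycles[cohort_ix]
    prevalent_cum = _cumulative(scenario.prevalent_array)
    incident_cum = _cumulative(scenario.incident_array)
    modality_order = np.array([int(s) for s in MODALITY_ORDER])
    init_state = np.where(
        cohort_ix == 0,
        modality_order[np.searchsorted(prevalent_cum, uni[:, 1], side="left")],
        modality_order[np.searchsorted(incident_cum, uni[:, 1], side="left")],
    )

    state = np.full(n, _NOT_ENTERED, dtype=int)
    tenure = np.zeros(n, dtype=int)
    flag = np.where(cohort_ix == 0, int(EntryClass.PREVALENT), int(EntryClass.INCIDENT))

    cost = np.zeros((n, len(COMPONENTS)))
    comp_ix = {name: i for i, name in enumerate(COMPONENTS)}
    costs_mat = cycle_cost_matrix(inputs, scenario)

    access_cost_by_state = np.array(
        [access_event_cost(None, State(s), inputs) if State(s) in DIALYSIS_STATES else 0.0
         for s in range(N_STATES)]
    )
    peritoneal = inputs.costs.peritoneal_access.point
    vascular = inputs.costs.vascular_access.point

    prev = scenario.prevalent_array
    hd_states = np.array([int(s) for s in HD_STATES])
    hd_cum = _cumulative(_normalised(prev[[MODALITY_ORDER.index(s) for s in HD_STATES]], 0))
    home_states = np.array([int(s) for s in HOME_HD_STATES])
    home_cum = _cumulative(
        _normalised(prev[[MODALITY_ORDER.index(s) for s in HOME_HD_STATES]], 0)
    )
    ichd_states = np.array([int(s) for s in ICHD_STATES])
    ichd_cum = _cumulative(
        _normalised(prev[[MODALITY_ORDER.index(s) for s in ICHD_STATES]], 0)
    )
    dial_states = np.array([int(s) for s in DIALYSIS_STATES])
    graft_cum = _cumulative(prev)

    band_of = np.zeros(n_cycles + 2, dtype=int)
    for k in range(1, n_cycles + 2):
        band_of[k] = int(tenure_band(k))

    t_rate = inputs.transitions.transplant_rate.point
    g_rate = inputs.transitions.graft_failure.point
    hr_by_state = np.ones(N_STATES)
    for s in (State.ICHD_HIGH_DOSE, State.HOME_HD_HIGH_DOSE):
        hr_by_state[s] = inputs.mortality.hr_high_dose_hd.point
    for s in HOME_HD_STATES:
        hr_by_state[s] *= inputs.mortality.hr_home_hd.point

    # switch-probability tables by (band, entry class)
    p_pd_to_hd = np.array(
        [
            [inputs.transitions.pd_to_hd.prob(b, EntryClass(f)) for f in range(2)]
            for b in range(4)
        ]
    )
    p_hd_to_pd = np.array(
        [
            [inputs.transitions.hd_to_pd.prob(b, EntryClass(f)) for f in range(2)]
            for b in range(4)
        ]
    )
    p_ichd_home = np.array(
        [inputs.transitions.ichd_to_home_hd.prob(b) for b in range(4)]
    )
    p_home_ichd = inputs.transitions.home_hd_to_ichd.fraction

    occupancy_snapshots: dict[int, np.ndarray] = {}

    for j in range(1, n_cycles + 1):
        # entries at the first cycle after each cohort's entry point
        entering = (entry == j - 1) & (state == _NOT_ENTERED)
        if entering.any():
            state[entering] = init_state[entering]
            tenure[entering] = 1
            charge = entering.copy()
            if not inputs.flags.charge_prevalent_baseline_access:
                charge &= cohort_ix != 0
            cost[charge, comp_ix["access"]] += access_cost_by_state[state[charge]]

        if j in snapshot_cycles:
            snap = np.zeros((n, N_STATES))
            active_now = state >= 0
            snap[active_now, state[active_now]] = 1.0
            occupancy_snapshots[j] = snap

        alive = (state >= 0) & (state != int(State.DEAD))
        if alive.any():
            yb = np.where((entry > 0) & (j - entry <= cpy), 0, 1)
            if inputs.flags.prevalent_hospitalisation_year1 and j <= cpy:
                yb = np.where(entry == 0, 0, yb)
            idx = np.nonzero(alive)[0]
            cost[idx] += costs_mat[state[idx], yb[idx]]

        # --- transitions at end of cycle -------------------------------
        u_d = uni[:, 2 + 3 * (j - 1)]
        u_e = uni[:, 3 + 3 * (j - 1)]
        u_s = uni[:, 4 + 3 * (j - 1)]

        # death probabilities, computed lazily per occupied (group, clock)
        q = np.zeros(n)
        for c in range(len(entry_cycles)):
            clock = j - 1 - entry_cycles[c]
            if clock < 0:
                continue
            in_cohort = alive & (cohort_ix == c)
            if not in_cohort.any():
                continue
            for s in DIALYSIS_STATES:
                mask = in_cohort & (state == int(s))
                if mask.any():
                    q[mask] = cycle_death_probability(
                        curves["dialysis"], int(clock), hr_by_state[s]
                    )
        tx_mask_states = alive & np.isin(state, (int(State.TRANSPLANT), int(State.POST_TRANSPLANT)))
        if tx_mask_states.any():
            for k in np.unique(tenure[tx_mask_states]):
                mask = tx_mask_states & (tenure == k)
                q[mask] = cycle_death_probability(curves["transplant"], int(k) - 1, 1.0)

        dying = alive & (u_d < q)
        survivors = alive & ~dying

        new_state = state.copy()
        new_tenure = tenure.copy()
        new_state[dying] = int(State.DEAD)

        # transplant tunnel: survivors move on after exactly one cycle
        from_tx = survivors & (state == int(State.TRANSPLANT))
        new_state[from_tx] = int(State.POST_TRANSPLANT)
        new_tenure[from_tx] = 1

        # post-transplant: graft failure back to dialysis
        from_post = survivors & (state == int(State.POST_TRANSPLANT))
        failing = from_post & (u_e < g_rate)
        if failing.any():
            dest = dial_states[np.searchsorted(graft_cum, u_s[failing], side="left")]
            new_state[failing] = dest
            new_tenure[failing] = 1
            flag[failing] = int(EntryClass.PREVALENT)
            cost[failing, comp_ix["access"]] += np.where(
                dest == int(State.PD), peritoneal, vascular
            )
        staying_post = from_post & ~failing
        new_tenure[staying_post] = tenure[staying_post] + 1

        # dialysis states: transplant, then modality switch, else stay
        on_dialysis = survivors & np.isin(state, dial_states)
        to_tx = on_dialysis & (u_e < t_rate)
        new_state[to_tx] = int(State.TRANSPLANT)
        new_tenure[to_tx] = 1

        switchable = on_dialysis & ~to_tx
        if switchable.any():
            band = band_of[np.clip(tenure, 0, n_cycles + 1)]
            moved = np.zeros(n, dtype=bool)

            pd_mask = switchable & (state == int(State.PD))
            if pd_mask.any():
                p = p_pd_to_hd[band[pd_mask], flag[pd_mask]]
                go = u_s[pd_mask] < p
                ix = np.nonzero(pd_mask)[0][go]
                if ix.size:
                    sub = u_s[ix] / p[go]
                    dest = hd_states[np.searchsorted(hd_cum, sub, side="left")]
                    new_state[ix] = dest
                    new_tenure[ix] = 1
                    cost[ix, comp_ix["access"]] += vascular
                    moved[ix] = True

            ichd_mask = switchable & np.isin(state, ichd_states)
            if ichd_mask.any():
                p1 = p_hd_to_pd[band[ichd_mask], flag[ichd_mask]]
                p2 = p_ichd_home[band[ichd_mask]]
                u = u_s[ichd_mask]
                ix_all = np.nonzero(ichd_mask)[0]
                to_pd = u < p1
                ix = ix_all[to_pd]
                if ix.size:
                    new_state[ix] = int(State.PD)
                    new_tenure[ix] = 1
                    cost[ix, comp_ix["access"]] += peritoneal
                    moved[ix] = True
                to_home = (~to_pd) & (u < p1 + p2)
                ix = ix_all[to_home]
                if ix.size:
                    sub = (u[to_home] - p1[to_home]) / p2[to_home]
                    dest = home_states[np.searchsorted(home_cum, sub, side="left")]
                    new_state[ix] = dest
                    new_tenure[ix] = 1
                    moved[ix] = True

            home_mask = switchable & np.isin(state, home_states)
            if home_mask.any():
                p1 = p_hd_to_pd[band[home_mask], flag[home_mask]]
                u = u_s[home_mask]
                ix_all = np.nonzero(home_mask)[0]
                to_pd = u < p1
                ix = ix_all[to_pd]
                if ix.size:
                    new_state[ix] = int(State.PD)
                    new_tenure[ix] = 1
                    cost[ix, comp_ix["access"]] += peritoneal
                    moved[ix] = True
                to_ichd = (~to_pd) & (u < p1 + p_home_ichd)
                ix = ix_all[to_ichd]
                if ix.size:
                    sub = (u[to_ichd] - p1[to_ichd]) / p_home_ichd
                    dest = ichd_states[np.searchsorted(ichd_cum, sub, side="left")]
                    new_state[ix] = dest
                    new_tenure[ix] = 1
                    moved[ix] = True

            stayers = switchable & ~moved
            new_tenure[stayers] = tenure[stayers] + 1

        state, tenure = new_state, new_tenure

    scale = total_mass / n
    occ_mean: dict[int, np.ndarray] = {}
    occ_se: dict[int, np.ndarray] = {}
    for cyc, snap in occupancy_snapshots.items():
        occ_mean[cyc] = snap.mean(axis=0) * total_mass
        occ_se[cyc] = snap.std(axis=0, ddof=1) / np.sqrt(n) * total_mass
    cost_mean = {
        comp: float(cost[:, i].mean() * total_mass) for comp, i in comp_ix.items()
    }
    cost_se = {
        comp: float(cost[:, i].std(ddof=1) / np.sqrt(n) * total_mass)
        for comp, i in comp_ix.items()
    }
    return MicrosimResult(
        n=n,
        seed=seed,
        total_mass=total_mass,
        snapshot_cycles=tuple(snapshot_cycles),
        occupancy_mean=occ_mean,
        occupancy_se=occ_se,
        cost_mean=cost_mean,
        cost_se=cost_se,
        metadata={
            "scenario": scenario.id,
            "survival": {k: c.to_dict() for k, c in curves.items()},
        },
    )
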