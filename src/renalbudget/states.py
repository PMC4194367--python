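"""Health states, tenure bands and model-time conventions.

The model tracks prevalent and incident dialysis patients through discrete
28-day cycles over a 5-year horizon.  Each dialysis modality is a separate
health state; kidney transplantation is a single-cycle tunnel state followed
by a post-transplant state from which graft failure returns patients to
dialysis.  Death is absorbing and reachable from every living state.
"""

from __future__ import annotations

from enum import IntEnum

CYCLE_DAYS = 28
DAYS_PER_YEAR = 365.25
CYCLE_YEARS = CYCLE_DAYS / DAYS_PER_YEAR
#: 13 cycles of 28 days = 364 days; an integral number of cycles per model
#: year keeps incident entry and annual cost proration exact.
CYCLES_PER_YEAR = 13
HORIZON_YEARS = 5
HORIZON_CYCLES = CYCLES_PER_YEAR * HORIZON_YEARS  # 65


class State(IntEnum):
    """Model health states (Figure-style flow: dialysis ↔, → transplant → post)."""

    PD = 0                    # peritoneal dialysis (APD/CAPD as a cost weight)
    ICHD_CONVENTIONAL = 1     # in-centre HD, 3 × 4 h sessions/week
    ICHD_HIGH_DOSE = 2        # in-centre HD, 5 sessions/week (always 0 in shipped scenarios)
    HOME_HD_CONVENTIONAL = 3  # home HD at the weekly tariff, 3 sessions/week
    HOME_HD_HIGH_DOSE = 4     # home HD, 5 × ≥4 h sessions/week
    TRANSPLANT = 5            # single-cycle tunnel state (procedure cycle)
    POST_TRANSPLANT = 6       # functioning graft; graft failure returns to dialysis
    DEAD = 7


N_STATES = len(State)

DIALYSIS_STATES: tuple[State, ...] = (
    State.PD,
    State.ICHD_CONVENTIONAL,
    State.ICHD_HIGH_DOSE,
    State.HOME_HD_CONVENTIONAL,
    State.HOME_HD_HIGH_DOSE,
)
HD_STATES: tuple[State, ...] = DIALYSIS_STATES[1:]
ICHD_STATES: tuple[State, ...] = (State.ICHD_CONVENTIONAL, State.ICHD_HIGH_DOSE)
HOME_HD_STATES: tuple[State, ...] = (State.HOME_HD_CONVENTIONAL, State.HOME_HD_HIGH_DOSE)
HIGH_DOSE_STATES: tuple[State, ...] = (State.ICHD_HIGH_DOSE, State.HOME_HD_HIGH_DOSE)
ALIVE_STATES: tuple[State, ...] = tuple(s for s in State if s is not State.DEAD)

#: Order of the five modality columns used by scenario distributions.
MODALITY_ORDER: tuple[State, ...] = DIALYSIS_STATES


class TenureBand(IntEnum):
    """Months-on-current-modality bands driving duration-dependent switching."""

    MONTHS_0_6 = 0
    MONTHS_7_12 = 1
    MONTHS_13_18 = 2
    MONTHS_19_PLUS = 3


def tenure_band(tenure: int) -> TenureBand:
    """Map a modality tenure (in 28-day cycles, 1-based) to its month band.

    Six months is ~6.5 cycles, rounded up, so cycles 1–7 fall in the 0–6
    month band; one year is 13 cycles, so cycle 13 (364 days) still belongs
    to 7–12 months.

    Parameters
    ----------
    tenure:
        Number of the current cycle within the present modality episode
        (the first cycle in a state has tenure 1).
    """
    if tenure < 1:
        raise ValueError(
            f"tenure must be >= 1 (entry is handled separately); got {tenure}"
        )
    if tenure <= 7:
        return TenureBand.MONTHS_0_6
    if tenure <= 13:
        return TenureBand.MONTHS_7_12
    if tenure <= 20:
        return TenureBand.MONTHS_13_18
    return TenureBand.MONTHS_19_PLUS


class EntryClass(IntEnum):
    """Incident vs prevalent row selection for the 0–6 month switch rates."""

    INCIDENT = 0
    PREVALENT = 1


class YearBand(IntEnum):
    """First year on dialysis vs follow-up years (hospitalisation rates)."""

    YEAR_1 = 0
    YEAR_2_PLUS = 1
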