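"""Model inputs: parameter loading, validation and scenario definitions.

All inputs to the budget-impact model — transition probabilities with their
one-way sensitivity ranges, survival-curve configuration, hospitalisation
probabilities, unit costs and the scenario modality distributions — live in
a single JSON document.  The packaged default (``data/default_config.json``)
carries the England NHS payer parameterisation: Payment-by-Results tariffs,
registry-derived population sizes (22,993 prevalent patients; 5,395 incident
patients entering annually in years 2–5) and the published modality-switch
probabilities.

Sensitivity ranges follow a ±25 % convention: ``low/high = point × (1 ∓ 0.25)``
rounded half-up at the printed precision of the parameter.  A handful of
published ranges do not follow that rule (most prominently the peritoneal
access cost, £854–£1,423 around a point of £1,233); those are stored verbatim
in the config as explicit ``low``/``high`` overrides.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np

from .states import MODALITY_ORDER, EntryClass, State, TenureBand, YearBand

__all__ = [
    "ParameterValue",
    "ScenarioSpec",
    "ModelInputs",
    "ConfigSchemaError",
    "ConfigValidationError",
    "derive_range",
    "round_half_up",
    "load_inputs",
    "default_inputs",
    "build_scenario",
    "SCENARIO_IDS",
]

SCENARIO_IDS = ("reference", "s1", "s2", "s3", "s4", "s5")

PERCENT_UNITS = "percent-per-28-days"
PROBABILITY_UNITS = "probability-per-28-days"
_COST_UNITS = ("GBP", "GBP-per-week", "GBP-per-day", "GBP-per-session")


class ConfigSchemaError(KeyError):
    """A required key is missing from the configuration document."""


class ConfigValidationError(ValueError):
    """A configuration value is present but out of range or inconsistent."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places, halves away from zero.

    Operates on the shortest decimal representation of the float, matching
    how spreadsheet-derived published tables round their displayed values.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def derive_range(point: float, factor: float = 0.25, decimals: int = 2) -> tuple[float, float]:
    """Low/high one-way sensitivity bounds as ``point × (1 ∓ factor)``.

    Bounds are rounded half-up at the printed precision ``decimals``.
    """
    if not 0 < factor < 1:
        raise ConfigValidationError(f"factor must be in (0, 1); got {factor}")
    if point < 0:
        raise ConfigValidationError(f"point must be non-negative; got {point}")
    return (
        round_half_up(point * (1 - factor), decimals),
        round_half_up(point * (1 + factor), decimals),
    )


@dataclass(frozen=True)
class ParameterValue:
    """A point estimate with low/high one-way sensitivity bounds."""

    point: float
    low: float
    high: float
    units: str = "dimensionless"
    decimals: int = 2

    def __post_init__(self) -> None:
        if not self.low <= self.point <= self.high:
            raise ConfigValidationError(
                f"require low <= point <= high; got ({self.low}, {self.point}, {self.high})"
            )
        if self.units == PROBABILITY_UNITS and not 0 <= self.low <= self.high <= 1:
            raise ConfigValidationError(
                f"28-day probability outside [0, 1]: ({self.low}, {self.high})"
            )
        if self.units == PERCENT_UNITS and not 0 <= self.low <= self.high <= 100:
            raise ConfigValidationError(
                f"percentage outside [0, 100]: ({self.low}, {self.high})"
            )
        if self.units in _COST_UNITS and self.low < 0:
            raise ConfigValidationError(f"costs must be >= 0; got low={self.low}")

    @classmethod
    def from_point(
        cls,
        point: float,
        units: str = "dimensionless",
        decimals: int = 2,
        factor: float = 0.25,
    ) -> "ParameterValue":
        low, high = derive_range(point, factor, decimals)
        return cls(point=point, low=low, high=high, units=units, decimals=decimals)

    @property
    def fraction(self) -> float:
        """Point value as a probability fraction (percent units divided by 100)."""
        return self.point / 100 if self.units == PERCENT_UNITS else self.point

    def bound_fraction(self, which: str) -> float:
        v = {"low": self.low, "point": self.point, "high": self.high}[which]
        return v / 100 if self.units == PERCENT_UNITS else v

    def with_point(self, point: float) -> "ParameterValue":
        """New value with a moved point (bounds widened if needed)."""
        return dataclasses.replace(
            self, point=point, low=min(self.low, point), high=max(self.high, point)
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "point": self.point,
            "low": self.low,
            "high": self.high,
            "units": self.units,
            "decimals": self.decimals,
        }


def _require(doc: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in doc:
        raise ConfigSchemaError(f"missing required config key: {path}.{key}" if path else
                                f"missing required config key: {key}")
    return doc[key]


def _pv(doc: Mapping[str, Any], key: str, path: str, units: str, decimals: int) -> ParameterValue:
    raw = _require(doc, key, path)
    if not isinstance(raw, Mapping):
        raise ConfigValidationError(f"{path}.{key} must be an object with a 'point' field")
    point = float(_require(raw, "point", f"{path}.{key}"))
    decimals = int(raw.get("decimals", decimals))
    units = raw.get("units", units)
    if "low" in raw or "high" in raw:
        low = float(raw.get("low", point))
        high = float(raw.get("high", point))
    else:
        low, high = derive_range(point, 0.25, decimals)
    try:
        return ParameterValue(point=point, low=low, high=high, units=units, decimals=decimals)
    except ConfigValidationError as err:
        raise ConfigValidationError(f"{path}.{key}: {err}") from None


@dataclass(frozen=True)
class Population:
    prevalent: int
    incident_per_year: int
    incident_entry_years: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.prevalent <= 0 or self.incident_per_year <= 0:
            raise ConfigValidationError("population sizes must be positive integers")


@dataclass(frozen=True)
class Mortality:
    hr_high_dose_hd: ParameterValue
    hr_home_hd: ParameterValue


@dataclass(frozen=True)
class CurveConfig:
    """Parametric survivor-function configuration for one population."""

    family: str
    anchors: tuple[tuple[float, float], ...]  # (time in years, S(t)) pairs

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "weibull", "gompertz"):
            raise ConfigValidationError(f"unknown survival family: {self.family!r}")


@dataclass(frozen=True)
class SurvivalConfig:
    dialysis: CurveConfig
    transplant: CurveConfig
    source: str = "synthetic parametric stand-in (assumption)"


@dataclass(frozen=True)
class IchdToHomeHd:
    months_0_12: ParameterValue
    months_13_18: ParameterValue
    months_19_plus: ParameterValue

    def prob(self, band: TenureBand) -> float:
        band = TenureBand(band)
        if band in (TenureBand.MONTHS_0_6, TenureBand.MONTHS_7_12):
            return self.months_0_12.fraction
        if band is TenureBand.MONTHS_13_18:
            return self.months_13_18.fraction
        return self.months_19_plus.fraction


@dataclass(frozen=True)
class BandedSwitch:
    """Duration-dependent modality switch rates (HD→PD or PD→HD pattern)."""

    months_0_6_incident: ParameterValue
    months_0_6_prevalent: ParameterValue
    months_7_12: ParameterValue
    months_13_18: ParameterValue
    months_19_plus: ParameterValue

    def prob(self, band: TenureBand, entry_class: EntryClass) -> float:
        band = TenureBand(band)
        entry_class = EntryClass(entry_class)
        if band is TenureBand.MONTHS_0_6:
            pv = (
                self.months_0_6_incident
                if entry_class is EntryClass.INCIDENT
                else self.months_0_6_prevalent
            )
            return pv.fraction
        if band is TenureBand.MONTHS_7_12:
            return self.months_7_12.fraction
        if band is TenureBand.MONTHS_13_18:
            return self.months_13_18.fraction
        return self.months_19_plus.fraction


@dataclass(frozen=True)
class Transitions:
    transplant_rate: ParameterValue
    graft_failure: ParameterValue
    ichd_to_home_hd: IchdToHomeHd
    home_hd_to_ichd: ParameterValue
    hd_to_pd: BandedSwitch
    pd_to_hd: BandedSwitch


@dataclass(frozen=True)
class Hospitalisation:
    """All-cause 28-day hospitalisation probabilities by modality and year band.

    Year-1 values come from trial data; follow-up years use year-1 × the
    follow-up ratio (0.69), rounded half-up at 2 decimals on the percent
    scale.  PD rates do not differ between the first and subsequent years.
    """

    year1: dict[str, ParameterValue]  # keys: ichd_conventional, home_hd_conventional, hd_high_dose, pd
    followup_ratio: float
    event_cost_hd: ParameterValue
    event_cost_pd: ParameterValue

    _GROUP_BY_STATE = {
        State.PD: "pd",
        State.ICHD_CONVENTIONAL: "ichd_conventional",
        State.ICHD_HIGH_DOSE: "hd_high_dose",
        State.HOME_HD_CONVENTIONAL: "home_hd_conventional",
        State.HOME_HD_HIGH_DOSE: "hd_high_dose",
    }

    def year2_plus(self, group: str) -> ParameterValue:
        """Follow-up-year probability derived from the year-1 value."""
        pv1 = self.year1[group]
        if group == "pd":
            return pv1
        point = round_half_up(pv1.point * self.followup_ratio, pv1.decimals)
        return ParameterValue.from_point(point, units=pv1.units, decimals=pv1.decimals)

    def probability(self, state: State, year_band: YearBand, which: str = "point") -> float:
        """28-day hospitalisation probability (as a fraction) for a dialysis state."""
        group = self._GROUP_BY_STATE[State(state)]
        pv = self.year1[group] if year_band is YearBand.YEAR_1 else self.year2_plus(group)
        return pv.bound_fraction(which)

    def event_cost(self, state: State) -> ParameterValue:
        return self.event_cost_pd if State(state) is State.PD else self.event_cost_hd


@dataclass(frozen=True)
class Costs:
    vascular_access: ParameterValue
    peritoneal_access: ParameterValue
    ichd_session_catheter: ParameterValue
    ichd_session_fistula: ParameterValue
    ichd_session_weighted: ParameterValue
    home_hd_weekly: ParameterValue
    apd_daily: ParameterValue
    capd_daily: ParameterValue
    esa_per_1000_units: ParameterValue
    esa_dose_hd_units_per_week: ParameterValue
    esa_dose_pd_units_per_week: ParameterValue
    monitoring_single: ParameterValue
    monitoring_multi: ParameterValue
    monitoring_visits_per_year: int
    hospitalisation_event_hd: ParameterValue
    hospitalisation_event_pd: ParameterValue
    transport_per_ichd_session: ParameterValue
    transplant_procedure: ParameterValue
    post_transplant_medication_annual: ParameterValue
    sessions_per_week_conventional: int = 3
    sessions_per_week_high_dose: int = 5

    @property
    def monitoring_weighted(self) -> float:
        """Equal-weight mean of single- and multi-professional visit tariffs."""
        return round_half_up(
            (self.monitoring_single.point + self.monitoring_multi.point) / 2, 0
        )


@dataclass(frozen=True)
class Flags:
    """Documented modelling choices exposed as switches."""

    charge_prevalent_baseline_access: bool = True
    monitor_post_transplant: bool = False
    prevalent_hospitalisation_year1: bool = False
    apd_share: float = 0.5
    per_patient_denominator: str = "years_lived"  # or "entrants"

    def __post_init__(self) -> None:
        if not 0 <= self.apd_share <= 1:
            raise ConfigValidationError(f"apd_share must be in [0, 1]; got {self.apd_share}")
        if self.per_patient_denominator not in ("years_lived", "entrants"):
            raise ConfigValidationError(
                f"per_patient_denominator must be 'years_lived' or 'entrants'; "
                f"got {self.per_patient_denominator!r}"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """A modality-mix scenario: prevalent/incident distributions and tariff."""

    id: str
    prevalent: tuple[float, ...]  # fractions over MODALITY_ORDER
    incident: tuple[float, ...]
    home_hd_high_dose_weekly_tariff: float

    def __post_init__(self) -> None:
        for name, dist in (("prevalent", self.prevalent), ("incident", self.incident)):
            if len(dist) != len(MODALITY_ORDER):
                raise ConfigValidationError(
                    f"scenario {self.id}: {name} distribution needs "
                    f"{len(MODALITY_ORDER)} entries"
                )
            if any(f < 0 for f in dist):
                raise ConfigValidationError(
                    f"scenario {self.id}: negative fraction in {name} distribution"
                )
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ConfigValidationError(
                    f"scenario {self.id}: {name} distribution sums to {sum(dist)}, not 1"
                )
        if self.home_hd_high_dose_weekly_tariff <= 0:
            raise ConfigValidationError(f"scenario {self.id}: tariff must be positive")

    @property
    def prevalent_array(self) -> np.ndarray:
        return np.asarray(self.prevalent, dtype=float)

    @property
    def incident_array(self) -> np.ndarray:
        return np.asarray(self.incident, dtype=float)

    def to_dict(self) -> dict[str, Any]:
        keys = [
            "pd",
            "ichd_conventional",
            "ichd_high_dose",
            "home_hd_conventional",
            "home_hd_high_dose",
        ]
        return {
            "prevalent_percent": {k: round(f * 100, 6) for k, f in zip(keys, self.prevalent)},
            "incident_percent": {k: round(f * 100, 6) for k, f in zip(keys, self.incident)},
            "home_hd_high_dose_weekly_tariff": self.home_hd_high_dose_weekly_tariff,
        }


@dataclass(frozen=True)
class ModelSettings:
    cycles_per_year: int = 13
    horizon_years: int = 5
    cycle_days: int = 28

    @property
    def horizon_cycles(self) -> int:
        return self.cycles_per_year * self.horizon_years


@dataclass(frozen=True)
class ModelInputs:
    """The complete, validated parameter set of the budget-impact model."""

    population: Population
    model: ModelSettings
    mortality: Mortality
    survival: SurvivalConfig
    transitions: Transitions
    hospitalisation: Hospitalisation
    costs: Costs
    flags: Flags
    scenarios: dict[str, ScenarioSpec] = field(default_factory=dict)

    # -- parameter registry -------------------------------------------------

    def iter_parameters(self) -> Iterator[tuple[str, ParameterValue]]:
        """Yield (dotted id, ParameterValue) for every swept-able parameter."""
        yield from _walk_parameters(self, "")

    def parameter(self, param_id: str) -> ParameterValue:
        for pid, pv in self.iter_parameters():
            if pid == param_id:
                return pv
        known = ", ".join(pid for pid, _ in self.iter_parameters())
        raise KeyError(f"unknown parameter id {param_id!r}; known ids: {known}")

    def with_parameter(self, param_id: str, point: float) -> "ModelInputs":
        """A copy of the inputs with one parameter's point value replaced."""
        self.parameter(param_id)  # raises on unknown id
        return _replace_parameter(self, param_id.split("."), point)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        t = self.transitions
        h = self.hospitalisation
        return {
            "population": {
                "prevalent": self.population.prevalent,
                "incident_per_year": self.population.incident_per_year,
                "incident_entry_years": list(self.population.incident_entry_years),
            },
            "model": {
                "cycles_per_year": self.model.cycles_per_year,
                "horizon_years": self.model.horizon_years,
                "cycle_days": self.model.cycle_days,
            },
            "mortality": {
                "hr_high_dose_hd": self.mortality.hr_high_dose_hd.to_dict(),
                "hr_home_hd": self.mortality.hr_home_hd.to_dict(),
            },
            "survival": {
                "dialysis": {
                    "family": self.survival.dialysis.family,
                    "anchors": {repr(t_): s for t_, s in self.survival.dialysis.anchors},
                },
                "transplant": {
                    "family": self.survival.transplant.family,
                    "anchors": {repr(t_): s for t_, s in self.survival.transplant.anchors},
                },
                "source": self.survival.source,
            },
            "transitions": {
                "transplant_rate": t.transplant_rate.to_dict(),
                "graft_failure": t.graft_failure.to_dict(),
                "ichd_to_home_hd": {
                    "months_0_12": t.ichd_to_home_hd.months_0_12.to_dict(),
                    "months_13_18": t.ichd_to_home_hd.months_13_18.to_dict(),
                    "months_19_plus": t.ichd_to_home_hd.months_19_plus.to_dict(),
                },
                "home_hd_to_ichd": t.home_hd_to_ichd.to_dict(),
                "hd_to_pd": {f.name: getattr(t.hd_to_pd, f.name).to_dict()
                             for f in dataclasses.fields(t.hd_to_pd)},
                "pd_to_hd": {f.name: getattr(t.pd_to_hd, f.name).to_dict()
                             for f in dataclasses.fields(t.pd_to_hd)},
            },
            "hospitalisation": {
                "followup_ratio": h.followup_ratio,
                "year1_percent": {k: v.to_dict() for k, v in h.year1.items()},
                "event_cost": {
                    "hd": h.event_cost_hd.to_dict(),
                    "pd": h.event_cost_pd.to_dict(),
                },
            },
            "costs": {
                **{
                    f.name: getattr(self.costs, f.name).to_dict()
                    for f in dataclasses.fields(self.costs)
                    if isinstance(getattr(self.costs, f.name), ParameterValue)
                },
                "monitoring_visits_per_year": self.costs.monitoring_visits_per_year,
                "sessions_per_week_conventional": self.costs.sessions_per_week_conventional,
                "sessions_per_week_high_dose": self.costs.sessions_per_week_high_dose,
            },
            "flags": {
                "charge_prevalent_baseline_access": self.flags.charge_prevalent_baseline_access,
                "monitor_post_transplant": self.flags.monitor_post_transplant,
                "prevalent_hospitalisation_year1": self.flags.prevalent_hospitalisation_year1,
                "apd_share": self.flags.apd_share,
                "per_patient_denominator": self.flags.per_patient_denominator,
            },
            "scenarios": {sid: sc.to_dict() for sid, sc in self.scenarios.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _walk_parameters(obj: Any, prefix: str) -> Iterator[tuple[str, ParameterValue]]:
    if isinstance(obj, ParameterValue):
        yield prefix, obj
        return
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        for f in dataclasses.fields(obj):
            if f.name in ("scenarios",):
                continue
            child = getattr(obj, f.name)
            sub = f"{prefix}.{f.name}" if prefix else f.name
            yield from _walk_parameters(child, sub)
    elif isinstance(obj, dict):
        for k, v in obj.items():
            sub = f"{prefix}.{k}" if prefix else str(k)
            yield from _walk_parameters(v, sub)


def _replace_parameter(obj: Any, path: list[str], point: float) -> Any:
    head, rest = path[0], path[1:]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        child = getattr(obj, head)
        new_child = (
            child.with_point(point) if not rest else _replace_parameter(child, rest, point)
        )
        return dataclasses.replace(obj, **{head: new_child})
    if isinstance(obj, dict):
        child = obj[head]
        new_child = (
            child.with_point(point) if not rest else _replace_parameter(child, rest, point)
        )
        new = dict(obj)
        new[head] = new_child
        return new
    raise KeyError(".".join(path))


# ---------------------------------------------------------------------------
# loading


def _parse_distribution(doc: Mapping[str, Any], path: str) -> tuple[float, ...]:
    keys = [
        "pd",
        "ichd_conventional",
        "ichd_high_dose",
        "home_hd_conventional",
        "home_hd_high_dose",
    ]
    vals = [float(_require(doc, k, path)) / 100.0 for k in keys]
    return tuple(vals)


def _parse_curve(doc: Mapping[str, Any], path: str) -> CurveConfig:
    family = str(_require(doc, "family", path))
    anchors_raw = _require(doc, "anchors", path)
    anchors = tuple(sorted((float(k), float(v)) for k, v in anchors_raw.items()))
    return CurveConfig(family=family, anchors=anchors)


def load_inputs(source: str | Path | Mapping[str, Any]) -> ModelInputs:
    """Load and validate a configuration document (path or parsed mapping).

    Raises
    ------
    ConfigSchemaError
        If a required key is absent (the message names the key).
    ConfigValidationError
        If a present value is out of range (probability bounds, negative
        costs, distributions not summing to one).
    """
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = dict(source)

    pop_doc = _require(doc, "population", "")
    population = Population(
        prevalent=int(_require(pop_doc, "prevalent", "population")),
        incident_per_year=int(_require(pop_doc, "incident_per_year", "population")),
        incident_entry_years=tuple(
            int(y) for y in _require(pop_doc, "incident_entry_years", "population")
        ),
    )

    model_doc = doc.get("model", {})
    model = ModelSettings(
        cycles_per_year=int(model_doc.get("cycles_per_year", 13)),
        horizon_years=int(model_doc.get("horizon_years", 5)),
        cycle_days=int(model_doc.get("cycle_days", 28)),
    )

    mort_doc = _require(doc, "mortality", "")
    mortality = Mortality(
        hr_high_dose_hd=_pv(mort_doc, "hr_high_dose_hd", "mortality", "dimensionless", 2),
        hr_home_hd=_pv(mort_doc, "hr_home_hd", "mortality", "dimensionless", 2),
    )
    if mortality.hr_high_dose_hd.low <= 0:
        raise ConfigValidationError("mortality.hr_high_dose_hd must be positive")

    surv_doc = _require(doc, "survival", "")
    survival = SurvivalConfig(
        dialysis=_parse_curve(_require(surv_doc, "dialysis", "survival"), "survival.dialysis"),
        transplant=_parse_curve(
            _require(surv_doc, "transplant", "survival"), "survival.transplant"
        ),
        source=surv_doc.get("source", "synthetic parametric stand-in (assumption)"),
    )

    tr_doc = _require(doc, "transitions", "")
    p = "transitions"
    ichd_home_doc = _require(tr_doc, "ichd_to_home_hd", p)
    hd_pd_doc = _require(tr_doc, "hd_to_pd", p)
    pd_hd_doc = _require(tr_doc, "pd_to_hd", p)
    transitions = Transitions(
        transplant_rate=_pv(tr_doc, "transplant_rate", p, PROBABILITY_UNITS, 3),
        graft_failure=_pv(tr_doc, "graft_failure", p, PROBABILITY_UNITS, 3),
        ichd_to_home_hd=IchdToHomeHd(
            months_0_12=_pv(ichd_home_doc, "months_0_12", f"{p}.ichd_to_home_hd", PERCENT_UNITS, 2),
            months_13_18=_pv(ichd_home_doc, "months_13_18", f"{p}.ichd_to_home_hd", PERCENT_UNITS, 2),
            months_19_plus=_pv(ichd_home_doc, "months_19_plus", f"{p}.ichd_to_home_hd", PERCENT_UNITS, 2),
        ),
        home_hd_to_ichd=_pv(tr_doc, "home_hd_to_ichd", p, PERCENT_UNITS, 2),
        hd_to_pd=BandedSwitch(
            **{
                k: _pv(hd_pd_doc, k, f"{p}.hd_to_pd", PERCENT_UNITS, 2)
                for k in (
                    "months_0_6_incident",
                    "months_0_6_prevalent",
                    "months_7_12",
                    "months_13_18",
                    "months_19_plus",
                )
            }
        ),
        pd_to_hd=BandedSwitch(
            **{
                k: _pv(pd_hd_doc, k, f"{p}.pd_to_hd", PERCENT_UNITS, 2)
                for k in (
                    "months_0_6_incident",
                    "months_0_6_prevalent",
                    "months_7_12",
                    "months_13_18",
                    "months_19_plus",
                )
            }
        ),
    )

    hosp_doc = _require(doc, "hospitalisation", "")
    y1_doc = _require(hosp_doc, "year1_percent", "hospitalisation")
    ev_doc = _require(hosp_doc, "event_cost", "hospitalisation")
    hospitalisation = Hospitalisation(
        year1={
            k: _pv(y1_doc, k, "hospitalisation.year1_percent", PERCENT_UNITS, 2)
            for k in ("ichd_conventional", "home_hd_conventional", "hd_high_dose", "pd")
        },
        followup_ratio=float(_require(hosp_doc, "followup_ratio", "hospitalisation")),
        event_cost_hd=_pv(ev_doc, "hd", "hospitalisation.event_cost", "GBP", 0),
        event_cost_pd=_pv(ev_doc, "pd", "hospitalisation.event_cost", "GBP", 0),
    )

    costs_doc = _require(doc, "costs", "")
    c = "costs"
    costs = Costs(
        vascular_access=_pv(costs_doc, "vascular_access", c, "GBP", 0),
        peritoneal_access=_pv(costs_doc, "peritoneal_access", c, "GBP", 0),
        ichd_session_catheter=_pv(costs_doc, "ichd_session_catheter", c, "GBP-per-session", 0),
        ichd_session_fistula=_pv(costs_doc, "ichd_session_fistula", c, "GBP-per-session", 0),
        ichd_session_weighted=_pv(costs_doc, "ichd_session_weighted", c, "GBP-per-session", 0),
        home_hd_weekly=_pv(costs_doc, "home_hd_weekly", c, "GBP-per-week", 0),
        apd_daily=_pv(costs_doc, "apd_daily", c, "GBP-per-day", 0),
        capd_daily=_pv(costs_doc, "capd_daily", c, "GBP-per-day", 0),
        esa_per_1000_units=_pv(costs_doc, "esa_per_1000_units", c, "GBP", 2),
        esa_dose_hd_units_per_week=_pv(costs_doc, "esa_dose_hd_units_per_week", c, "units-per-week", 0),
        esa_dose_pd_units_per_week=_pv(costs_doc, "esa_dose_pd_units_per_week", c, "units-per-week", 0),
        monitoring_single=_pv(costs_doc, "monitoring_single", c, "GBP", 0),
        monitoring_multi=_pv(costs_doc, "monitoring_multi", c, "GBP", 0),
        monitoring_visits_per_year=int(_require(costs_doc, "monitoring_visits_per_year", c)),
        hospitalisation_event_hd=_pv(costs_doc, "hospitalisation_event_hd", c, "GBP", 0),
        hospitalisation_event_pd=_pv(costs_doc, "hospitalisation_event_pd", c, "GBP", 0),
        transport_per_ichd_session=_pv(costs_doc, "transport_per_ichd_session", c, "GBP-per-session", 0),
        transplant_procedure=_pv(costs_doc, "transplant_procedure", c, "GBP", 0),
        post_transplant_medication_annual=_pv(
            costs_doc, "post_transplant_medication_annual", c, "GBP", 0
        ),
        sessions_per_week_conventional=int(costs_doc.get("sessions_per_week_conventional", 3)),
        sessions_per_week_high_dose=int(costs_doc.get("sessions_per_week_high_dose", 5)),
    )

    flags_doc = doc.get("flags", {})
    flags = Flags(
        charge_prevalent_baseline_access=bool(
            flags_doc.get("charge_prevalent_baseline_access", True)
        ),
        monitor_post_transplant=bool(flags_doc.get("monitor_post_transplant", False)),
        prevalent_hospitalisation_year1=bool(
            flags_doc.get("prevalent_hospitalisation_year1", False)
        ),
        apd_share=float(flags_doc.get("apd_share", 0.5)),
        per_patient_denominator=str(flags_doc.get("per_patient_denominator", "years_lived")),
    )

    scen_doc = _require(doc, "scenarios", "")
    scenarios: dict[str, ScenarioSpec] = {}
    for sid, s in scen_doc.items():
        scenarios[sid] = ScenarioSpec(
            id=sid,
            prevalent=_parse_distribution(
                _require(s, "prevalent_percent", f"scenarios.{sid}"), f"scenarios.{sid}.prevalent_percent"
            ),
            incident=_parse_distribution(
                _require(s, "incident_percent", f"scenarios.{sid}"), f"scenarios.{sid}.incident_percent"
            ),
            home_hd_high_dose_weekly_tariff=float(
                _require(s, "home_hd_high_dose_weekly_tariff", f"scenarios.{sid}")
            ),
        )

    return ModelInputs(
        population=population,
        model=model,
        mortality=mortality,
        survival=survival,
        transitions=transitions,
        hospitalisation=hospitalisation,
        costs=costs,
        flags=flags,
        scenarios=scenarios,
    )


def default_inputs() -> ModelInputs:
    """The packaged England NHS parameterisation."""
    with resources.files("renalbudget.data").joinpath("default_config.json").open() as fh:
        return load_inputs(json.load(fh))


def build_scenario(scenario_id: str, inputs: ModelInputs | None = None) -> ScenarioSpec:
    """Return one of the packaged modality-mix scenarios by id."""
    inputs = inputs if inputs is not None else default_inputs()
    try:
        return inputs.scenarios[scenario_id]
    except KeyError:
        valid = ", ".join(sorted(inputs.scenarios))
        raise KeyError(f"unknown scenario id {scenario_id!r}; valid ids: {valid}") from None
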