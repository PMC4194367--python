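"""Parametric survivor functions and per-cycle conditional death probabilities.

The registry survival curves the model conceptually rests on (age/gender
adjusted dialysis and transplant survivor functions) are not published at
patient level, so this module provides a configurable parametric stand-in:
exponential, Weibull or Gompertz survivor functions solved to pass through
user-supplied survival anchors (e.g. 1- and 5-year survival probabilities).

Per-cycle death probabilities are the conditional survivor ratio over one
28-day cycle, with treatment effects applied as proportional hazards:

    q(t; HR) = 1 − [S(t + Δ) / S(t)]^HR

so a hazard ratio of 0.76 for high-dose haemodialysis scales the cumulative
hazard increment of the cycle, not the probability itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import CurveConfig, SurvivalConfig
from .states import CYCLE_YEARS

__all__ = [
    "SurvivalCurve",
    "cycle_death_probability",
    "fit_to_anchors",
    "make_default_curves",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """A parametric survivor function S(t), t in years.

    Parameters by family:

    - ``exponential``: ``(rate,)`` — S(t) = exp(−rate·t)
    - ``weibull``: ``(scale, shape)`` — S(t) = exp(−(t/scale)^shape);
      shape = 1 reduces to exponential with rate 1/scale
    - ``gompertz``: ``(rate, shape)`` — hazard h(t) = rate·shape^t, i.e.
      S(t) = exp(−rate·(shape^t − 1)/ln shape); shape = 1 reduces to
      exponential with the same rate
    """

    family: str
    parameters: tuple[float, ...]
    population: str = "dialysis"

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "weibull", "gompertz"):
            raise ValueError(f"unknown survival family {self.family!r}")
        n_expected = 1 if self.family == "exponential" else 2
        if len(self.parameters) != n_expected:
            raise ValueError(
                f"{self.family} family needs {n_expected} parameter(s); "
                f"got {self.parameters}"
            )

    def survival(self, t_years: float | np.ndarray) -> float | np.ndarray:
        """S(t): probability of surviving beyond ``t_years``."""
        t = np.asarray(t_years, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        if self.family == "exponential":
            (rate,) = self.parameters
            out = np.exp(-rate * t)
        elif self.family == "weibull":
            scale, shape = self.parameters
            out = np.exp(-np.power(t / scale, shape))
        else:  # gompertz
            rate, shape = self.parameters
            if abs(shape - 1.0) < 1e-12:
                out = np.exp(-rate * t)
            else:
                out = np.exp(-rate * (np.power(shape, t) - 1.0) / math.log(shape))
        return out.item() if np.isscalar(t_years) else out

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "parameters": list(self.parameters),
            "population": self.population,
        }


def cycle_death_probability(
    curve: SurvivalCurve, tenure: int, hazard_ratio: float = 1.0
) -> float:
    """Conditional probability of dying during the (tenure+1)-th cycle.

    ``tenure`` is the number of completed 28-day cycles on the curve's
    clock; the returned probability covers the interval
    [tenure·Δ, (tenure+1)·Δ] with Δ = 28 days, under a proportional-hazards
    adjustment with the given hazard ratio.
    """
    if tenure < 0:
        raise ValueError(f"tenure must be >= 0; got {tenure}")
    if hazard_ratio <= 0:
        raise ValueError(f"hazard_ratio must be positive; got {hazard_ratio}")
    t0 = tenure * CYCLE_YEARS
    s0 = curve.survival(t0)
    if s0 <= 0.0:
        raise ValueError(
            f"survivor function is zero at t={t0:.3f} years; cohort extinct "
            "beyond curve support"
        )
    s1 = curve.survival(t0 + CYCLE_YEARS)
    q = 1.0 - (s1 / s0) ** hazard_ratio
    # guard against round-off just outside [0, 1)
    return min(max(q, 0.0), 1.0)


def _validate_anchors(anchors: tuple[tuple[float, float], ...]) -> None:
    if not anchors:
        raise ValueError("at least one survival anchor is required")
    last_t, last_s = 0.0, 1.0
    for t, s in anchors:
        if t <= 0:
            raise ValueError(f"anchor times must be positive; got {t}")
        if not 0 < s < 1:
            raise ValueError(
                f"anchor survival must lie strictly in (0, 1); got S({t}) = {s} "
                "(degenerate anchor)"
            )
        if t <= last_t or s >= last_s:
            raise ValueError("anchors must be strictly decreasing in time")
        last_t, last_s = t, s


def fit_to_anchors(
    family: str,
    anchors: tuple[tuple[float, float], ...] | dict[float, float],
    population: str = "dialysis",
) -> SurvivalCurve:
    """Solve curve parameters so S passes through the given anchors.

    ``anchors`` maps time in years to survival probability.  The exponential
    family takes exactly one anchor (closed form); Weibull and Gompertz take
    exactly two (closed form and bracketed root-find respectively).
    """
    if isinstance(anchors, dict):
        anchors = tuple(sorted(anchors.items()))
    _validate_anchors(anchors)

    if family == "exponential":
        if len(anchors) != 1:
            raise ValueError(
                "exponential family takes exactly one anchor; for two anchors "
                "use the 'weibull' or 'gompertz' family"
            )
        t1, s1 = anchors[0]
        return SurvivalCurve("exponential", (-math.log(s1) / t1,), population)

    if len(anchors) != 2:
        raise ValueError(f"{family} family takes exactly two anchors")
    (t1, s1), (t2, s2) = anchors

    if family == "weibull":
        h1, h2 = -math.log(s1), -math.log(s2)  # cumulative hazards
        shape = math.log(h2 / h1) / math.log(t2 / t1)
        if shape <= 0:
            raise ValueError(
                "anchors infeasible for the weibull family (non-increasing "
                "cumulative hazard); try the 'gompertz' family"
            )
        scale = t1 / h1 ** (1.0 / shape)
        return SurvivalCurve("weibull", (scale, shape), population)

    # gompertz: solve shape b from H(t2)/H(t1) = (b^t2 - 1)/(b^t1 - 1)
    h1, h2 = -math.log(s1), -math.log(s2)
    target = h2 / h1

    def f(b: float) -> float:
        if abs(b - 1.0) < 1e-12:
            return t2 / t1 - target
        return (b**t2 - 1.0) / (b**t1 - 1.0) - target

    lo, hi = 1e-6, 1.0 + 1e-9
    if f(lo) * f(hi) > 0:
        hi = 2.0
        while f(lo) * f(hi) > 0 and hi < 1e6:
            hi *= 2
        if f(lo) * f(hi) > 0:
            raise ValueError(
                "anchors infeasible for the gompertz family; try 'weibull'"
            )
    shape = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
    if abs(shape - 1.0) < 1e-9:
        rate = h1 / t1
    else:
        rate = h1 * math.log(shape) / (shape**t1 - 1.0)
    return SurvivalCurve("gompertz", (rate, shape), population)


def curve_from_config(cfg: CurveConfig, population: str) -> SurvivalCurve:
    return fit_to_anchors(cfg.family, cfg.anchors, population)


def make_default_curves(
    survival_config: SurvivalConfig | None = None,
) -> dict[str, SurvivalCurve]:
    """Dialysis and transplant curves from a survival configuration.

    Without an argument, returns the packaged defaults: exponential curves
    anchored at 1-year survival of 0.88 (dialysis) and 0.97 (transplant).
    These are documented assumptions standing in for unpublished registry
    parameterisations, not published values.
    """
    if survival_config is None:
        from .config import default_inputs

        survival_config = default_inputs().survival
    return {
        "dialysis": curve_from_config(survival_config.dialysis, "dialysis"),
        "transplant": curve_from_config(survival_config.transplant, "transplant"),
    }
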