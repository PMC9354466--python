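"""Parametric survival distributions shared by the simulator and the fitter.

All five families conventionally used for survival extrapolation in health
technology assessment are supported: exponential, Weibull, log-logistic,
log-normal and Gompertz.  Time is measured in months throughout.

Parameterizations (S = survival function):

=============  ==========================  =================================
family         parameters                  S(t)
=============  ==========================  =================================
exponential    rate (1/months)             exp(-rate * t)
weibull        scale, shape                exp(-(t/scale)**shape)
loglogistic    scale, shape                1 / (1 + (t/scale)**shape)
lognormal      mu, sigma (log-months)      1 - Phi((ln t - mu)/sigma)
gompertz       rate, shape (shape > 0)     exp(-rate/shape * (e**(shape*t)-1))
=============  ==========================  =================================

The Gompertz shape is restricted to positive values so that S(t) -> 0 as
t -> infinity; a negative shape would leave a plateau of immortal patients,
which is incompatible with a terminal-illness cohort model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import UnsupportedDistributionError

SUPPORTED_FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gompertz")

#: ordered parameter names per family (order used for CSV export and fitting)
PARAM_NAMES: Mapping[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("scale", "shape"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
    "gompertz": ("rate", "shape"),
}


def validate_family(family: str) -> str:
    if family not in SUPPORTED_FAMILIES:
        raise UnsupportedDistributionError(
            f"unknown distribution family {family!r}; "
            f"supported: {', '.join(SUPPORTED_FAMILIES)}"
        )
    return family


class SurvivalFunction:
    """Minimal survival-function interface: vectorized ``sf`` and ``median``."""

    def sf(self, t):  # pragma: no cover - interface
        raise NotImplementedError

    def median(self) -> float:
        """Time at which survival first reaches 0.5 (bisection fallback)."""
        lo, hi = 0.0, 1.0
        while self.sf(hi) > 0.5:
            hi *= 2.0
            if hi > 1e9:
                return math.inf
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if self.sf(mid) > 0.5:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ParametricSurvival(SurvivalFunction):
    """One of the five supported parametric families with fixed parameters."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        validate_family(self.family)
        expected = len(PARAM_NAMES[self.family])
        if len(self.params) != expected:
            raise ValueError(
                f"{self.family} takes {expected} parameter(s), got {len(self.params)}"
            )
        if any(p <= 0 for p in self.params if self.family != "lognormal") or (
            self.family == "lognormal" and self.params[1] <= 0
        ):
            raise ValueError(f"{self.family} parameters must be positive: {self.params}")

    # -- survival -----------------------------------------------------------
    def sf(self, t):
        t = np.asarray(t, dtype=float)
        f, p = self.family, self.params
        with np.errstate(divide="ignore", over="ignore"):
            if f == "exponential":
                out = np.exp(-p[0] * t)
            elif f == "weibull":
                out = np.exp(-np.power(t / p[0], p[1]))
            elif f == "loglogistic":
                out = 1.0 / (1.0 + np.power(t / p[0], p[1]))
            elif f == "lognormal":
                out = np.where(t > 0, stats.norm.sf((np.log(np.maximum(t, 1e-300)) - p[0]) / p[1]), 1.0)
            else:  # gompertz
                rate, shape = p
                out = np.exp(-rate / shape * np.expm1(shape * t))
        out = np.where(t <= 0, 1.0, out)
        return out if out.ndim else float(out)

    # -- quantiles ----------------------------------------------------------
    def ppf_survival(self, u):
        """Time t such that S(t) = u, for u in (0, 1] (comonotone sampling)."""
        u = np.asarray(u, dtype=float)
        f, p = self.family, self.params
        if f == "exponential":
            t = -np.log(u) / p[0]
        elif f == "weibull":
            t = p[0] * np.power(-np.log(u), 1.0 / p[1])
        elif f == "loglogistic":
            t = p[0] * np.power((1.0 - u) / u, 1.0 / p[1])
        elif f == "lognormal":
            t = np.exp(p[0] + p[1] * stats.norm.isf(u))
        else:  # gompertz
            rate, shape = p
            t = np.log1p(-shape / rate * np.log(u)) / shape
        return t if t.ndim else float(t)

    def median(self) -> float:
        return float(self.ppf_survival(0.5))

    def sample(self, n: int, rng: np.random.Generator):
        """Draw event times by inverse transform on the survival scale."""
        return self.ppf_survival(rng.uniform(size=n))


@dataclass(frozen=True)
class PowerSurvival(SurvivalFunction):
    """Proportional-hazards modification S(t)**hr of a base survival curve.

    Raising a survival function to the power of a hazard ratio multiplies the
    cumulative hazard by that ratio, which is exactly the proportional-hazards
    assumption used to build the experimental arm from the control-arm fit.
    """

    base: SurvivalFunction
    hr: float

    def __post_init__(self):
        if self.hr <= 0:
            raise ValueError(f"hazard ratio must be positive, got {self.hr}")

    def sf(self, t):
        return np.power(self.base.sf(t), self.hr)

    def ppf_survival(self, u):
        # S_new(t) = u  <=>  S_base(t) = u**(1/hr)
        return self.base.ppf_survival(np.power(u, 1.0 / self.hr))

    def median(self) -> float:
        return float(self.ppf_survival(0.5))


def from_median(family: str, median: float, shape: float | None = None) -> ParametricSurvival:
    """Construct a distribution from its median (convenience for scenarios).

    For two-parameter families a shape must be supplied; the scale is solved
    so that S(median) = 0.5.
    """
    validate_family(family)
    if median <= 0:
        raise ValueError("median must be positive")
    if family == "exponential":
        return ParametricSurvival("exponential", (math.log(2) / median,))
    if shape is None or shape <= 0:
        raise ValueError(f"{family} requires a positive shape")
    if family == "weibull":
        return ParametricSurvival("weibull", (median / math.log(2) ** (1 / shape), shape))
    if family == "loglogistic":
        return ParametricSurvival("loglogistic", (median, shape))
    if family == "lognormal":
        return ParametricSurvival("lognormal", (math.log(median), shape))
    # gompertz: rate solved from (rate/shape) * (e^(shape*m) - 1) = ln 2
    rate = math.log(2) * shape / math.expm1(shape * median)
    return ParametricSurvival("gompertz", (rate, shape))
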