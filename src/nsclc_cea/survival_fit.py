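"""Parametric survival fitting, model selection and transition probabilities.

The control arm's reconstructed patient-level data are fitted with the
conventional candidate set of parametric families; the best fit by AIC is
carried forward.  The experimental arm is derived from the selected control
fit by the proportional-hazards transformation S(t)**HR, and per-cycle
transition probabilities follow from the interval-conditional event
probability 1 - S(t + delta)/S(t).

Fitting is delegated to lifelines' maximum-likelihood univariate fitters
(with a custom Gompertz fitter restricted to positive shape); the
exponential family uses its closed-form MLE events / total-time directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import LogLogisticFitter, LogNormalFitter, WeibullFitter
from lifelines.exceptions import ConvergenceError
from lifelines.fitters import ParametricUnivariateFitter

from .errors import (
    AbsorbedStateError,
    EmptyInputError,
    FitFailureError,
    NoEventsError,
)
from .survival_dists import (
    PARAM_NAMES,
    ParametricSurvival,
    PowerSurvival,
    SurvivalFunction,
    validate_family,
)
from .synthetic_trial import IPDRecord

DAYS_PER_MONTH = 30.4375  # 365.25 / 12, applied uniformly
DAYS_PER_YEAR = 365.25


class _GompertzFitter(ParametricUnivariateFitter):
    """Gompertz MLE with cumulative hazard (rate/shape)(e^(shape t) - 1).

    The shape is bounded away from zero on the positive side so the induced
    survival always decays to zero (no immortal fraction).
    """

    _fitted_parameter_names = ["nu_", "b_"]
    _bounds = [(1e-9, None), (1e-6, None)]

    def _cumulative_hazard(self, params, times):
        nu, b = params
        return (nu / b) * np.expm1(b * times)


@dataclass(frozen=True)
class FittedSurvival:
    """A fitted parametric family with likelihood-based fit scores."""

    family: str
    params: tuple[float, ...]
    loglik: float
    aic: float
    bic: float
    n: int

    def __post_init__(self):
        validate_family(self.family)
        k = len(self.params)
        if not math.isclose(self.aic, 2 * k - 2 * self.loglik, rel_tol=1e-9, abs_tol=1e-8):
            raise ValueError("aic inconsistent with 2k - 2 loglik")

    @property
    def survival(self) -> ParametricSurvival:
        return ParametricSurvival(self.family, self.params)

    @property
    def n_params(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class HazardRatio:
    """Treatment effect on the hazard scale, optionally with a 95% CI."""

    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    endpoint: str = ""
    subgroup: str = "entire population"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("hazard ratio must be positive")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("supply both CI bounds or neither")
        if self.ci_low is not None and not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def fit_parametric(records: Sequence[IPDRecord], family: str) -> FittedSurvival:
    """Maximum-likelihood fit of one family under right censoring."""
    validate_family(family)
    records = list(records)
    if not records:
        raise EmptyInputError("cannot fit an empty record set")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=float)
    d = events.sum()
    if d < 1:
        raise NoEventsError("parametric fitting requires at least one event")
    n = len(records)

    if family == "exponential":
        # closed-form MLE: rate = events / total observed time
        rate = d / times.sum()
        loglik = d * math.log(rate) - rate * times.sum()
        params = (rate,)
    else:
        fitter_cls = {
            "weibull": WeibullFitter,
            "loglogistic": LogLogisticFitter,
            "lognormal": LogNormalFitter,
            "gompertz": _GompertzFitter,
        }[family]
        try:
            fitter = fitter_cls().fit(times, events)
        except (ConvergenceError, ValueError, RuntimeError) as exc:
            raise FitFailureError(f"{family} fit failed: {exc}") from exc
        # lifelines parameter order matches the canonical (scale, shape) /
        # (mu, sigma) / (rate, shape) orders used by ParametricSurvival
        params = tuple(float(fitter.params_.iloc[i]) for i in range(len(fitter.params_)))
        loglik = float(fitter.log_likelihood_)
        if not all(np.isfinite(params)) or not np.isfinite(loglik):
            raise FitFailureError(f"{family} fit produced non-finite estimates")

    k = len(params)
    return FittedSurvival(
        family=family,
        params=params,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        n=n,
    )


def fit_candidates(
    records: Sequence[IPDRecord],
    families: Sequence[str] = ("exponential", "weibull", "loglogistic", "lognormal", "gompertz"),
) -> list[FittedSurvival]:
    """Fit every candidate family, silently skipping non-converging ones
    (at least one fit must succeed)."""
    fits = []
    errors = []
    for family in families:
        try:
            fits.append(fit_parametric(records, family))
        except FitFailureError as exc:
            errors.append(str(exc))
    if not fits:
        raise FitFailureError("no candidate family converged: " + "; ".join(errors))
    return fits


def select_best_fit(fits: Sequence[FittedSurvival]) -> FittedSurvival:
    """Minimum-AIC selection; ties go to fewer parameters, then family id."""
    fits = list(fits)
    if not fits:
        raise EmptyInputError("no fits to select from")
    return min(fits, key=lambda f: (round(f.aic, 9), f.n_params, f.family))


def apply_hazard_ratio(base: FittedSurvival | SurvivalFunction, hr: HazardRatio | float) -> SurvivalFunction:
    """Proportional-hazards modification S(t)**hr of a fitted curve."""
    value = hr.value if isinstance(hr, HazardRatio) else float(hr)
    surv = base.survival if isinstance(base, FittedSurvival) else base
    if value == 1.0:
        return surv
    return PowerSurvival(surv, value)


def interval_transition_prob(S: SurvivalFunction, t: float, delta: float) -> float:
    """Probability of the event within (t, t + delta] given survival to t."""
    if delta <= 0:
        raise ValueError("cycle length must be positive")
    s_t = float(S.sf(t))
    if s_t <= 0:
        raise AbsorbedStateError(f"survival is zero at t={t}; state is absorbed")
    p = 1.0 - float(S.sf(t + delta)) / s_t
    return float(min(max(p, 0.0), 1.0))


def fits_to_frame(fits: Sequence[FittedSurvival]) -> pd.DataFrame:
    """Fit summaries in the exportable CSV layout."""
    rows = []
    for f in fits:
        rows.append(
            {
                "family": f.family,
                "param_names": ";".join(PARAM_NAMES[f.family]),
                "param_values": ";".join(f"{v:.10g}" for v in f.params),
                "loglik": f.loglik,
                "aic": f.aic,
                "bic": f.bic,
                "n": f.n,
            }
        )
    return pd.DataFrame(rows)
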