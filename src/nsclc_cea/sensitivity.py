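"""Deterministic, threshold and probabilistic sensitivity analysis.

* One-way DSA: each parameter is pushed to its low and high bound with all
  others at base, the ICER is recorded at both ends, and entries are sorted
  by descending span for the tornado diagram.  Default ranges are +/-20% of
  base; hazard ratios use their reported 95% confidence intervals.
* Threshold analysis: bisection for the parameter value at which the ICER
  crosses the willingness-to-pay threshold.
* PSA: parameters drawn jointly and independently from beta (utilities and
  probabilities), gamma (costs), lognormal (hazard ratios) or uniform
  distributions, hyperparameters set by method of moments from
  (base, low, high); each iteration re-runs both strategies and records the
  incremental cost and effect.  The cost-effectiveness acceptability curve
  is the fraction of draws with positive net monetary benefit at each WTP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DistributionSpecError, NoCrossingError
from .model import CEAModel

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DSARange:
    """Low/base/high triple for one parameter."""

    parameter: str
    low: float
    high: float
    base: float

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.parameter}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: ICER at each end of a parameter's range."""

    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one parameter in the PSA."""

    parameter: str
    family: str  # beta | gamma | lognormal | uniform
    hyperparams: tuple[float, ...]

    def __post_init__(self):
        if self.family not in ("beta", "gamma", "lognormal", "uniform", "degenerate"):
            raise ValueError(f"unknown PSA distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float:
        h = self.hyperparams
        if self.family == "beta":
            return float(rng.beta(h[0], h[1]))
        if self.family == "gamma":
            return float(rng.gamma(h[0], h[1]))  # shape, scale
        if self.family == "lognormal":
            return float(rng.lognormal(h[0], h[1]))
        if self.family == "uniform":
            return float(rng.uniform(h[0], h[1]))
        return float(h[0])  # degenerate

    @classmethod
    def from_range(cls, parameter: str, family: str, base: float, low: float, high: float
                   ) -> "ParameterDistribution":
        """Method-of-moments hyperparameters from a (base, low, high) triple.

        The range is read as an approximate 95% interval, so the standard
        deviation is (high - low) / (2 * 1.96); lognormal parameters come
        from the interval on the log scale (the HR confidence-interval
        convention).
        """
        if high < low:
            raise ValueError("high < low")
        if high == low:
            return cls(parameter, "degenerate", (base,))
        if family == "uniform":
            return cls(parameter, "uniform", (low, high))
        if family == "lognormal":
            if min(base, low, high) <= 0:
                raise ValueError("lognormal requires positive bounds")
            sigma = (math.log(high) - math.log(low)) / (2 * _Z95)
            return cls(parameter, "lognormal", (math.log(base), sigma))
        sd = (high - low) / (2 * _Z95)
        var = sd * sd
        if family == "beta":
            if not 0.0 < base < 1.0:
                raise ValueError("beta requires base in (0, 1)")
            nu = base * (1 - base) / var - 1.0
            if nu <= 0:
                raise ValueError("beta variance too large for its mean")
            return cls(parameter, "beta", (base * nu, (1 - base) * nu))
        if family == "gamma":
            if base <= 0:
                raise ValueError("gamma requires positive base")
            return cls(parameter, "gamma", (base * base / var, var / base))
        raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class PSAResult:
    """Paired incremental (cost, QALY) draws from the PSA."""

    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    seed: int
    n_iterations: int

    def __post_init__(self):
        if len(self.delta_cost) != self.n_iterations or len(self.delta_qalys) != self.n_iterations:
            raise ValueError("draw arrays must match n_iterations")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iter": np.arange(self.n_iterations),
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
            }
        )


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------

def default_ranges(
    model: CEAModel,
    rel: float = 0.20,
    hr_cis: Mapping[str, tuple[float, float]] | None = None,
    exclude: Sequence[str] = ("discount_annual",),
) -> list[DSARange]:
    """+/-20% ranges around every base parameter (HRs use CIs when given).

    Probabilities are capped at 1; the discount rate is excluded by default
    (it is usually varied as a scenario, 0-8%, not a tornado bar).
    """
    ranges = []
    for name, base in model.base_params.items():
        if name in exclude:
            continue
        if hr_cis and name in hr_cis:
            lo, hi = hr_cis[name]
            lo, hi = min(lo, base), max(hi, base)
        else:
            lo, hi = base * (1 - rel), base * (1 + rel)
            if name.startswith(("u_", "p_subsequent", "ae_disc")):
                hi = min(hi, 1.0)
        ranges.append(DSARange(name, lo, hi, base))
    return ranges


def _icer_for_tornado(model: CEAModel, overrides: Mapping[str, float]) -> float:
    """ICER with dominance mapped to signed infinities for bar plotting."""
    pair = model.evaluate(overrides)
    comp = pair.comparison
    if comp.icer is not None:
        return comp.icer
    return -math.inf if comp.cost_effective else math.inf


def one_way_dsa(model: CEAModel, ranges: Iterable[DSARange]) -> list[TornadoEntry]:
    """Re-evaluate the ICER at each parameter's bounds, sorted by span."""
    ranges = list(ranges)
    for r in ranges:
        if r.parameter not in model.base_params:
            raise ConfigError(f"unknown parameter id: {r.parameter}")
    entries = [
        TornadoEntry(
            r.parameter,
            _icer_for_tornado(model, {r.parameter: r.low}),
            _icer_for_tornado(model, {r.parameter: r.high}),
        )
        for r in ranges
    ]
    entries.sort(key=lambda e: -e.span)
    return entries


def tornado_to_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "span": e.span,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# threshold analysis
# ---------------------------------------------------------------------------

def threshold_search(
    model: CEAModel,
    parameter: str,
    wtp: float,
    bracket: tuple[float, float],
    rel_tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Bisection for the parameter value at which ICER(parameter) = wtp.

    Returns ``(value, icer_at_value)``.  Raises :class:`NoCrossingError`
    when the ICER minus WTP does not change sign over the bracket.
    """
    if parameter not in model.base_params:
        raise ConfigError(f"unknown parameter id: {parameter}")
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")

    def g(x: float) -> float:
        return _icer_for_tornado(model, {parameter: x}) - wtp

    # the ICER need not be monotone over the whole bracket (it diverges
    # where the incremental effect crosses zero), so locate the first
    # finite sign change on a coarse scan before bisecting
    grid = np.linspace(lo, hi, 33)
    values = [g(x) for x in grid]
    seg = None
    for (xa, ga), (xb, gb) in zip(zip(grid, values), zip(grid[1:], values[1:])):
        if np.isfinite(ga) and np.isfinite(gb) and ga * gb <= 0:
            seg = (xa, xb, ga, gb)
            break
    if seg is None:
        raise NoCrossingError(
            f"no ICER = {wtp:g} crossing for {parameter} in [{lo:g}, {hi:g}]"
        )
    lo, hi, g_lo, g_hi = seg
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        if g_mid == 0.0 or (hi - lo) <= rel_tol * max(1.0, abs(mid)):
            break
        if g_lo * g_mid <= 0:
            hi = mid
        else:
            lo, g_lo = mid, g_mid
    value = float(0.5 * (lo + hi))
    return value, float(_icer_for_tornado(model, {parameter: value}))


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def default_distributions(
    model: CEAModel,
    ranges: Iterable[DSARange] | None = None,
    hr_cis: Mapping[str, tuple[float, float]] | None = None,
) -> list[ParameterDistribution]:
    """Conventional distribution assignment by parameter domain.

    Beta for utilities and probabilities, gamma for costs, lognormal for
    hazard ratios; fixed (degenerate) whenever the base is on the boundary
    of its domain.
    """
    ranges = list(ranges) if ranges is not None else default_ranges(model, hr_cis=hr_cis)
    dists = []
    for r in ranges:
        name, base = r.parameter, r.base
        if name.startswith("hr_"):
            family = "lognormal"
        elif name.startswith(("u_", "p_subsequent", "ae_disc")):
            family = "beta"
        else:
            family = "gamma"
        if r.low == r.high or base == 0 or (family == "beta" and not 0 < base < 1):
            dists.append(ParameterDistribution(name, "degenerate", (base,)))
        else:
            dists.append(ParameterDistribution.from_range(name, family, base, r.low, r.high))
    return dists


#: domain validators used to reject invalid PSA draws before model entry
_PARAM_DOMAIN = {
    "u_": lambda v: 0.0 <= v <= 1.0,
    "p_subsequent": lambda v: 0.0 <= v <= 1.0,
    "ae_disc": lambda v: 0.0 <= v < 1.0,
    "hr_": lambda v: v > 0.0,
    "discount_annual": lambda v: 0.0 <= v < 1.0,
}


def _valid_draw(name: str, value: float) -> bool:
    for prefix, check in _PARAM_DOMAIN.items():
        if name.startswith(prefix):
            return check(value)
    return value >= 0.0  # costs and burdens


def run_psa(
    model: CEAModel,
    dists: Sequence[ParameterDistribution],
    n: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo PSA: sample all parameters jointly, re-run, record deltas.

    One master seed spawns an independent substream per iteration, so
    results are reproducible and insensitive to iteration count changes
    upstream of the requested ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for d in dists:
        if d.parameter not in model.base_params:
            raise ConfigError(f"unknown parameter id: {d.parameter}")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n)
    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        overrides = {}
        for dist in dists:
            for _attempt in range(101):
                value = dist.sample(rng)
                if _valid_draw(dist.parameter, value):
                    break
            else:
                raise DistributionSpecError(
                    f"{dist.parameter}: >100 invalid draws from {dist.family}"
                )
            overrides[dist.parameter] = value
        pair = model.evaluate(overrides)
        d_cost[i] = pair.comparison.delta_cost
        d_qaly[i] = pair.comparison.delta_qalys
    return PSAResult(d_cost, d_qaly, seed=seed, n_iterations=n)


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Probability of positive net monetary benefit at each WTP value."""
    if result.n_iterations == 0:
        raise ValueError("empty PSA result")
    points = []
    for wtp in wtp_grid:
        nmb = wtp * result.delta_qalys - result.delta_cost
        points.append(CEACPoint(float(wtp), float(np.mean(nmb > 0))))
    return points


def ceac_to_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame({"wtp": [p.wtp for p in points],
                         "probability": [p.probability for p in points]})
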