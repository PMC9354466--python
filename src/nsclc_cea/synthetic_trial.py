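"""Synthetic two-arm trial generator with known ground truth.

The published trial's raw data are unavailable, so every downstream stage
(reconstruction, fitting, Markov modelling, economics, sensitivity analysis)
is exercised against simulated cohorts whose survival distributions, hazard
ratios and censoring pattern are known exactly.  The module also emulates the
"digitization" step of reading coordinates off a published Kaplan-Meier plot,
including probability-scale noise and a number-at-risk table.

Joint PFS/OS dependence: progression-free and overall survival times are
drawn comonotonically (one uniform per subject mapped through both quantile
functions).  This preserves both specified marginals exactly while
guaranteeing PFS <= OS whenever OS stochastically dominates PFS, which every
sensible oncology scenario satisfies; residual violations (non-ordered
family pairs) are repaired by clamping OS up to PFS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .survival_dists import ParametricSurvival, validate_family

ENDPOINTS = ("PFS", "OS")

IPD_COLUMNS = ["arm", "endpoint", "time_months", "event"]


@dataclass(frozen=True)
class ArmSpec:
    """Ground-truth survival specification for one trial arm."""

    name: str
    pfs_family: str
    pfs_params: tuple[float, ...]
    os_family: str
    os_params: tuple[float, ...]
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("arm size must be >= 1")
        validate_family(self.pfs_family)
        validate_family(self.os_family)

    @property
    def pfs(self) -> ParametricSurvival:
        return ParametricSurvival(self.pfs_family, tuple(self.pfs_params))

    @property
    def os(self) -> ParametricSurvival:
        return ParametricSurvival(self.os_family, tuple(self.os_params))


@dataclass(frozen=True)
class TrialSpec:
    """A two-arm trial with administrative censoring and random dropout."""

    arms: tuple[ArmSpec, ArmSpec]
    censor_time: float = 30.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.arms) != 2:
            raise ValueError("a trial has exactly two arms")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")


@dataclass(frozen=True)
class IPDRecord:
    """One subject's (time, event) observation for a single endpoint."""

    arm: str
    endpoint: str
    time: float
    event: int

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("observation time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass(frozen=True)
class KMCurve:
    """Digitized Kaplan-Meier coordinates for one arm/endpoint."""

    coords: tuple[tuple[float, float], ...]
    endpoint: str = ""
    arm: str = ""

    def __post_init__(self):
        if not self.coords:
            raise ValueError("curve needs at least one coordinate")
        t0, s0 = self.coords[0]
        if not (t0 == 0.0 and abs(s0 - 1.0) < 1e-12):
            raise ValueError("curve must start at (0, 1)")
        times = [c[0] for c in self.coords]
        survs = [c[1] for c in self.coords]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("curve times must be strictly increasing")
        if any(s < -1e-12 or s > 1 + 1e-12 for s in survs):
            raise ValueError("survival values must lie in [0, 1]")
        if any(b > a + 1e-12 for a, b in zip(survs, survs[1:])):
            raise ValueError("survival must be non-increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([c[0] for c in self.coords])

    @property
    def survival(self) -> np.ndarray:
        return np.array([c[1] for c in self.coords])


@dataclass(frozen=True)
class RiskTable:
    """Number-at-risk table accompanying a published KM plot."""

    times: tuple[float, ...]
    n_at_risk: tuple[int, ...]

    def __post_init__(self):
        if len(self.times) != len(self.n_at_risk):
            raise ValueError("times and n_at_risk must have the same length")
        if any(n < 0 for n in self.n_at_risk):
            raise ValueError("number at risk cannot be negative")
        if any(later > earlier for earlier, later in zip(self.n_at_risk, self.n_at_risk[1:])):
            raise ValueError("number at risk must be non-increasing")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("risk-table times must be strictly increasing")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_ipd(spec: TrialSpec) -> list[IPDRecord]:
    """Simulate individual patient data for both arms and both endpoints.

    Observed time = min(latent event time, dropout time, administrative
    censor time); event = 1 iff the latent time is the minimum.  The same
    dropout/censor times apply to a subject's PFS and OS observations.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[IPDRecord] = []
    for arm in spec.arms:
        u = rng.uniform(size=arm.n)
        pfs_latent = arm.pfs.ppf_survival(u)
        os_latent = np.maximum(arm.os.ppf_survival(u), pfs_latent)
        if spec.dropout_rate > 0:
            dropout = rng.exponential(1.0 / spec.dropout_rate, size=arm.n)
        else:
            dropout = np.full(arm.n, np.inf)
        censor = np.minimum(dropout, spec.censor_time)
        for endpoint, latent in (("PFS", pfs_latent), ("OS", os_latent)):
            time = np.minimum(latent, censor)
            event = (latent <= censor).astype(int)
            records.extend(
                IPDRecord(arm.name, endpoint, float(max(t, 1e-9)), int(e))
                for t, e in zip(time, event)
            )
    return records


def records_to_frame(records: Iterable[IPDRecord]) -> pd.DataFrame:
    """IPD records as a DataFrame in the package's CSV dialect."""
    return pd.DataFrame(
        [(r.arm, r.endpoint, r.time, r.event) for r in records],
        columns=IPD_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[IPDRecord]:
    return [
        IPDRecord(str(r.arm), str(r.endpoint), float(r.time_months), int(r.event))
        for r in frame.itertuples()
    ]


def filter_records(
    records: Iterable[IPDRecord], arm: str | None = None, endpoint: str | None = None
) -> list[IPDRecord]:
    return [
        r
        for r in records
        if (arm is None or r.arm == arm) and (endpoint is None or r.endpoint == endpoint)
    ]


# ---------------------------------------------------------------------------
# digitization
# ---------------------------------------------------------------------------

def digitize_km(
    records: Sequence[IPDRecord],
    grid: Sequence[float],
    jitter: float = 0.005,
    seed: int | None = None,
    risk_times: Sequence[float] | None = None,
) -> tuple[KMCurve, RiskTable]:
    """Emulate reading a published KM curve off a figure.

    The exact product-limit estimator is evaluated at ``grid`` points,
    truncated Gaussian noise of standard deviation ``jitter`` is added on the
    probability scale, and the result is re-monotonized (cumulative minimum)
    so it remains a valid survival curve.  The risk table counts subjects
    still under observation at each boundary in ``risk_times`` (default: the
    grid itself).
    """
    records = list(records)
    if not records:
        raise EmptyInputError("cannot digitize an empty record set")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    from .km_reconstruct import km_estimator  # local import to avoid a cycle

    km = km_estimator(records)
    grid = np.asarray(sorted(set(float(g) for g in grid)))
    if grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
    surv = _step_eval(km.times, km.survival, grid)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noisy = surv + rng.normal(0.0, jitter, size=surv.shape)
        noisy = np.clip(noisy, 0.0, 1.0)
        noisy[0] = 1.0
        surv = np.minimum.accumulate(noisy)
    arm = records[0].arm
    endpoint = records[0].endpoint
    curve = KMCurve(tuple(zip(grid.tolist(), surv.tolist())), endpoint=endpoint, arm=arm)

    boundaries = np.asarray(risk_times if risk_times is not None else grid, dtype=float)
    obs_times = np.array([r.time for r in records])
    n_at_risk = tuple(int((obs_times >= b).sum()) for b in boundaries)
    return curve, RiskTable(tuple(boundaries.tolist()), n_at_risk)


def _step_eval(times: np.ndarray, survival: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Right-continuous step-function evaluation of a KM curve."""
    idx = np.searchsorted(times, at, side="right") - 1
    idx = np.clip(idx, 0, len(times) - 1)
    return survival[idx]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_ipd_csv(records: Iterable[IPDRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_ipd_csv(path) -> list[IPDRecord]:
    return frame_to_records(pd.read_csv(path))


def write_km_csv(curve: KMCurve, path) -> None:
    pd.DataFrame(curve.coords, columns=["time_months", "survival"]).to_csv(path, index=False)


def read_km_csv(path, endpoint: str = "", arm: str = "") -> KMCurve:
    df = pd.read_csv(path)
    return KMCurve(
        tuple(zip(df["time_months"].astype(float), df["survival"].astype(float))),
        endpoint=endpoint,
        arm=arm,
    )


def write_risk_csv(risk: RiskTable, path) -> None:
    pd.DataFrame({"time_months": risk.times, "n_at_risk": risk.n_at_risk}).to_csv(
        path, index=False
    )


def read_risk_csv(path) -> RiskTable:
    df = pd.read_csv(path)
    return RiskTable(
        tuple(df["time_months"].astype(float)), tuple(df["n_at_risk"].astype(int))
    )
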