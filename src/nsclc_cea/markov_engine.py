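"""Four-state cohort Markov model over 21-day cycles.

States: PFS on treatment, PFS off treatment after adverse-event (AE)
discontinuation, progressive disease (PD), and death.  The AE state is a
"temporary" PFS state: patients keep PFS transitions and utility but stop
accruing drug-acquisition costs, and never restart treatment.

Transition construction anchors the cohort's all-cause survival to the
fitted overall-survival curve: each alive state's per-cycle death
probability equals the interval-conditional OS event probability
1 - S_os(t + d)/S_os(t), so 1 - death occupancy reproduces S_os exactly at
every cycle boundary.  Progression claims the remainder of the PFS exit
probability after death takes its OS-implied share (floored at zero when
the digitized curves cross).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InconsistentCurvesError
from .survival_dists import SurvivalFunction
from .survival_fit import DAYS_PER_MONTH, DAYS_PER_YEAR

STATES = ("PFS_ON", "PFS_OFF_AE", "PD", "DEATH")
PFS_ON, PFS_OFF_AE, PD, DEATH = range(4)


@dataclass(frozen=True)
class StateSpace:
    """Ordered health-state labels; DEATH is absorbing."""

    states: tuple[str, ...] = STATES


@dataclass(frozen=True)
class CycleSettings:
    """Cycle length, horizon and half-cycle correction flag."""

    cycle_days: float = 21.0
    horizon_years: float = 20.0
    half_cycle_correction: bool = True

    def __post_init__(self):
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")

    @property
    def n_cycles(self) -> int:
        return int(math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_days))

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle row-stochastic 4x4 transition matrices."""

    matrices: np.ndarray  # (n_cycles, 4, 4)

    def __post_init__(self):
        m = self.matrices
        if m.ndim != 3 or m.shape[1:] != (4, 4):
            raise ValueError("matrices must have shape (n_cycles, 4, 4)")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(m[:, DEATH, :], np.eye(4)[DEATH], atol=1e-12):
            raise ValueError("DEATH must be absorbing")

    @property
    def n_cycles(self) -> int:
        return self.matrices.shape[0]


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy over time plus per-cycle entrants into PD and death.

    ``occupancy`` has ``n_cycles + 1`` rows: row k is the distribution at
    the start of cycle k (time k * cycle_days).
    """

    occupancy: np.ndarray  # (n_cycles + 1, 4)
    entrants_pd: np.ndarray  # (n_cycles,)
    entrants_death: np.ndarray  # (n_cycles,)

    def __post_init__(self):
        occ = self.occupancy
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("occupancy rows must sum to 1")
        if np.any(np.diff(occ[:, DEATH]) < -1e-12):
            raise ValueError("DEATH occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEATH]

    def to_frame(self, settings: CycleSettings) -> pd.DataFrame:
        cycles = np.arange(self.occupancy.shape[0])
        return pd.DataFrame(
            {
                "cycle": cycles,
                "time_days": cycles * settings.cycle_days,
                "pfs_on": self.occupancy[:, PFS_ON],
                "pfs_off_ae": self.occupancy[:, PFS_OFF_AE],
                "pd": self.occupancy[:, PD],
                "death": self.occupancy[:, DEATH],
            }
        )


def build_transition_schedule(
    pfs: SurvivalFunction,
    os: SurvivalFunction,
    ae_disc: float,
    settings: CycleSettings,
) -> TransitionSchedule:
    """Derive per-cycle transition matrices from PFS and OS curves.

    ``ae_disc`` is the constant per-cycle probability that a surviving,
    non-progressing patient on treatment discontinues due to adverse events.
    """
    n = settings.n_cycles
    t = np.arange(n + 1) * settings.cycle_months
    s_os = np.asarray(os.sf(t), dtype=float)
    s_pfs = np.asarray(pfs.sf(t), dtype=float)
    return schedule_from_arrays(s_pfs, s_os, ae_disc)


def schedule_from_arrays(
    s_pfs: np.ndarray, s_os: np.ndarray, ae_disc: float, strict: bool = True
) -> TransitionSchedule:
    """Schedule from survival values tabulated at the cycle boundaries.

    ``s_pfs`` and ``s_os`` have length n_cycles + 1 (element k is survival
    at the start of cycle k).  Exposed separately so that repeated
    re-evaluations (probabilistic sensitivity analysis) can reuse tabulated
    base curves and apply hazard-ratio powers as cheap array operations.

    ``strict=False`` clips any PFS > OS crossing instead of raising; this
    is required when independently varied hazard ratios make the curves
    cross structurally (e.g. a large OS hazard ratio in the DSA/PSA), in
    which case death simply claims the whole PFS exit probability.
    """
    if not 0.0 <= ae_disc < 1.0:
        raise ValueError("ae_disc must lie in [0, 1)")
    if strict and np.any(s_pfs > s_os + 1e-6):
        raise InconsistentCurvesError("PFS survival exceeds OS survival beyond tolerance")
    s_pfs = np.minimum(s_pfs, s_os)  # clip residual sub-tolerance crossings
    n = len(s_os) - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        q_os = 1.0 - np.where(s_os[:-1] > 0, s_os[1:] / s_os[:-1], 0.0)
        q_pfs = 1.0 - np.where(s_pfs[:-1] > 0, s_pfs[1:] / s_pfs[:-1], 0.0)
    q_os = np.where(s_os[:-1] > 0, q_os, 1.0)
    q_pfs = np.where(s_pfs[:-1] > 0, q_pfs, 1.0)
    q_os = np.clip(q_os, 0.0, 1.0)
    q_pfs = np.clip(q_pfs, 0.0, 1.0)
    p_pd = np.clip(q_pfs - q_os, 0.0, 1.0 - q_os)
    stay_pfs = 1.0 - q_os - p_pd

    m = np.zeros((n, 4, 4))
    m[:, PFS_ON, DEATH] = q_os
    m[:, PFS_ON, PD] = p_pd
    m[:, PFS_ON, PFS_OFF_AE] = stay_pfs * ae_disc
    m[:, PFS_ON, PFS_ON] = stay_pfs * (1.0 - ae_disc)
    m[:, PFS_OFF_AE, DEATH] = q_os
    m[:, PFS_OFF_AE, PD] = p_pd
    m[:, PFS_OFF_AE, PFS_OFF_AE] = stay_pfs
    m[:, PD, DEATH] = q_os
    m[:, PD, PD] = 1.0 - q_os
    m[:, DEATH, DEATH] = 1.0
    return TransitionSchedule(m)


def run_cohort(
    schedule: TransitionSchedule,
    settings: CycleSettings | None = None,
    initial: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate the cohort through the schedule from 100% PFS on treatment."""
    n = schedule.n_cycles
    if settings is not None and settings.n_cycles != n:
        raise ValueError(
            f"schedule has {n} cycles but settings imply {settings.n_cycles}"
        )
    occ = np.zeros((n + 1, 4))
    occ[0] = np.array([1.0, 0.0, 0.0, 0.0]) if initial is None else np.asarray(initial, float)
    entrants_pd = np.zeros(n)
    entrants_death = np.zeros(n)
    for k in range(n):
        mk = schedule.matrices[k]
        occ[k + 1] = occ[k] @ mk
        entrants_pd[k] = occ[k, PFS_ON] * mk[PFS_ON, PD] + occ[k, PFS_OFF_AE] * mk[PFS_OFF_AE, PD]
        entrants_death[k] = occ[k + 1, DEATH] - occ[k, DEATH]
    return CohortTrace(occ, entrants_pd, entrants_death)


def per_cycle_from_cumulative(cumulative: float, n_cycles: int) -> float:
    """Constant per-cycle probability reproducing a cumulative proportion.

    Used to calibrate the AE-discontinuation probability from a reported
    cumulative discontinuation fraction over a treatment duration.
    """
    if not 0.0 <= cumulative < 1.0:
        raise ValueError("cumulative proportion must lie in [0, 1)")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    return 1.0 - (1.0 - cumulative) ** (1.0 / n_cycles)
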