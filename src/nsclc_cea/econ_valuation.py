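"""Costs, utilities, discounting, and incremental cost-effectiveness.

All monetary values are 2021 US dollars from the Chinese healthcare-system
perspective.  Costs and QALYs are discounted at 5% per year by default, per
the Chinese pharmacoeconomic guidelines, with the discount factor evaluated
at each cycle's start time.

Cost categories follow the usual layout of a first-line oncology model:

* drug acquisition (vial-rounded doses by body surface area or the Calvert
  formula) plus premedication, accruing in the on-treatment PFS state only
  and respecting per-drug maximum cycle counts (e.g. platinum induction);
* adverse-event management, a frequency-weighted one-off burden charged in
  the first cycle (the same weighted-sum algorithm supplies the one-off
  AE disutility on the QALY side);
* routine follow-up and best supportive care for all alive states;
* subsequent anticancer therapy for the progressed state, scaled by the
  proportion of progressed patients who receive it;
* a one-time end-of-life cost on entry into death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .markov_engine import DEATH, PD, PFS_OFF_AE, PFS_ON, CohortTrace, CycleSettings
from .survival_fit import DAYS_PER_YEAR

DEFAULT_WTP = 35_663.0  # 3x China's 2021 per-capita GDP, USD/QALY


@dataclass(frozen=True)
class DrugComponent:
    """One drug in a regimen with its dosing rule and unit price."""

    name: str
    dose_rule: str  # per_m2 | flat | calvert_auc
    dose: float  # mg/m2, mg, or AUC target respectively
    unit_size: float  # mg per vial/unit
    unit_price: float  # USD per unit
    max_cycles: int | None = None  # None = until leaving PFS_ON

    def __post_init__(self):
        if self.dose_rule not in ("per_m2", "flat", "calvert_auc"):
            raise ValueError(f"unknown dose rule {self.dose_rule!r}")
        if self.dose < 0 or self.unit_price < 0 or self.unit_size <= 0:
            raise ValueError("doses and prices must be non-negative, unit size positive")


@dataclass(frozen=True)
class RegimenSpec:
    """A treatment arm's drug regimen and the dosing covariates."""

    components: tuple[DrugComponent, ...]
    premedication_per_cycle: float = 0.0
    bsa: float = 1.72  # mean body surface area, m^2
    crcl: float = 70.0  # mean creatinine clearance, ml/min
    vial_rounding: bool = True

    def __post_init__(self):
        if self.bsa <= 0 or self.crcl <= 0 or self.premedication_per_cycle < 0:
            raise ValueError("bsa/crcl must be positive, premedication >= 0")


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities and per-arm AE disutility tables."""

    u_pfs: float = 0.856
    u_pd: float = 0.768
    ae_disutilities: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=dict
    )  # arm -> ((frequency, disutility), ...)

    def __post_init__(self):
        for u in (self.u_pfs, self.u_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utilities must lie in [0, 1], got {u}")
        for arm, pairs in self.ae_disutilities.items():
            for freq, _ in pairs:
                if not 0.0 <= freq <= 1.0:
                    raise ValueError(f"AE frequency out of [0, 1] for arm {arm}")


@dataclass(frozen=True)
class CostInputs:
    """All cost parameters for both strategies."""

    regimens: Mapping[str, RegimenSpec]  # arm -> regimen
    ae_costs: Mapping[str, tuple[tuple[float, float], ...]] = field(default_factory=dict)
    followup_per_cycle: float = 0.0
    bsc_per_cycle: float = 0.0
    subsequent_therapy_per_cycle: float = 0.0
    p_subsequent: Mapping[str, float] = field(default_factory=dict)  # arm -> proportion
    end_of_life_onetime: float = 0.0
    discount_annual: float = 0.05
    currency: str = "2021 USD"

    def __post_init__(self):
        for v in (
            self.followup_per_cycle,
            self.bsc_per_cycle,
            self.subsequent_therapy_per_cycle,
            self.end_of_life_onetime,
        ):
            if v < 0:
                raise ValueError("monetary values must be >= 0")
        for arm, p in self.p_subsequent.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_subsequent for {arm} must lie in [0, 1]")
        if not 0.0 <= self.discount_annual < 1.0:
            raise ValueError("annual discount rate must lie in [0, 1)")


class Dominance(Enum):
    NONE = "none"
    DOMINANT = "dominant"  # comparator a is cheaper and more effective
    DOMINATED = "dominated"  # comparator a is costlier and less effective


@dataclass(frozen=True)
class EconomicResult:
    """Discounted totals and per-cycle category ledgers for one strategy."""

    arm: str
    total_cost: float
    total_qalys: float
    total_life_years: float
    cost_ledger: Mapping[str, np.ndarray]
    qaly_ledger: Mapping[str, np.ndarray]

    def __post_init__(self):
        ledger_cost = sum(float(v.sum()) for v in self.cost_ledger.values())
        ledger_qaly = sum(float(v.sum()) for v in self.qaly_ledger.values())
        if not math.isclose(ledger_cost, self.total_cost, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("cost ledger does not sum to total")
        if not math.isclose(ledger_qaly, self.total_qalys, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("QALY ledger does not sum to total")


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental comparison of strategy a versus comparator b."""

    arm_a: str
    arm_b: str
    delta_cost: float
    delta_qalys: float
    icer: float | None
    dominance: Dominance
    wtp: float
    cost_effective: bool


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def component_dose_mg(comp: DrugComponent, bsa: float, crcl: float) -> float:
    """Administered dose in mg under the component's dosing rule."""
    if comp.dose_rule == "flat":
        return comp.dose
    if comp.dose_rule == "per_m2":
        return comp.dose * bsa
    # Calvert formula: dose (mg) = target AUC x (creatinine clearance + 25)
    return comp.dose * (crcl + 25.0)


def cycle_drug_cost(regimen: RegimenSpec, cycle: int = 0) -> float:
    """Drug-acquisition cost of one cycle, with vial rounding by default.

    Components whose ``max_cycles`` cap has been reached contribute nothing
    from that cycle on (cycle indices are 0-based).
    """
    total = regimen.premedication_per_cycle
    for comp in regimen.components:
        if comp.max_cycles is not None and cycle >= comp.max_cycles:
            continue
        dose = component_dose_mg(comp, regimen.bsa, regimen.crcl)
        if regimen.vial_rounding:
            units = math.ceil(dose / comp.unit_size - 1e-12)
        else:
            units = dose / comp.unit_size
        total += units * comp.unit_price
    return total


def ae_burden(pairs: Iterable[tuple[float, float]]) -> float:
    """Frequency-weighted sum of per-adverse-event values (cost or disutility)."""
    total = 0.0
    for freq, value in pairs:
        if not 0.0 <= freq <= 1.0:
            raise ValueError("AE frequencies must lie in [0, 1]")
        total += freq * value
    return total


def discount_factor(cycle_index: int, settings: CycleSettings, annual_rate: float) -> float:
    """(1 + r)^(-k * cycle_days / 365.25), the factor at cycle k's start."""
    if cycle_index < 0:
        raise ValueError("cycle index must be >= 0")
    years = cycle_index * settings.cycle_days / DAYS_PER_YEAR
    return float((1.0 + annual_rate) ** (-years))


def _discount_vector(n: int, settings: CycleSettings, rate: float) -> np.ndarray:
    years = np.arange(n) * settings.cycle_days / DAYS_PER_YEAR
    return (1.0 + rate) ** (-years)


def relative_price_reduction(new_price: float, reference_price: float) -> float:
    """Percent reduction of ``new_price`` relative to ``reference_price``."""
    if reference_price <= 0:
        raise ValueError("reference price must be positive")
    return 100.0 * (1.0 - new_price / reference_price)


# ---------------------------------------------------------------------------
# strategy valuation
# ---------------------------------------------------------------------------

def evaluate_strategy(
    trace: CohortTrace,
    costs: CostInputs,
    utils: UtilityInputs,
    settings: CycleSettings,
    arm: str,
) -> EconomicResult:
    """Attach costs and utilities to a cohort trace and accumulate totals.

    With half-cycle correction on, state-occupancy rewards are valued at
    cycle midpoints (average of adjacent occupancy rows); one-off rewards
    (AE burden, end-of-life cost) are not half-cycle corrected.
    """
    n = trace.n_cycles
    if settings.n_cycles != n:
        raise ValueError(f"trace has {n} cycles but settings imply {settings.n_cycles}")
    regimen = costs.regimens[arm]

    occ = trace.occupancy
    occ_cycle = 0.5 * (occ[:-1] + occ[1:]) if settings.half_cycle_correction else occ[:-1]
    disc = _discount_vector(n, settings, costs.discount_annual)

    drug_per_cycle = np.array([cycle_drug_cost(regimen, k) for k in range(n)])
    p_sub = costs.p_subsequent.get(arm, 0.0)
    alive = occ_cycle[:, PFS_ON] + occ_cycle[:, PFS_OFF_AE] + occ_cycle[:, PD]

    ae_cost_once = np.zeros(n)
    ae_cost_once[0] = ae_burden(costs.ae_costs.get(arm, ()))

    cost_ledger = {
        "drug": occ_cycle[:, PFS_ON] * drug_per_cycle * disc,
        "adverse_events": ae_cost_once * disc,
        "followup": alive * costs.followup_per_cycle * disc,
        "bsc": alive * costs.bsc_per_cycle * disc,
        "subsequent_therapy": occ_cycle[:, PD]
        * costs.subsequent_therapy_per_cycle
        * p_sub
        * disc,
        "end_of_life": trace.entrants_death * costs.end_of_life_onetime * disc,
    }

    cyc_years = settings.cycle_years
    ae_dis_once = np.zeros(n)
    ae_dis_once[0] = ae_burden(utils.ae_disutilities.get(arm, ()))
    pfs_occ = occ_cycle[:, PFS_ON] + occ_cycle[:, PFS_OFF_AE]
    qaly_ledger = {
        "pfs": pfs_occ * utils.u_pfs * cyc_years * disc,
        "pd": occ_cycle[:, PD] * utils.u_pd * cyc_years * disc,
        "ae_disutility": -ae_dis_once * disc,
    }

    life_years = float(((pfs_occ + occ_cycle[:, PD]) * cyc_years * disc).sum())
    total_cost = float(sum(v.sum() for v in cost_ledger.values()))
    total_qalys = float(sum(v.sum() for v in qaly_ledger.values()))
    return EconomicResult(
        arm=arm,
        total_cost=total_cost,
        total_qalys=total_qalys,
        total_life_years=life_years,
        cost_ledger=cost_ledger,
        qaly_ledger=qaly_ledger,
    )


def compare_strategies(
    a: EconomicResult, b: EconomicResult, wtp: float = DEFAULT_WTP
) -> ComparisonResult:
    """Incremental cost-effectiveness of strategy ``a`` versus comparator ``b``.

    The ICER is reported only when the sign of the incremental effect makes
    it meaningful; when ``a`` is cheaper and more effective it dominates
    (cost-effective at any WTP), and conversely when dominated.
    """
    d_cost = a.total_cost - b.total_cost
    d_qalys = a.total_qalys - b.total_qalys

    if d_qalys == 0.0:
        dominance = Dominance.DOMINANT if d_cost < 0 else (
            Dominance.DOMINATED if d_cost > 0 else Dominance.NONE
        )
        return ComparisonResult(
            a.arm, b.arm, d_cost, d_qalys, None, dominance, wtp, d_cost <= 0
        )
    if d_qalys > 0 and d_cost <= 0:
        return ComparisonResult(
            a.arm, b.arm, d_cost, d_qalys, None, Dominance.DOMINANT, wtp, True
        )
    if d_qalys < 0 and d_cost >= 0:
        return ComparisonResult(
            a.arm, b.arm, d_cost, d_qalys, None, Dominance.DOMINATED, wtp, False
        )
    icer = d_cost / d_qalys
    if d_qalys > 0:
        decision = icer < wtp
    else:  # a saves money while losing QALYs: acceptable if savings per QALY lost exceed WTP
        decision = icer > wtp
    return ComparisonResult(a.arm, b.arm, d_cost, d_qalys, icer, Dominance.NONE, wtp, decision)


def ledgers_to_frame(result: EconomicResult) -> pd.DataFrame:
    """Per-cycle discounted cost and QALY categories as a tidy frame."""
    n = len(next(iter(result.cost_ledger.values())))
    data = {"cycle": np.arange(n)}
    for name, v in result.cost_ledger.items():
        data[f"cost_{name}"] = v
    for name, v in result.qaly_ledger.items():
        data[f"qaly_{name}"] = v
    return pd.DataFrame(data)
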