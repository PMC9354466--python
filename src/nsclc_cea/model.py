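"""The configured cost-effectiveness model: one object, many evaluations.

:class:`CEAModel` binds the fitted control-arm survival curves, the hazard
ratios for the intervention arm, and all cost/utility inputs into a single
callable surface.  Every scalar the sensitivity analyses may vary is exposed
through a flat parameter registry (``base_params``), and ``evaluate``
re-runs both strategies with any subset of parameters overridden.

The control arm's PFS and OS curves are tabulated once at the cycle
boundaries; hazard-ratio overrides are then plain element-wise powers, which
keeps a 10,000-iteration probabilistic sensitivity analysis tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .econ_valuation import (
    ComparisonResult,
    CostInputs,
    EconomicResult,
    UtilityInputs,
    ae_burden,
    compare_strategies,
    evaluate_strategy,
    DEFAULT_WTP,
)
from .errors import ConfigError
from .markov_engine import CycleSettings, run_cohort, schedule_from_arrays
from .survival_dists import SurvivalFunction


@dataclass(frozen=True)
class StrategyPair:
    """Both strategies' economics plus their incremental comparison."""

    intervention: EconomicResult
    control: EconomicResult
    comparison: ComparisonResult

    @property
    def icer(self) -> float | None:
        return self.comparison.icer


class CEAModel:
    """Fully configured two-strategy Markov cost-effectiveness model.

    Parameters
    ----------
    pfs_control, os_control
        Fitted survival functions for the control (chemotherapy-only) arm.
    hr_pfs, hr_os
        Hazard ratios applied to the control curves to obtain the
        intervention arm under proportional hazards.
    ae_disc
        Per-cycle adverse-event discontinuation probability per arm.
    costs, utils, settings
        Economic inputs and cycle settings shared by both strategies.
    intervention, control
        Arm labels, used to index per-arm tables in ``costs``/``utils``.
    """

    def __init__(
        self,
        pfs_control: SurvivalFunction,
        os_control: SurvivalFunction,
        hr_pfs: float,
        hr_os: float,
        ae_disc: Mapping[str, float],
        costs: CostInputs,
        utils: UtilityInputs,
        settings: CycleSettings,
        intervention: str = "TPP",
        control: str = "PP",
        wtp: float = DEFAULT_WTP,
    ):
        self.settings = settings
        self.intervention = intervention
        self.control = control
        self.wtp = wtp
        self._costs = costs
        self._utils = utils

        t = np.arange(settings.n_cycles + 1) * settings.cycle_months
        self._s_pfs_control = np.asarray(pfs_control.sf(t), dtype=float)
        self._s_os_control = np.asarray(os_control.sf(t), dtype=float)

        self.base_params: dict[str, float] = {
            "hr_pfs": float(hr_pfs),
            "hr_os": float(hr_os),
            "u_pfs": utils.u_pfs,
            "u_pd": utils.u_pd,
            "followup_per_cycle": costs.followup_per_cycle,
            "bsc_per_cycle": costs.bsc_per_cycle,
            "subsequent_therapy_per_cycle": costs.subsequent_therapy_per_cycle,
            "end_of_life_onetime": costs.end_of_life_onetime,
            "discount_annual": costs.discount_annual,
        }
        for arm in (intervention, control):
            self.base_params[f"ae_disc_{arm}"] = float(ae_disc.get(arm, 0.0))
            self.base_params[f"p_subsequent_{arm}"] = float(
                costs.p_subsequent.get(arm, 0.0)
            )
            self.base_params[f"ae_cost_{arm}"] = ae_burden(costs.ae_costs.get(arm, ()))
            self.base_params[f"ae_disutility_{arm}"] = ae_burden(
                utils.ae_disutilities.get(arm, ())
            )
            for comp in costs.regimens[arm].components:
                self.base_params[f"price_{arm}_{comp.name}"] = comp.unit_price

    # -- parameter plumbing --------------------------------------------------
    def resolve_params(self, overrides: Mapping[str, float] | None = None) -> dict[str, float]:
        if not overrides:
            return dict(self.base_params)
        unknown = set(overrides) - set(self.base_params)
        if unknown:
            raise ConfigError(f"unknown parameter id(s): {sorted(unknown)}")
        merged = dict(self.base_params)
        merged.update({k: float(v) for k, v in overrides.items()})
        return merged

    def _materialize_inputs(self, p: Mapping[str, float]) -> tuple[CostInputs, UtilityInputs]:
        regimens = {}
        for arm, regimen in self._costs.regimens.items():
            comps = tuple(
                replace(c, unit_price=p.get(f"price_{arm}_{c.name}", c.unit_price))
                for c in regimen.components
            )
            regimens[arm] = replace(regimen, components=comps)
        costs = replace(
            self._costs,
            regimens=regimens,
            ae_costs={arm: ((1.0, p[f"ae_cost_{arm}"]),) for arm in regimens},
            followup_per_cycle=p["followup_per_cycle"],
            bsc_per_cycle=p["bsc_per_cycle"],
            subsequent_therapy_per_cycle=p["subsequent_therapy_per_cycle"],
            p_subsequent={arm: p[f"p_subsequent_{arm}"] for arm in regimens},
            end_of_life_onetime=p["end_of_life_onetime"],
            discount_annual=p["discount_annual"],
        )
        utils = replace(
            self._utils,
            u_pfs=p["u_pfs"],
            u_pd=p["u_pd"],
            ae_disutilities={arm: ((1.0, p[f"ae_disutility_{arm}"]),) for arm in regimens},
        )
        return costs, utils

    # -- evaluation -----------------------------------------------------------
    def evaluate(self, overrides: Mapping[str, float] | None = None) -> StrategyPair:
        """Run both strategies under (optionally overridden) parameters."""
        p = self.resolve_params(overrides)
        costs, utils = self._materialize_inputs(p)

        results = {}
        for arm, hr_pfs, hr_os in (
            (self.control, 1.0, 1.0),
            (self.intervention, p["hr_pfs"], p["hr_os"]),
        ):
            s_pfs = np.power(self._s_pfs_control, hr_pfs)
            s_os = np.power(self._s_os_control, hr_os)
            schedule = schedule_from_arrays(s_pfs, s_os, p[f"ae_disc_{arm}"], strict=False)
            trace = run_cohort(schedule, self.settings)
            results[arm] = evaluate_strategy(trace, costs, utils, self.settings, arm)

        comparison = compare_strategies(
            results[self.intervention], results[self.control], self.wtp
        )
        return StrategyPair(results[self.intervention], results[self.control], comparison)

    def icer(self, overrides: Mapping[str, float] | None = None) -> float | None:
        return self.evaluate(overrides).icer
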