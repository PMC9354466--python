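"""Shared fixtures: analytic survival inputs and a small configured model."""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from nsclc_cea import (
    ArmSpec,
    CEAModel,
    CostInputs,
    CycleSettings,
    DrugComponent,
    RegimenSpec,
    TrialSpec,
    UtilityInputs,
)
from nsclc_cea.survival_dists import from_median

MEDIAN_PFS_PP = 7.6  # months, control-arm trial anchor
MEDIAN_OS_PP = 18.0  # months, reference-scenario placeholder
HR_PFS = 0.645
HR_OS = 0.70


def make_trial(n=500, censor_time=1e6, dropout_rate=0.0, seed=0,
               pfs_family="exponential", pfs_shape=None):
    """Two-arm exponential-truth trial; intervention arm via exact HRs."""
    pfs_pp = from_median(pfs_family, MEDIAN_PFS_PP, pfs_shape)
    os_pp = from_median("exponential", MEDIAN_OS_PP)
    if pfs_family == "exponential":
        pfs_tpp = ("exponential", (pfs_pp.params[0] * HR_PFS,))
    else:  # weibull: scale rescales by hr**(-1/shape)
        pfs_tpp = ("weibull", (pfs_pp.params[0] * HR_PFS ** (-1 / pfs_pp.params[1]),
                               pfs_pp.params[1]))
    os_tpp = ("exponential", (os_pp.params[0] * HR_OS,))
    arms = (
        ArmSpec("PP", pfs_pp.family, pfs_pp.params, os_pp.family, os_pp.params, n),
        ArmSpec("TPP", pfs_tpp[0], pfs_tpp[1], os_tpp[0], os_tpp[1], n),
    )
    return TrialSpec(arms=arms, censor_time=censor_time, dropout_rate=dropout_rate,
                     seed=seed)


@pytest.fixture(scope="session")
def settings():
    return CycleSettings(cycle_days=21, horizon_years=20, half_cycle_correction=True)


def make_model(settings, *, hr_pfs=HR_PFS, hr_os=HR_OS, equal_arms=False,
               followup=92.0, subsequent=580.0, wtp=35_663.0):
    """A fully analytic CEAModel (no fitting) for economics/sensitivity tests."""
    pfs = from_median("exponential", MEDIAN_PFS_PP)
    os_ = from_median("exponential", MEDIAN_OS_PP)
    tis = DrugComponent("tislelizumab", "flat", 200, 100, 338.0)
    pem = DrugComponent("pemetrexed", "per_m2", 500, 500, 124.0)
    carb = DrugComponent("carboplatin", "calvert_auc", 5, 100, 9.0, max_cycles=4)
    reg_tpp = RegimenSpec((tis, pem, carb), premedication_per_cycle=15.0)
    reg_pp = RegimenSpec((pem, carb), premedication_per_cycle=15.0)
    if equal_arms:
        reg_tpp = reg_pp
    costs = CostInputs(
        regimens={"TPP": reg_tpp, "PP": reg_pp},
        ae_costs={"TPP": ((0.3, 600.0),), "PP": ((0.28, 550.0),)} if not equal_arms else {},
        followup_per_cycle=followup,
        bsc_per_cycle=150.0,
        subsequent_therapy_per_cycle=subsequent,
        p_subsequent={"TPP": 0.5, "PP": 0.5},
        end_of_life_onetime=1869.0,
        discount_annual=0.05,
    )
    utils = UtilityInputs(
        u_pfs=0.856,
        u_pd=0.768,
        ae_disutilities={"TPP": ((0.3, 0.15),), "PP": ((0.28, 0.14),)} if not equal_arms else {},
    )
    ae_disc = {"TPP": 0.0, "PP": 0.0} if equal_arms else {"TPP": 0.0134, "PP": 0.012}
    return CEAModel(
        pfs_control=pfs,
        os_control=os_,
        hr_pfs=hr_pfs,
        hr_os=hr_os,
        ae_disc=ae_disc,
        costs=costs,
        utils=utils,
        settings=settings,
        wtp=wtp,
    )


@pytest.fixture(scope="session")
def model(settings):
    return make_model(settings)
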