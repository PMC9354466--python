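"""Parametric fitting, AIC selection, HR transform, transition probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from nsclc_cea import (
    FittedSurvival,
    HazardRatio,
    IPDRecord,
    apply_hazard_ratio,
    fit_parametric,
    interval_transition_prob,
    select_best_fit,
)
from nsclc_cea.errors import AbsorbedStateError, EmptyInputError, NoEventsError
from nsclc_cea.survival_dists import SUPPORTED_FAMILIES, from_median
from nsclc_cea.survival_fit import DAYS_PER_MONTH

RATE = 0.0912  # per month: exponential with median ~7.6 months


def exp_records(n, rate=RATE, seed=0):
    rng = np.random.default_rng(seed)
    return [IPDRecord("A", "PFS", float(t), 1) for t in rng.exponential(1 / rate, n)]


class TestFitParametric:
    def test_exponential_rate_recovery(self):
        fit = fit_parametric(exp_records(2_000, seed=1), "exponential")
        assert fit.params[0] == pytest.approx(RATE, rel=0.05)

    def test_weibull_shape_near_one_on_exponential_data(self):
        fit = fit_parametric(exp_records(2_000, seed=2), "weibull")
        assert 0.9 <= fit.params[1] <= 1.1

    def test_single_event_closed_form(self):
        fit = fit_parametric([IPDRecord("A", "PFS", 4.0, 1)], "exponential")
        assert fit.params[0] == pytest.approx(0.25)

    def test_all_censored_rejected(self):
        recs = [IPDRecord("A", "PFS", t, 0) for t in (1.0, 2.0)]
        with pytest.raises(NoEventsError):
            fit_parametric(recs, "weibull")

    @pytest.mark.parametrize("family", SUPPORTED_FAMILIES)
    def test_aic_bic_consistency_and_survival_shape(self, family):
        fit = fit_parametric(exp_records(400, seed=3), family)
        k = fit.n_params
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, abs=1e-8)
        assert fit.bic == pytest.approx(k * math.log(fit.n) - 2 * fit.loglik, abs=1e-8)
        S = fit.survival
        t = np.linspace(0, 600, 400)
        s = S.sf(t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] < 0.01  # decays to zero (no immortal plateau)


class TestSelectBestFit:
    def test_true_family_selected_at_large_n(self):
        # nested models: Weibull pays +2 AIC for its extra parameter
        recs = exp_records(5_000, seed=4)
        fits = [fit_parametric(recs, f) for f in ("exponential", "weibull")]
        assert select_best_fit(fits).family == "exponential"

    def test_singleton_returned_unchanged(self):
        fit = fit_parametric(exp_records(50, seed=5), "exponential")
        assert select_best_fit([fit]) is fit

    def test_exact_tie_prefers_fewer_parameters(self):
        one = FittedSurvival("exponential", (0.1,), loglik=-10.0, aic=22.0,
                             bic=22.0 + math.log(5) - 2, n=5)
        two = FittedSurvival("weibull", (10.0, 1.0), loglik=-9.0, aic=22.0,
                             bic=22.0 + 2 * math.log(5) - 4, n=5)
        assert select_best_fit([two, one]) is one

    def test_empty_collection_rejected(self):
        with pytest.raises(EmptyInputError):
            select_best_fit([])


class TestHazardRatio:
    def test_identity_at_hr_one(self):
        base = fit_parametric(exp_records(100, seed=6), "exponential")
        out = apply_hazard_ratio(base, HazardRatio(1.0))
        assert out == base.survival  # same family and parameters, unwrapped

    def test_exponential_median_scales_inversely(self):
        base = from_median("exponential", 7.6)
        new = apply_hazard_ratio(base, HazardRatio(0.645, endpoint="PFS"))
        assert new.median() == pytest.approx(7.6 / 0.645, rel=1e-9)
        assert new.median() == pytest.approx(11.78, abs=0.01)

    @given(t=st.floats(0.01, 100), hr=st.floats(0.05, 1.0))
    @hyp_settings(max_examples=50, deadline=None)
    def test_protective_hr_raises_survival(self, t, hr):
        base = from_median("weibull", 7.6, shape=1.3)
        assert apply_hazard_ratio(base, hr).sf(t) >= base.sf(t)

    def test_ci_must_bracket_estimate(self):
        with pytest.raises(ValueError):
            HazardRatio(0.645, ci_low=0.7, ci_high=0.9)


class TestIntervalTransitionProb:
    def test_memoryless_closed_form(self):
        # 21-day cycle in months: p = 1 - exp(-lambda * delta) ~ 0.0610
        S = from_median("exponential", math.log(2) / 0.0912)
        delta = 21 / DAYS_PER_MONTH
        p0 = interval_transition_prob(S, 0.0, delta)
        assert p0 == pytest.approx(1 - math.exp(-0.0912 * delta), abs=1e-12)
        assert p0 == pytest.approx(0.0610, abs=5e-4)
        # memorylessness: independent of the cycle start
        assert interval_transition_prob(S, 37.0, delta) == pytest.approx(p0, abs=1e-12)

    def test_vanishing_cycle_length(self):
        S = from_median("exponential", 10.0)
        assert interval_transition_prob(S, 5.0, 1e-9) < 1e-8

    def test_absorbed_state_rejected(self):
        S = from_median("weibull", 1.0, shape=2.0)
        with pytest.raises(AbsorbedStateError):
            interval_transition_prob(S, 1e4, 1.0)

    @pytest.mark.parametrize("family,shape", [("exponential", None), ("weibull", 1.3),
                                              ("loglogistic", 2.0), ("gompertz", 0.05)])
    def test_chained_probabilities_recompose_survival(self, family, shape):
        S = from_median(family, 9.0, shape)
        delta = 21 / DAYS_PER_MONTH
        prod = 1.0
        for k in range(60):
            prod *= 1.0 - interval_transition_prob(S, k * delta, delta)
        assert prod == pytest.approx(float(S.sf(60 * delta)), abs=1e-10)
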