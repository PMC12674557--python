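"""Parametric fitting: closed-form checks, recovery, AIC selection, PH adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from lifelines import LogNormalFitter, WeibullFitter

from hcc_cea import survival_models as sm
from hcc_cea import synthetic_trial as st

from conftest import OS_WEIBULL, PFS_LOGNORMAL, make_trial


class TestFitParametric:
    def test_exponential_mle_is_events_over_time(self):
        ipd = make_trial(n=400, family="exponential", params=(0.06,), cutoff=30.0, accrual=10.0, seed=2)
        fit = sm.fit_parametric(ipd, "exponential")
        closed_form = ipd.n_events / ipd.times.sum()
        assert fit.params[0] == pytest.approx(closed_form, rel=1e-9)

    def test_weibull_parameter_recovery_uncensored(self):
        ipd = make_trial(n=2000, family="weibull", params=OS_WEIBULL, cutoff=math.inf, seed=0)
        fit = sm.fit_parametric(ipd, "weibull")
        assert fit.params[0] == pytest.approx(OS_WEIBULL[0], rel=0.10)
        assert fit.params[1] == pytest.approx(OS_WEIBULL[1], rel=0.10)

    def test_lognormal_mle_matches_closed_form_uncensored(self):
        ipd = make_trial(n=2000, family="lognormal", params=PFS_LOGNORMAL, cutoff=math.inf, seed=9)
        fit = sm.fit_parametric(ipd, "lognormal")
        logt = np.log(ipd.times)
        assert fit.params[0] == pytest.approx(logt.mean(), abs=1e-5)
        assert fit.params[1] == pytest.approx(logt.std(), abs=1e-5)

    def test_weibull_fit_agrees_with_lifelines_under_censoring(self):
        """Independent MLE cross-check: lifelines' Weibull (S=exp(-(t/b)^k))."""
        ipd = make_trial(n=500, family="weibull", params=OS_WEIBULL, cutoff=34.0, accrual=23.0, seed=4)
        ours = sm.fit_parametric(ipd, "weibull")
        wf = WeibullFitter().fit(ipd.times, ipd.events)
        lam_ll = wf.lambda_ ** (-wf.rho_)  # convert to S=exp(-lam t^gamma)
        assert ours.params[1] == pytest.approx(wf.rho_, rel=1e-3)
        assert ours.params[0] == pytest.approx(lam_ll, rel=1e-3)
        assert ours.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)

    def test_lognormal_fit_agrees_with_lifelines_under_censoring(self):
        ipd = make_trial(n=500, family="lognormal", params=PFS_LOGNORMAL, cutoff=34.0, accrual=23.0, seed=6)
        ours = sm.fit_parametric(ipd, "lognormal")
        lnf = LogNormalFitter().fit(ipd.times, ipd.events)
        assert ours.params[0] == pytest.approx(lnf.mu_, rel=1e-3)
        assert ours.params[1] == pytest.approx(lnf.sigma_, rel=1e-3)

    def test_all_censored_rejected(self):
        ipd = st.PseudoIPD(np.array([1.0, 2.0]), np.array([0, 0]))
        with pytest.raises(ValueError, match="event"):
            sm.fit_parametric(ipd, "weibull")

    def test_unknown_family_rejected(self):
        ipd = make_trial(n=50, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            sm.fit_parametric(ipd, "gompertz")


class TestCompareFits:
    def test_aic_is_definitional_and_selected_is_argmin(self):
        ipd = make_trial(n=300, family="exponential", params=(0.05,), cutoff=40.0, accrual=10.0, seed=1)
        comp = sm.compare_fits(ipd)
        for fam, fit in comp.fits.items():
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        table = comp.table()
        assert comp.selected == table["aic"].idxmin()
        # exponential truth: its 1-extra-parameter supersets fit no better
        # than ~2 AIC above (chi-square 1 dof), so exponential usually wins
        assert table.loc["weibull", "aic"] >= table.loc["exponential", "aic"] - 2.0

    def test_single_family_selected(self):
        ipd = make_trial(n=200, seed=3)
        comp = sm.compare_fits(ipd, families=("lognormal",))
        assert comp.selected == "lognormal"


class TestSurvivalAt:
    def test_weibull_median_closed_form(self):
        model = sm.ParametricSurvival("weibull", OS_WEIBULL)
        med = (math.log(2.0) / OS_WEIBULL[0]) ** (1.0 / OS_WEIBULL[1])
        assert med == pytest.approx(15.57, abs=0.05)
        assert model.survival_at(med) == pytest.approx(0.5, abs=1e-12)
        assert model.median() == pytest.approx(med)

    def test_lognormal_median_closed_form(self):
        model = sm.ParametricSurvival("lognormal", PFS_LOGNORMAL)
        med = math.exp(PFS_LOGNORMAL[0])
        assert med == pytest.approx(6.74, abs=0.01)
        assert model.survival_at(med) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "family,params",
        [
            ("exponential", (0.05,)),
            ("weibull", OS_WEIBULL),
            ("lognormal", PFS_LOGNORMAL),
            ("loglogistic", (10.0, 1.5)),
        ],
    )
    def test_survival_at_zero_is_one(self, family, params):
        assert sm.ParametricSurvival(family, params).survival_at(0.0) == 1.0

    def test_negative_time_rejected(self):
        model = sm.ParametricSurvival("weibull", OS_WEIBULL)
        with pytest.raises(ValueError):
            model.survival_at(-1.0)


class TestApplyHR:
    def test_hr_one_is_identity(self):
        model = sm.ParametricSurvival("lognormal", PFS_LOGNORMAL)
        adj = sm.apply_hr(model, 1.0)
        t = np.linspace(0.0, 60.0, 31)
        assert adj.survival_at(t) == pytest.approx(model.survival_at(t))

    def test_weibull_ph_closed_under_scale(self):
        """S^hr for a Weibull equals a Weibull with scale hr*lam."""
        lam, gam = OS_WEIBULL
        adj = sm.apply_hr(sm.ParametricSurvival("weibull", (lam, gam)), 0.64)
        equivalent = sm.ParametricSurvival("weibull", (0.64 * lam, gam))
        t = np.linspace(0.0, 120.0, 61)
        assert adj.survival_at(t) == pytest.approx(equivalent.survival_at(t))

    def test_protective_hr_raises_survival(self):
        model = sm.ParametricSurvival("weibull", OS_WEIBULL)
        adj = sm.apply_hr(model, 0.64)
        t = np.linspace(0.5, 60.0, 40)
        assert np.all(adj.survival_at(t) >= model.survival_at(t))

    def test_hr_ordering_preserved_pointwise(self):
        model = sm.ParametricSurvival("lognormal", PFS_LOGNORMAL)
        t = np.linspace(0.5, 60.0, 40)
        s_low = sm.apply_hr(model, 0.5).survival_at(t)
        s_high = sm.apply_hr(model, 1.5).survival_at(t)
        assert np.all(s_low >= s_high)

    def test_nonpositive_hr_rejected(self):
        model = sm.ParametricSurvival("weibull", OS_WEIBULL)
        with pytest.raises(ValueError):
            sm.apply_hr(model, 0.0)


@settings(max_examples=40, deadline=None)
@given(
    family=hst.sampled_from(sm.FAMILIES),
    p1=hst.floats(min_value=0.005, max_value=5.0),
    p2=hst.floats(min_value=0.2, max_value=5.0),
)
def test_survival_function_shape_properties(family, p1, p2):
    """S(0)=1, S non-increasing, S(t) -> 0 for large t, for any parameters."""
    params = (p1,) if family == "exponential" else (p1, p2)
    if family == "lognormal":
        params = (math.log(p1), p2)
    model = sm.ParametricSurvival(family, params)
    t = np.linspace(0.0, 5000.0, 200)
    s = model.survival_at(t)
    assert s[0] == 1.0
    assert np.all(np.diff(s) <= 1e-12)
    assert s[-1] < 0.5 or model.median() > 1000.0
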