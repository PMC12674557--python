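"""Cohort engine: occupancy identities, accrual arithmetic, ICER logic."""

import math

import numpy as np
import pytest
from scipy import special, stats

from hcc_cea import markov_cea as mc
from hcc_cea import survival_models as sm

from conftest import OS_WEIBULL, PFS_LOGNORMAL

OS_MODEL = sm.ParametricSurvival("weibull", OS_WEIBULL)
PFS_MODEL = sm.ParametricSurvival("lognormal", PFS_LOGNORMAL)


def cabo_arm(**kw):
    args = dict(
        name="atezo-cabo",
        pfs_model=PFS_MODEL,
        os_model=OS_MODEL,
        dosing_mg_per_cycle={"atezolizumab": 1200.0, "cabozantinib": 840.0},
        ae_incidences={"ast_increase": 0.09, "alt_increase": 0.08, "hypertension": 0.09},
        p_subsequent_active=0.20,
    )
    args.update(kw)
    return mc.ArmSpec(**args)


class TestStateOccupancy:
    def test_entry_state_is_all_pfs(self):
        trace = mc.state_occupancy(PFS_MODEL, OS_MODEL, mc.ModelSettings())
        assert (trace.pfs[0], trace.pd[0], trace.death[0]) == (1.0, 0.0, 0.0)

    def test_identical_curves_leave_pd_empty(self):
        trace = mc.state_occupancy(OS_MODEL, OS_MODEL, mc.ModelSettings())
        assert np.all(trace.pd == 0.0)

    def test_pd_occupancy_matches_closed_forms_at_12_months(self):
        settings = mc.ModelSettings()
        trace = mc.state_occupancy(PFS_MODEL, OS_MODEL, settings)
        k = int(round(12.0 / settings.cycle_length_months))
        t = trace.time_months[k]
        lam, gam = OS_WEIBULL
        mu, sigma = PFS_LOGNORMAL
        s_os = math.exp(-lam * t**gam)
        s_pfs = stats.norm.sf((math.log(t) - mu) / sigma)
        assert trace.pd[k] == pytest.approx(s_os - s_pfs, abs=1e-12)

    def test_occupancy_conserved_and_death_monotone(self):
        for hr_os, hr_pfs in [(None, None), (0.64, 0.95)]:
            arm = cabo_arm(hr_os=hr_os, hr_pfs=hr_pfs)
            pfs_c, os_c = arm.curves()
            trace = mc.state_occupancy(pfs_c, os_c, mc.ModelSettings())
            assert np.max(np.abs(trace.pfs + trace.pd + trace.death - 1.0)) < 1e-9
            assert np.all(np.diff(trace.death) >= -1e-12)

    def test_transition_diagnostics_reproduce_occupancy(self):
        """Replaying the per-cycle probabilities regenerates the trace."""
        trace = mc.state_occupancy(PFS_MODEL, OS_MODEL, mc.ModelSettings())
        pfs, pd_ = [1.0], [0.0]
        for k in range(trace.n_cycles):
            exits = trace.p_pfs_exit[k] * pfs[-1]
            dead_from_pfs = trace.p_pfs_death[k] * pfs[-1]
            inflow = exits - dead_from_pfs
            dead_from_pd = trace.p_pd_death[k] * (pd_[-1] + inflow)
            pfs.append(pfs[-1] - exits)
            pd_.append(pd_[-1] + inflow - dead_from_pd)
        assert np.asarray(pfs) == pytest.approx(trace.pfs, abs=1e-9)
        assert np.asarray(pd_) == pytest.approx(trace.pd, abs=1e-9)


class TestAccrueOutcomes:
    def test_zero_utilities_zero_ae_gives_zero_qalys(self):
        trace = mc.state_occupancy(PFS_MODEL, OS_MODEL, mc.ModelSettings())
        utils = mc.UtilityInputs(u_pfs=0.0, u_pd=0.0, ae_disutility=0.0)
        ly, qaly = mc.accrue_outcomes(trace, utils, 0.0, mc.ModelSettings())
        assert qaly == 0.0
        assert ly > 0.0

    def test_undiscounted_ly_matches_weibull_mean(self):
        """With half-cycle (trapezoid) accrual and no discounting the model
        life expectancy reproduces lam^(-1/gam)*Gamma(1+1/gam)."""
        settings = mc.ModelSettings(discount_rate=0.0, half_cycle_correction=True)
        trace = mc.state_occupancy(OS_MODEL, OS_MODEL, settings)
        ly, _ = mc.accrue_outcomes(trace, mc.UtilityInputs(), 0.0, settings)
        lam, gam = OS_WEIBULL
        mean_months = lam ** (-1.0 / gam) * special.gamma(1.0 + 1.0 / gam)
        assert ly == pytest.approx(mean_months / 12.0, rel=0.005)

    def test_exponential_discounted_ly_matches_geometric_series(self):
        lam = 0.05
        exp_model = sm.ParametricSurvival("exponential", (lam,))
        settings = mc.ModelSettings()
        trace = mc.state_occupancy(exp_model, exp_model, settings)
        ly, _ = mc.accrue_outcomes(trace, mc.UtilityInputs(), 0.0, settings)
        u = settings.cycle_length_months
        q = math.exp(-lam * u) * (1.03) ** (-u / 12.0)
        closed = (u / 12.0) * q * (1.0 - q**trace.n_cycles) / (1.0 - q)
        assert ly == pytest.approx(closed, rel=1e-6)

    def test_qalys_bounded_by_lys_and_discount_monotone(self):
        arm = cabo_arm()
        for rate in (0.0, 0.03, 0.06):
            settings = mc.ModelSettings(discount_rate=rate)
            res = mc.run_arm(arm, settings, mc.UtilityInputs(), mc.CostInputs())
            assert res.qalys <= res.life_years
        r0 = mc.run_arm(arm, mc.ModelSettings(discount_rate=0.0), mc.UtilityInputs(), mc.CostInputs())
        r6 = mc.run_arm(arm, mc.ModelSettings(discount_rate=0.06), mc.UtilityInputs(), mc.CostInputs())
        assert r6.life_years < r0.life_years
        assert r6.qalys < r0.qalys

    def test_horizon_cap_is_non_binding(self):
        arm = cabo_arm()
        base = mc.run_arm(arm, mc.ModelSettings(), mc.UtilityInputs(), mc.CostInputs())
        longer = mc.run_arm(
            arm, mc.ModelSettings(max_horizon_years=60.0), mc.UtilityInputs(), mc.CostInputs()
        )
        assert longer.life_years == pytest.approx(base.life_years, rel=1e-3)


class TestAccrueCosts:
    def test_zero_prices_zero_cost(self):
        arm = cabo_arm()
        zero = mc.CostInputs(
            atezolizumab_per_10mg=0.0,
            bevacizumab_per_10mg=0.0,
            cabozantinib_per_mg=0.0,
            testing_per_cycle=0.0,
            subsequent_active_per_patient=0.0,
            subsequent_bsc_per_patient=0.0,
            ae_event_costs={"ast_increase": 0.0, "alt_increase": 0.0, "hypertension": 0.0},
        )
        res = mc.run_arm(arm, mc.ModelSettings(), mc.UtilityInputs(), zero)
        assert res.total_cost == 0.0

    def test_drug_cost_per_cycle_hand_arithmetic(self):
        costs = mc.CostInputs()
        beva_cycle = costs.drug_cost_per_cycle({"atezolizumab": 1200.0, "bevacizumab": 1050.0})
        assert beva_cycle == pytest.approx(120 * 82.678 + 105 * 73.579)
        cabo_cycle = costs.drug_cost_per_cycle({"cabozantinib": 40.0 * 21.0})
        assert cabo_cycle == pytest.approx(40 * 21 * 9.44)

    def test_unknown_drug_rejected(self):
        with pytest.raises(KeyError):
            mc.CostInputs().drug_cost_per_cycle({"sorafenib": 100.0})

    def test_one_time_mode_cheaper_than_per_cycle(self):
        """Charging progression once costs less than charging every PD cycle
        whenever mean PD duration exceeds one cycle."""
        arm = cabo_arm()
        per_cycle = mc.run_arm(arm, mc.ModelSettings(), mc.UtilityInputs(), mc.CostInputs())
        one_time = mc.run_arm(
            arm,
            mc.ModelSettings(),
            mc.UtilityInputs(),
            mc.CostInputs(post_progression_cost_mode="one_time"),
        )
        assert one_time.cost_breakdown.post_progression < per_cycle.cost_breakdown.post_progression
        assert one_time.cost_breakdown.drug == per_cycle.cost_breakdown.drug

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            mc.CostInputs(post_progression_cost_mode="weekly")


class TestRunArmAndICER:
    def test_unit_hazard_ratios_reproduce_baseline(self):
        base = mc.run_arm(cabo_arm(), mc.ModelSettings(), mc.UtilityInputs(), mc.CostInputs())
        unit = mc.run_arm(
            cabo_arm(hr_os=1.0, hr_pfs=1.0), mc.ModelSettings(), mc.UtilityInputs(), mc.CostInputs()
        )
        assert unit.life_years == pytest.approx(base.life_years)
        assert unit.qalys == pytest.approx(base.qalys)
        assert unit.total_cost == pytest.approx(base.total_cost)

    def test_protective_os_hr_extends_life(self):
        base = mc.run_arm(cabo_arm(), mc.ModelSettings(), mc.UtilityInputs(), mc.CostInputs())
        adj = mc.run_arm(
            cabo_arm(hr_os=0.64, hr_pfs=1.0), mc.ModelSettings(), mc.UtilityInputs(), mc.CostInputs()
        )
        assert adj.life_years > base.life_years

    def test_icer_arithmetic_and_flags(self):
        settings = mc.ModelSettings()
        a = mc.run_arm(cabo_arm(hr_os=0.64, hr_pfs=0.95, name="a"), settings, mc.UtilityInputs(), mc.CostInputs())
        b = mc.run_arm(cabo_arm(name="b"), settings, mc.UtilityInputs(), mc.CostInputs())
        ce = mc.icer(a, b, settings)
        assert ce.icer_per_qaly == pytest.approx(ce.delta_cost / ce.delta_qaly)
        assert ce.icer_per_ly == pytest.approx(ce.delta_cost / ce.delta_ly)
        assert ce.nmb == pytest.approx(ce.delta_qaly * settings.wtp - ce.delta_cost)
        same = mc.icer(b, b, settings)
        assert same.delta_qaly == 0.0
        assert not same.icer_defined

    def test_dominance_flags(self):
        settings = mc.ModelSettings()
        base = mc.run_arm(cabo_arm(), settings, mc.UtilityInputs(), mc.CostInputs())

        def synthetic(name, qalys, cost):
            return mc.ArmResult(
                name=name,
                life_years=qalys,
                qalys=qalys,
                cost_breakdown=mc.CostBreakdown(drug=cost, testing=0.0, adverse_events=0.0, post_progression=0.0),
                trace=base.trace,
            )

        better_cheaper = synthetic("x", base.qalys + 0.5, base.total_cost - 1000.0)
        ce = mc.icer(better_cheaper, base, settings)
        assert ce.dominance == "intervention_dominant"
        rev = mc.icer(base, better_cheaper, settings)
        assert rev.dominance == "intervention_dominated"
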