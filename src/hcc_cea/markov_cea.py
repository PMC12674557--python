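"""Three-state Markov cohort model for first-line advanced HCC therapy.

States are progression-free (PFS), progressed disease (PD) and death.  The
whole cohort enters progression-free; occupancy at each 3-week cycle is
taken directly from the parametric PFS and OS curves via the
partitioned-survival identity

    PFS(t) = S_PFS(t),   Death(t) = 1 - S_OS(t),
    PD(t)  = max(0, S_OS(t) - S_PFS(t)),

with per-cycle transition probabilities derived as diagnostics that
reproduce exactly these occupancies.  The comparator arm uses the fitted
baseline curves; the intervention arm applies hazard ratios to them as
``S**HR``.  Discounted life-years, QALYs and costs are accrued per cycle
and summarized as incremental cost-effectiveness ratios.

Accrual convention: state membership is counted at the end of each cycle
(no half-cycle correction by default; a half-cycle flag averages the
start- and end-of-cycle sums).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .survival_models import apply_hr

__all__ = [
    "DAYS_PER_MONTH",
    "ModelSettings",
    "UtilityInputs",
    "CostInputs",
    "ArmSpec",
    "CohortTrace",
    "CostBreakdown",
    "ArmResult",
    "CEResult",
    "state_occupancy",
    "accrue_outcomes",
    "accrue_costs",
    "run_arm",
    "icer",
]

DAYS_PER_MONTH = 30.4375

#: $ per mg implied by each unit-price field of :class:`CostInputs`.
_PRICE_FIELDS: Mapping[str, tuple[str, float]] = {
    "atezolizumab": ("atezolizumab_per_10mg", 0.1),
    "bevacizumab": ("bevacizumab_per_10mg", 0.1),
    "cabozantinib": ("cabozantinib_per_mg", 1.0),
}


@dataclasses.dataclass(frozen=True)
class ModelSettings:
    """Global model settings (time in months unless noted)."""

    cycle_length_months: float = 21.0 / DAYS_PER_MONTH
    discount_rate: float = 0.03  # annual
    max_horizon_years: float = 40.0
    death_prob_stop: float = 0.999
    half_cycle_correction: bool = False
    wtp: float = 150_000.0  # $ per QALY

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ValueError("discount rate must lie in [0, 1]")
        if self.cycle_length_months <= 0:
            raise ValueError("cycle length must be positive")

    def cycle_times(self) -> np.ndarray:
        """Cycle boundary times 0, u, 2u, ... up to the horizon cap."""
        n = int(math.floor(self.max_horizon_years * 12.0 / self.cycle_length_months))
        return np.arange(n + 1) * self.cycle_length_months

    def discount_factors(self, t_months: np.ndarray) -> np.ndarray:
        return (1.0 + self.discount_rate) ** (-(np.asarray(t_months) / 12.0))


@dataclasses.dataclass(frozen=True)
class UtilityInputs:
    u_pfs: float = 0.76
    u_pd: float = 0.68
    ae_disutility: float = 0.16  # one-off, grade >= 3 adverse events

    def __post_init__(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclasses.dataclass(frozen=True)
class CostInputs:
    """Unit prices (2023 USD) and the post-progression accrual convention.

    ``per_cycle`` charges the expected per-patient subsequent-treatment cost
    against PD occupancy every cycle; ``one_time`` charges it once to the
    cohort fraction newly entering PD each cycle.
    """

    atezolizumab_per_10mg: float = 82.678
    bevacizumab_per_10mg: float = 73.579
    cabozantinib_per_mg: float = 9.44
    testing_per_cycle: float = 797.33
    subsequent_active_per_patient: float = 108_336.0
    subsequent_bsc_per_patient: float = 37_084.0
    ae_event_costs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"ast_increase": 59.0, "alt_increase": 59.0, "hypertension": 1701.0}
    )
    post_progression_cost_mode: str = "per_cycle"

    def __post_init__(self) -> None:
        numeric = [
            self.atezolizumab_per_10mg,
            self.bevacizumab_per_10mg,
            self.cabozantinib_per_mg,
            self.testing_per_cycle,
            self.subsequent_active_per_patient,
            self.subsequent_bsc_per_patient,
            *self.ae_event_costs.values(),
        ]
        if any(v < 0 for v in numeric):
            raise ValueError("unit costs must be non-negative")
        if self.post_progression_cost_mode not in ("per_cycle", "one_time"):
            raise ValueError(
                f"unknown post_progression_cost_mode {self.post_progression_cost_mode!r}"
            )

    def drug_cost_per_cycle(self, dosing_mg_per_cycle: Mapping[str, float]) -> float:
        """Acquisition cost of one cycle's dosing (linear mg pricing)."""
        total = 0.0
        for drug, mg in dosing_mg_per_cycle.items():
            if drug not in _PRICE_FIELDS:
                raise KeyError(f"no unit price for drug {drug!r}")
            field, per_mg_factor = _PRICE_FIELDS[drug]
            total += mg * per_mg_factor * getattr(self, field)
        return total


@dataclasses.dataclass(frozen=True)
class ArmSpec:
    """Everything needed to evaluate one treatment arm.

    ``pfs_model``/``os_model`` are the baseline survival functions (any
    object with ``survival_at``); when ``hr_pfs``/``hr_os`` are given the
    arm uses the proportional-hazards-adjusted curves ``S**HR``.
    """

    name: str
    pfs_model: object
    os_model: object
    dosing_mg_per_cycle: Mapping[str, float]
    ae_incidences: Mapping[str, float]
    p_subsequent_active: float
    hr_pfs: float | None = None
    hr_os: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_subsequent_active <= 1.0:
            raise ValueError("p_subsequent_active must lie in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.ae_incidences.values()):
            raise ValueError("adverse-event incidences must lie in [0, 1]")
        if any(mg < 0 for mg in self.dosing_mg_per_cycle.values()):
            raise ValueError("dosing must be non-negative")

    def curves(self) -> tuple[object, object]:
        pfs = self.pfs_model if self.hr_pfs is None else apply_hr(self.pfs_model, self.hr_pfs)
        os_ = self.os_model if self.hr_os is None else apply_hr(self.os_model, self.hr_os)
        return pfs, os_

    @property
    def total_ae_incidence(self) -> float:
        return float(sum(self.ae_incidences.values()))


@dataclasses.dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle state occupancy plus transition-probability diagnostics.

    Row ``k`` is the cycle boundary at time ``k * cycle_length``; transition
    arrays (length ``n_cycles``) describe the move from boundary ``k`` to
    ``k + 1`` and reproduce the occupancies exactly.
    """

    time_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    death: np.ndarray
    p_pfs_exit: np.ndarray
    p_pfs_death: np.ndarray
    p_pd_death: np.ndarray
    pd_inflow: np.ndarray  # cohort fraction newly progressing each cycle

    def __post_init__(self) -> None:
        occ = self.pfs + self.pd + self.death
        if np.max(np.abs(occ - 1.0)) > 1e-9:
            raise ValueError("state occupancies must sum to 1 at every cycle")
        if np.any(np.diff(self.death) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")
        if np.any(self.pfs < -1e-12) or np.any(self.pd < -1e-12):
            raise ValueError("occupancies must be non-negative")

    @property
    def n_cycles(self) -> int:
        return int(self.time_months.size - 1)

    @property
    def alive(self) -> np.ndarray:
        return self.pfs + self.pd

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_months": self.time_months,
                "pfs": self.pfs,
                "pd": self.pd,
                "death": self.death,
            }
        )
        for name in ("p_pfs_exit", "p_pfs_death", "p_pd_death", "pd_inflow"):
            col = np.full(self.time_months.size, np.nan)
            col[: self.n_cycles] = getattr(self, name)
            df[name] = col
        return df


def state_occupancy(pfs_curve, os_curve, settings: ModelSettings) -> CohortTrace:
    """Cohort occupancy over the model horizon from the two survival curves.

    The horizon ends at the first cycle where cohort mortality exceeds
    ``settings.death_prob_stop`` (or at the 40-year cap).  PFS exceeding OS
    (curve inconsistency) is clamped, with a warning when the excess is
    persistent (> 1e-6).
    """
    t = settings.cycle_times()
    s_os = np.asarray(os_curve.survival_at(t), dtype=float)
    s_pfs = np.asarray(pfs_curve.survival_at(t), dtype=float)
    excess = s_pfs - s_os
    if np.any(excess > 1e-6):
        warnings.warn("PFS curve exceeds OS curve; clamping PFS occupancy to OS")
    s_pfs = np.minimum(s_pfs, s_os)
    # monotone repair against floating-point wiggle
    s_os = np.minimum.accumulate(s_os)
    s_pfs = np.minimum.accumulate(s_pfs)

    death = 1.0 - s_os
    stop = np.nonzero(death > settings.death_prob_stop)[0]
    k_end = int(stop[0]) if stop.size else t.size - 1
    k_end = max(k_end, 1)
    t, s_os, s_pfs, death = t[: k_end + 1], s_os[: k_end + 1], s_pfs[: k_end + 1], death[: k_end + 1]
    pfs = s_pfs
    pd_ = np.maximum(s_os - s_pfs, 0.0)

    # diagnostics: split each cycle's deaths between PFS and PD in
    # proportion to occupancy, clamped so PD inflow stays non-negative
    deaths = np.diff(death)
    pfs_exit = -np.diff(pfs)
    alive = pfs[:-1] + pd_[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(alive > 0, pfs[:-1] / np.where(alive > 0, alive, 1.0), 0.0)
    d_from_pfs = np.minimum(deaths * share, pfs_exit)
    d_from_pd = deaths - d_from_pfs
    inflow = pfs_exit - d_from_pfs
    with np.errstate(divide="ignore", invalid="ignore"):
        p_exit = np.where(pfs[:-1] > 0, pfs_exit / pfs[:-1], 0.0)
        p_pfs_death = np.where(pfs[:-1] > 0, d_from_pfs / pfs[:-1], 0.0)
        denom = pd_[:-1] + inflow
        p_pd_death = np.where(denom > 0, d_from_pd / denom, 0.0)

    return CohortTrace(
        time_months=t,
        pfs=pfs,
        pd=pd_,
        death=death,
        p_pfs_exit=p_exit,
        p_pfs_death=p_pfs_death,
        p_pd_death=p_pd_death,
        pd_inflow=inflow,
    )


def _cycle_weights(trace: CohortTrace, settings: ModelSettings) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle discount weights under the accrual convention.

    Returns (weights over cycle boundaries, discount factor at entry).
    End-of-cycle accounting zeroes the weight at t = 0; the half-cycle
    option averages start- and end-of-cycle weights.
    """
    d = settings.discount_factors(trace.time_months)
    w = np.zeros_like(d)
    if settings.half_cycle_correction:
        w[1:] += 0.5 * d[1:]
        w[:-1] += 0.5 * d[:-1]
    else:
        w[1:] = d[1:]
    return w, float(d[0])


def accrue_outcomes(
    trace: CohortTrace,
    utilities: UtilityInputs,
    ae_total_incidence: float,
    settings: ModelSettings,
) -> tuple[float, float]:
    """Discounted life-years and QALYs for one arm.

    QALYs weight PFS and PD occupancy by their utilities; the grade >= 3
    adverse-event disutility is a one-off decrement at model entry lasting
    one cycle, weighted by the arm's summed AE incidence.
    """
    u_years = settings.cycle_length_months / 12.0
    w, d0 = _cycle_weights(trace, settings)
    ly = float(np.sum(trace.alive * w) * u_years)
    qaly = float(np.sum((trace.pfs * utilities.u_pfs + trace.pd * utilities.u_pd) * w) * u_years)
    qaly -= ae_total_incidence * utilities.ae_disutility * u_years * d0
    return ly, qaly


@dataclasses.dataclass(frozen=True)
class CostBreakdown:
    drug: float
    testing: float
    adverse_events: float
    post_progression: float

    @property
    def total(self) -> float:
        return self.drug + self.testing + self.adverse_events + self.post_progression


def accrue_costs(
    trace: CohortTrace,
    costs: CostInputs,
    arm: ArmSpec,
    settings: ModelSettings,
) -> CostBreakdown:
    """Discounted cost accrual for one arm.

    Drug acquisition and testing are charged against PFS occupancy
    (treat-to-progression); adverse-event management once in the first
    cycle; post-progression care (expected mix of subsequent active
    treatment and best supportive care, weighted by
    ``p_subsequent_active``) either per cycle of PD occupancy or once per
    newly progressing cohort fraction.
    """
    w, d0 = _cycle_weights(trace, settings)
    drug_cycle = costs.drug_cost_per_cycle(arm.dosing_mg_per_cycle)
    pfs_cycles = float(np.sum(trace.pfs * w))
    drug = drug_cycle * pfs_cycles
    testing = costs.testing_per_cycle * pfs_cycles
    ae = (
        sum(
            arm.ae_incidences.get(name, 0.0) * cost
            for name, cost in costs.ae_event_costs.items()
        )
        * d0
    )
    pp_expected = (
        arm.p_subsequent_active * costs.subsequent_active_per_patient
        + (1.0 - arm.p_subsequent_active) * costs.subsequent_bsc_per_patient
    )
    if costs.post_progression_cost_mode == "per_cycle":
        post = pp_expected * float(np.sum(trace.pd * w))
    else:  # one_time: charge each newly progressing fraction once, at entry to PD
        d = settings.discount_factors(trace.time_months)
        post = pp_expected * float(np.sum(trace.pd_inflow * d[1 : trace.n_cycles + 1]))
    return CostBreakdown(drug=drug, testing=testing, adverse_events=ae, post_progression=post)


@dataclasses.dataclass(frozen=True)
class ArmResult:
    name: str
    life_years: float
    qalys: float
    cost_breakdown: CostBreakdown
    trace: CohortTrace

    @property
    def total_cost(self) -> float:
        return self.cost_breakdown.total


def run_arm(
    arm: ArmSpec,
    settings: ModelSettings,
    utilities: UtilityInputs,
    costs: CostInputs,
) -> ArmResult:
    """Evaluate one arm end to end: curves -> occupancy -> outcomes/costs."""
    pfs_curve, os_curve = arm.curves()
    trace = state_occupancy(pfs_curve, os_curve, settings)
    ly, qaly = accrue_outcomes(trace, utilities, arm.total_ae_incidence, settings)
    breakdown = accrue_costs(trace, costs, arm, settings)
    return ArmResult(name=arm.name, life_years=ly, qalys=qaly, cost_breakdown=breakdown, trace=trace)


@dataclasses.dataclass(frozen=True)
class CEResult:
    """Incremental results of intervention versus comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: float  # NaN when the denominator is zero
    icer_per_qaly: float
    nmb: float  # at the settings' willingness-to-pay
    dominance: str  # "", "intervention_dominant" or "intervention_dominated"

    @property
    def icer_defined(self) -> bool:
        return math.isfinite(self.icer_per_qaly)


def icer(intervention: ArmResult, comparator: ArmResult, settings: ModelSettings) -> CEResult:
    """Incremental cost-effectiveness of one arm over another."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_ly = intervention.life_years - comparator.life_years
    d_qaly = intervention.qalys - comparator.qalys
    per_ly = d_cost / d_ly if d_ly != 0 else math.nan
    per_qaly = d_cost / d_qaly if d_qaly != 0 else math.nan
    if d_qaly > 0 and d_cost < 0:
        dominance = "intervention_dominant"
    elif d_qaly < 0 and d_cost > 0:
        dominance = "intervention_dominated"
    else:
        dominance = ""
    return CEResult(
        intervention=intervention.name,
        comparator=comparator.name,
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_ly=per_ly,
        icer_per_qaly=per_qaly,
        nmb=d_qaly * settings.wtp - d_cost,
        dominance=dominance,
    )
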