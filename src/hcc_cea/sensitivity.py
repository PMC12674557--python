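"""Deterministic and probabilistic sensitivity analyses.

One-way analysis (tornado): each uncertain parameter is pushed to its low
and high bound with everything else at base, and the ICER swing is ranked.

Probabilistic analysis: all uncertain parameters are drawn jointly and
independently from distributions matched to their published ranges —
gamma for costs, beta for proportions/probabilities/utilities, log-normal
for hazard ratios — and both arms are re-evaluated per draw with shared
draws for shared parameters.  Acceptability curves report, per
willingness-to-pay value, the fraction of draws in which each arm has the
highest net monetary benefit.

Range convention: a published (low, high) range is read as a 95% interval,
so the standard error is (high - low) / (2 * 1.959964); beta and gamma
parameters follow by method of moments from (mean, SE) and the log-normal
takes its log-scale SE from the CI of the ratio.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import BEVA, CABO, ModelOutput, ParamSpec, default_config, param_specs, run_model
from .indirect_comparison import Z_95

__all__ = [
    "dist_from_range",
    "sample_parameters",
    "owsa",
    "psa",
    "ceac",
    "crossover_wtp",
    "PSAResult",
]


class _Degenerate:
    """Point mass; what a 'fixed' or zero-width-range parameter samples from."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        return np.full(size, self.value) if size is not None else self.value

    def mean(self) -> float:
        return self.value


def dist_from_range(spec: ParamSpec):
    """Sampling distribution for one parameter from its (low, high) range.

    Returns a frozen scipy distribution (or a point mass for ``fixed`` /
    zero-width specs).  Beta and gamma match mean and SE by method of
    moments; the log-normal has median ``base`` and log-SE from the range
    read as a ratio-scale 95% CI.
    """
    mean = spec.base
    se = (spec.high - spec.low) / (2.0 * Z_95)
    if spec.dist == "fixed" or se == 0.0:
        return _Degenerate(mean)
    if spec.dist == "beta":
        scale = spec.scale if spec.scale is not None else 1.0
        m, s = mean / scale, se / scale
        if not 0.0 < m < 1.0:
            raise ValueError(f"{spec.name}: beta mean {m} outside (0, 1)")
        nu = m * (1.0 - m) / s**2 - 1.0
        if nu <= 0:
            raise ValueError(f"{spec.name}: SE {s} infeasible for a beta with mean {m}")
        dist = stats.beta(m * nu, (1.0 - m) * nu)
        return dist if scale == 1.0 else stats.beta(m * nu, (1.0 - m) * nu, scale=scale)
    if spec.dist == "gamma":
        if mean <= 0:
            raise ValueError(f"{spec.name}: gamma requires a positive mean")
        shape = (mean / se) ** 2
        return stats.gamma(shape, scale=se**2 / mean)
    if spec.dist == "lognormal":
        sigma = (math.log(spec.high) - math.log(spec.low)) / (2.0 * Z_95)
        return stats.lognorm(sigma, scale=mean)
    raise ValueError(f"{spec.name}: unknown distribution family {spec.dist!r}")


def sample_parameters(
    specs: Sequence[ParamSpec], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` joint independent samples of every parameter (one column each)."""
    return pd.DataFrame(
        {spec.name: np.asarray(dist_from_range(spec).rvs(size=n, random_state=rng)) for spec in specs}
    )


# --------------------------------------------------------------------------
# One-way sensitivity analysis
# --------------------------------------------------------------------------


def owsa(cfg: dict | None = None, specs: Sequence[ParamSpec] | None = None) -> pd.DataFrame:
    """Tornado table: ICER per QALY at each parameter's low and high bound.

    Rows are sorted by bar width (|ICER_high - ICER_low|) descending; a row
    whose model run fails is flagged in the ``error`` column, not dropped.
    """
    cfg = cfg if cfg is not None else default_config()
    if specs is None:
        specs = param_specs(cfg)
    base_icer = run_model(cfg).ce.icer_per_qaly
    rows = []
    for spec in specs:
        row: dict = {"parameter": spec.name, "base": spec.base, "low": spec.low, "high": spec.high}
        for bound, key in ((spec.low, "icer_low"), (spec.high, "icer_high")):
            try:
                row[key] = run_model(cfg, overrides={spec.name: bound}).ce.icer_per_qaly
            except Exception as exc:  # model failure at an extreme: flag, keep row
                row[key] = math.nan
                row["error"] = str(exc)
        row["width"] = abs(row["icer_high"] - row["icer_low"])
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("width", ascending=False, ignore_index=True)
    df.attrs["base_icer"] = base_icer
    return df


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PSAResult:
    """Per-draw (cost, effect) pairs for both arms plus sampling metadata."""

    samples: pd.DataFrame  # draw, then cost_<arm>, qaly_<arm> columns
    parameters: pd.DataFrame  # the sampled parameter matrix
    n_resampled: int
    seed: int

    @property
    def arms(self) -> list[str]:
        return [c.removeprefix("cost_") for c in self.samples.columns if c.startswith("cost_")]

    def incremental(self) -> pd.DataFrame:
        """Incremental (delta_cost, delta_qaly) of atezo-beva vs atezo-cabo."""
        return pd.DataFrame(
            {
                "delta_cost": self.samples[f"cost_{BEVA}"] - self.samples[f"cost_{CABO}"],
                "delta_qaly": self.samples[f"qaly_{BEVA}"] - self.samples[f"qaly_{CABO}"],
            }
        )


def psa(
    cfg: dict | None = None,
    n_iter: int = 10_000,
    seed: int = 1,
    specs: Sequence[ParamSpec] | None = None,
    include_discount: bool = False,
) -> PSAResult:
    """Monte Carlo parameter uncertainty analysis.

    Every uncertain parameter is drawn jointly per iteration and both arms
    are evaluated on the same draw (shared utilities, costs, baseline
    curves).  The discount rate is held at base by default.  A draw whose
    model evaluation fails is resampled (and counted).
    """
    cfg = cfg if cfg is not None else default_config()
    if specs is None:
        specs = param_specs(cfg, include_discount=include_discount)
    rng = np.random.default_rng(seed)
    params = sample_parameters(specs, n_iter, rng)
    records = []
    n_resampled = 0
    i = 0
    while i < n_iter:
        overrides = {name: float(params.iloc[i][name]) for name in params.columns}
        try:
            out = run_model(cfg, overrides=overrides)
        except Exception:
            n_resampled += 1
            if n_resampled > 100 + n_iter:
                raise RuntimeError("PSA: excessive model failures during resampling")
            redraw = sample_parameters(specs, 1, rng)
            params.iloc[i] = redraw.iloc[0]
            continue
        rec = {"draw": i}
        for name, res in out.arms.items():
            rec[f"cost_{name}"] = res.total_cost
            rec[f"qaly_{name}"] = res.qalys
        records.append(rec)
        i += 1
    return PSAResult(
        samples=pd.DataFrame(records),
        parameters=params,
        n_resampled=n_resampled,
        seed=seed,
    )


def ceac(result: PSAResult, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    Per WTP value, the probability that each arm has the maximal net
    monetary benefit (exact ties split equally across the tied arms).
    """
    if len(result.samples) == 0:
        raise ValueError("CEAC requires at least one valid PSA draw")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 2_000_000.0 + 1.0, 10_000.0)
    arms = result.arms
    costs = np.column_stack([result.samples[f"cost_{a}"].to_numpy() for a in arms])
    qalys = np.column_stack([result.samples[f"qaly_{a}"].to_numpy() for a in arms])
    out = {"wtp": wtp_grid}
    probs = np.zeros((len(wtp_grid), len(arms)))
    for i, w in enumerate(wtp_grid):
        nmb = qalys * w - costs
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    for j, a in enumerate(arms):
        out[f"p_{a}"] = probs[:, j]
    return pd.DataFrame(out)


def crossover_wtp(ceac_df: pd.DataFrame, arm_a: str = BEVA, arm_b: str = CABO) -> float | None:
    """WTP at which the two arms' acceptability curves cross.

    Linear interpolation within the first grid interval where the sign of
    ``p_a - p_b`` changes; ``None`` when the curves never cross on the grid.
    """
    diff = (ceac_df[f"p_{arm_a}"] - ceac_df[f"p_{arm_b}"]).to_numpy()
    wtp = ceac_df["wtp"].to_numpy()
    if diff[0] == 0.0:
        return float(wtp[0])
    sign_change = np.nonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)[0]
    exact_zero = np.nonzero(diff == 0.0)[0]
    candidates = []
    if sign_change.size:
        i = int(sign_change[0])
        frac = diff[i] / (diff[i] - diff[i + 1])
        candidates.append(float(wtp[i] + frac * (wtp[i + 1] - wtp[i])))
    if exact_zero.size:
        candidates.append(float(wtp[exact_zero[0]]))
    return min(candidates) if candidates else None
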