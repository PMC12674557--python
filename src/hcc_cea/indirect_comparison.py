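"""Anchored indirect comparison of hazard ratios (Bucher method).

Two treatments never compared head-to-head are compared through a common
anchor (here: each combination regimen's trial used sorafenib as control).
On the log scale the anchored contrast is the difference of the two trials'
log hazard ratios and its variance the sum of their variances; for a
two-trial star network this analytic fixed-effects estimate coincides with
the network estimate under a normal model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import pandas as pd

__all__ = ["Z_95", "HRSummary", "hr_from_ci", "bucher_indirect", "read_trial_summaries"]

#: two-sided 95% normal quantile
Z_95 = 1.959964


@dataclasses.dataclass(frozen=True)
class HRSummary:
    """A hazard ratio with its 95% confidence interval (ratio scale).

    The log-scale standard error is recovered from the CI width under
    log-normality: ``se = (ln hi - ln lo) / (2 * 1.959964)``.
    """

    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if min(self.point, self.ci_low, self.ci_high) <= 0:
            raise ValueError("hazard ratios and CI bounds must be positive")
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError(
                f"CI must bracket the point estimate: {self.ci_low} <= {self.point} <= {self.ci_high}"
            )
        if self.ci_low == self.ci_high:
            raise ValueError("degenerate CI: cannot derive a standard error from zero width")

    @property
    def log_hr(self) -> float:
        return math.log(self.point)

    @property
    def se_log_hr(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2.0 * Z_95)

    def to_dict(self) -> dict:
        return {
            "hr": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_hr": self.log_hr,
            "se_log_hr": self.se_log_hr,
        }


def hr_from_ci(point: float, ci_low: float, ci_high: float) -> HRSummary:
    """Build an :class:`HRSummary` from a published point estimate and CI."""
    return HRSummary(point=point, ci_low=ci_low, ci_high=ci_high)


def bucher_indirect(ab_vs_anchor: HRSummary, ac_vs_anchor: HRSummary) -> HRSummary:
    """Anchored comparison of B versus C through their common comparator A.

    Returns the hazard ratio of the first treatment versus the second:
    ``log HR = log HR(B vs A) - log HR(C vs A)``, variances added, 95% CI
    by normal quantiles.
    """
    log_hr = ab_vs_anchor.log_hr - ac_vs_anchor.log_hr
    se = math.sqrt(ab_vs_anchor.se_log_hr**2 + ac_vs_anchor.se_log_hr**2)
    return HRSummary(
        point=math.exp(log_hr),
        ci_low=math.exp(log_hr - Z_95 * se),
        ci_high=math.exp(log_hr + Z_95 * se),
    )


def read_trial_summaries(path: str | Path) -> pd.DataFrame:
    """Read a trial-summary CSV: trial, comparison, endpoint, hr, ci_low, ci_high."""
    df = pd.read_csv(path)
    required = {"trial", "comparison", "endpoint", "hr", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial summary CSV missing columns: {sorted(missing)}")
    return df


def indirect_from_summaries(df: pd.DataFrame, endpoint: str) -> HRSummary:
    """Anchored comparison for one endpoint from a two-row summary table."""
    rows = df[df["endpoint"] == endpoint]
    if len(rows) != 2:
        raise ValueError(f"need exactly two trial rows for endpoint {endpoint!r}, got {len(rows)}")
    first, second = (hr_from_ci(r.hr, r.ci_low, r.ci_high) for r in rows.itertuples())
    return bucher_indirect(first, second)


def write_indirect_results(results: dict[str, HRSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in results.items()}, fh, indent=2)
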