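"""Group comparisons and correlation battery.

Demographics and vortex metrics are compared between groups with the
Mann-Whitney-Wilcoxon rank-sum test; relationships between physiological and
vortex parameters use ordinary least-squares linear correlation (R^2 =
squared Pearson r, p from the t distribution on n-2 df). Family-wise error
across the correlation battery is controlled with Bonferroni correction
(threshold alpha / n_tests; the canonical battery of 8 covariates x 2
outcomes x 2 groups = 32 analyses gives 0.05 / 32 = 0.0015625).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError

__all__ = [
    "RankSumResult",
    "CorrelationResult",
    "StatsReport",
    "rank_sum_test",
    "linear_correlation",
    "bonferroni_threshold",
    "correlation_battery",
    "TABLE3_COVARIATES",
    "TABLE3_OUTCOMES",
]

# canonical battery: per-subject covariates against the two vortex outcomes
TABLE3_COVARIATES = [
    "body_surface_area",
    "age",
    "heart_rate",
    "end_diastolic_volume",
    "stroke_volume",
    "ejection_fraction",
    "peak_filling_rate",
    "e_peak_velocity",
]
TABLE3_OUTCOMES = ["ed_vortex_volume", "ed_vv_percent"]


@dataclass
class RankSumResult:
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str  # "exact" or "asymptotic"


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class StatsReport:
    """Comparison/correlation rows plus the family-wise threshold."""

    comparisons: pd.DataFrame
    alpha: float = 0.05
    n_tests: int = 1
    threshold: float = dataclass_field(init=False)

    def __post_init__(self):
        self.threshold = bonferroni_threshold(self.alpha, self.n_tests)
        if "p_value" in self.comparisons.columns and len(self.comparisons):
            self.comparisons = self.comparisons.assign(
                significant=self.comparisons["p_value"] < self.threshold
            )


def rank_sum_test(
    group_a, group_b, continuity: bool = True
) -> RankSumResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    The exact null distribution is used for combined n <= 20 without ties;
    otherwise the normal approximation with tie correction (and, by default,
    continuity correction) applies — the study's group sizes (16 and 23) fall
    in the approximation regime.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DomainError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) + len(b) <= 20) and not has_ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    return RankSumResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        method="exact" if exact else "asymptotic",
    )


def linear_correlation(x, y) -> CorrelationResult:
    """OLS linear correlation: slope, intercept, R^2 and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DomainError("need matched x/y with at least 3 observations")
    if np.ptp(x) == 0:
        raise DomainError("x has zero variance")
    if np.ptp(y) == 0:
        # a constant outcome carries no linear association
        return CorrelationResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=len(x)
        )
    res = sps.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise DomainError("n_tests must be at least 1")
    return alpha / n_tests


def correlation_battery(
    per_subject: pd.DataFrame,
    covariates: list[str] | None = None,
    outcomes: list[str] | None = None,
    group_column: str = "group",
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> StatsReport:
    """Run the covariate x outcome x group correlation battery.

    One OLS correlation per (group, outcome, covariate) cell, mirroring the
    declarative structure of the clinical table; ``n_tests`` defaults to the
    number of cells attempted (32 for the canonical battery). Cells with
    missing columns or fewer than 3 complete observations are reported with
    NaN results rather than silently dropped from the count.
    """
    covariates = covariates if covariates is not None else TABLE3_COVARIATES
    outcomes = outcomes if outcomes is not None else TABLE3_OUTCOMES
    groups = sorted(per_subject[group_column].unique())
    rows = []
    for group in groups:
        sub = per_subject[per_subject[group_column] == group]
        for outcome in outcomes:
            for cov in covariates:
                row = {
                    "group": group,
                    "outcome": outcome,
                    "covariate": cov,
                    "n": 0,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "r_squared": np.nan,
                    "p_value": np.nan,
                }
                if cov in sub.columns and outcome in sub.columns:
                    pair = sub[[cov, outcome]].dropna()
                    if len(pair) >= 3 and np.ptp(pair[cov].to_numpy()) > 0:
                        res = linear_correlation(pair[cov], pair[outcome])
                        row.update(
                            n=res.n,
                            slope=res.slope,
                            intercept=res.intercept,
                            r_squared=res.r_squared,
                            p_value=res.p_value,
                        )
                rows.append(row)
    table = pd.DataFrame(rows)
    return StatsReport(
        comparisons=table,
        alpha=alpha,
        n_tests=n_tests if n_tests is not None else len(rows),
    )
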