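"""Cohort-level descriptive statistics.

Three small procedures cover the baseline comparisons reported for the
cohort: a continuity-corrected Wald difference of two proportions with 95%
CI (e.g. prior metered-dose-inhaler experience between the DPI-experienced
and DPI-naive strata), Pearson chi-squared tests for categorical baselines,
and one-way ANOVA reconstructed from group summary statistics (mean, SD, n)
as printed in baseline tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z_95 = 1.96  # conventional two-sided 95% normal quantile


@dataclass(frozen=True)
class PropComparison:
    p1: float
    n1: int
    p2: float
    n2: int
    delta: float      # percentage points
    ci_low: float
    ci_high: float
    p_value: float
    method: str


def prop_diff_ci(p1: float, n1: int, p2: float, n2: int) -> PropComparison:
    """Difference of two independent proportions, continuity-corrected Wald CI.

    delta = 100 (p1 - p2) in percentage points;
    CI = delta +/- [z * sqrt(p1 q1/n1 + p2 q2/n2) + (1/n1 + 1/n2)/2] * 100,
    clipped to [-100, 100].  The attached two-sided p-value is the Yates
    continuity-corrected chi-squared test on the implied 2x2 table, matching
    the continuity-corrected interval.

    Proportions may be passed as rounded percentages-on-[0,1]; counts are
    reconstructed by rounding p*n to the nearest integer.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    delta = 100.0 * (p1 - p2)
    half = (
        Z_95 * np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        + 0.5 * (1.0 / n1 + 1.0 / n2)
    ) * 100.0
    lo = max(delta - half, -100.0)
    hi = min(delta + half, 100.0)
    x1, x2 = round(p1 * n1), round(p2 * n2)
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() <= 0 or table.sum(axis=1).min() <= 0:
        p_value = float("nan")
    else:
        _, p_value, _, _ = stats.chi2_contingency(table, correction=True)
    return PropComparison(
        p1=p1, n1=n1, p2=p2, n2=n2,
        delta=delta, ci_low=lo, ci_high=hi,
        p_value=float(p_value),
        method="wald-cc",
    )


def prop_diff_ci_from_counts(x1: int, n1: int, x2: int, n2: int) -> PropComparison:
    """Counts-first entry point (preferred over rounded percentages)."""
    return prop_diff_ci(x1 / n1, n1, x2 / n2, n2)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared test (no continuity correction) on an r x c table.

    Returns (statistic, df, p_value); df = (r-1)(c-1).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: zero marginal row/column")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def anova_from_summary(means, sds, ns) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group summary statistics.

    Between-group SS from the group means and sizes, within-group SS from the
    SDs; identical to classic ANOVA on the raw data.  Returns
    (F, df_between, df_within, p_value).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (len(means) == len(sds) == len(ns)):
        raise ValueError("means, sds and ns must have equal length")
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(sds <= 0):
        raise ValueError("sds must be positive")
    grand = float(np.sum(ns * means) / ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df1 = len(means) - 1
    df2 = int(ns.sum()) - len(means)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p
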