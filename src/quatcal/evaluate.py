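"""Recovery statistics, outlier rejection and method-comparison tests.

Recovery % (100 x predicted/actual) is the primary accuracy measure.
Validation recoveries outside a configurable acceptance band (default
97.0-104.5 %) are flagged and excluded from the summary mean/SD; a Dixon
Q-test is available as an alternative rejection rule.  Method comparison
uses the classic pooled-variance two-sample t test and the variance-ratio
F test against their two-tailed / upper-tail critical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RecoveryEntry", "RegressionSummary", "StatsComparison",
           "recovery_percent", "reject_outliers", "dixon_q_flags",
           "summarize_recoveries", "fit_pred_vs_actual", "two_sample_t",
           "f_ratio", "critical_values", "compare_methods",
           "DEFAULT_REJECTION_BAND"]

#: Default recovery acceptance band (%): entries outside are excluded.
DEFAULT_REJECTION_BAND = (97.0, 104.5)

# Two-tailed Dixon Q critical values at alpha = 0.05, n = 3..10.
_DIXON_Q95 = {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
              8: 0.526, 9: 0.493, 10: 0.466}


def recovery_percent(predicted: float, actual: float) -> float:
    """100 x predicted / actual."""
    if actual <= 0:
        raise ValueError("invalid-input: actual concentration must be positive")
    return 100.0 * predicted / actual


def reject_outliers(recoveries, band=DEFAULT_REJECTION_BAND):
    """Flag recoveries outside [band.low, band.high] %.

    Returns (kept_values, rejected_flags); flags align with the input
    order.  Raises if nothing survives.
    """
    low, high = band
    if low >= high:
        raise ValueError("invalid-input: band.low must be below band.high")
    rec = np.asarray(list(recoveries), dtype=float)
    flags = (rec < low) | (rec > high)
    kept = rec[~flags]
    if kept.size == 0:
        raise ValueError("empty-after-rejection: every recovery was rejected")
    return kept, flags


def dixon_q_flags(values, alpha: float = 0.05) -> np.ndarray:
    """Dixon Q test on the most extreme value (n = 3..10), single pass."""
    if alpha != 0.05:
        raise ValueError("invalid-input: Dixon table available at alpha = 0.05 only")
    v = np.asarray(list(values), dtype=float)
    flags = np.zeros(v.size, dtype=bool)
    if not 3 <= v.size <= 10:
        return flags
    order = np.argsort(v)
    s = v[order]
    span = s[-1] - s[0]
    if span == 0:
        return flags
    q_low = (s[1] - s[0]) / span
    q_high = (s[-1] - s[-2]) / span
    qc = _DIXON_Q95[v.size]
    if q_high >= q_low and q_high > qc:
        flags[order[-1]] = True
    elif q_low > q_high and q_low > qc:
        flags[order[0]] = True
    return flags


def summarize_recoveries(kept) -> tuple[float, float]:
    """Mean and SD (n-1 denominator) of the kept recoveries, %."""
    kept = np.asarray(list(kept), dtype=float)
    if kept.size < 2:
        raise ValueError("insufficient-data: need at least two kept recoveries")
    return float(kept.mean()), float(kept.std(ddof=1))


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r: float
    n: int


def fit_pred_vs_actual(predicted, actual) -> RegressionSummary:
    """OLS line predicted = slope·actual + intercept, with Pearson r."""
    pred = np.asarray(list(predicted), dtype=float)
    act = np.asarray(list(actual), dtype=float)
    if pred.size != act.size or pred.size < 3:
        raise ValueError("invalid-input: need >= 3 paired values")
    if np.ptp(act) == 0:
        raise ValueError("degenerate-regression: actual values are constant")
    res = stats.linregress(act, pred)
    return RegressionSummary(float(res.slope), float(res.intercept),
                             float(res.rvalue), pred.size)


def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int) -> float:
    """Pooled-variance two-sample |t| with df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("invalid-input: each group needs n >= 2")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    if sp2 == 0:
        if mean1 == mean2:
            return 0.0
        raise ValueError("infinite-statistic: zero pooled variance with unequal means")
    return float(abs(mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def f_ratio(variance1: float, variance2: float) -> float:
    """Variance ratio with the larger variance in the numerator (F >= 1)."""
    if variance1 <= 0 or variance2 <= 0:
        raise ValueError("invalid-input: variances must be positive")
    return float(max(variance1, variance2) / min(variance1, variance2))


def critical_values(alpha: float, n1: int, n2: int) -> tuple[float, float]:
    """(two-tailed t critical at df = n1+n2-2, upper-tail F at (n1-1, n2-1))."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("invalid-input: alpha must lie in (0, 1)")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, n1 + n2 - 2))
    f_crit = float(stats.f.ppf(1.0 - alpha, n1 - 1, n2 - 1))
    return t_crit, f_crit


@dataclass(frozen=True)
class StatsComparison:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t_statistic: float
    f_statistic: float
    t_critical: float
    f_critical: float
    alpha: float

    @property
    def significant(self) -> bool:
        """True unless both t and F fall below their critical values."""
        return not (self.t_statistic < self.t_critical
                    and self.f_statistic < self.f_critical)


def compare_methods(group1, group2, alpha: float = 0.05) -> StatsComparison:
    """t/F comparison of two recovery groups (raw % values in, stats out)."""
    g1 = np.asarray(list(group1), dtype=float)
    g2 = np.asarray(list(group2), dtype=float)
    m1, s1 = float(g1.mean()), float(g1.std(ddof=1))
    m2, s2 = float(g2.mean()), float(g2.std(ddof=1))
    t_stat = two_sample_t(m1, s1, len(g1), m2, s2, len(g2))
    f_stat = f_ratio(s1 ** 2, s2 ** 2) if s1 > 0 and s2 > 0 else 1.0
    t_crit, f_crit = critical_values(alpha, len(g1), len(g2))
    return StatsComparison(m1, s1, len(g1), m2, s2, len(g2),
                           t_stat, f_stat, t_crit, f_crit, alpha)
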