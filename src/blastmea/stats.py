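"""Group-comparison statistics for exposure experiments.

The experimental design crosses exposure frequency (control / low / mid /
high) with peak amplitude (250 / 350 kPa) and timepoint (1 h / 24 h),
n organoids per group.  Group values are reported as mean +/- SEM after
iterative Grubbs outlier exclusion, normalized either as percent of the
control-group mean or as percent difference from a baseline.  Hypothesis
tests: two-tailed Student's (or Welch's) t-test, one-way ANOVA with Tukey's
HSD for multiple comparisons, and Pearson's chi-squared on count tables for
datasets whose control measures zero (where ratio normalization is
undefined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

__all__ = [
    "GroupResult",
    "TestReport",
    "NormalizedValues",
    "percent_of_control",
    "percent_difference",
    "grubbs_exclude",
    "grubbs_critical_value",
    "two_sample_ttest",
    "one_way_anova_tukey",
    "chi_squared_counts",
    "summarize_group",
]


@dataclass
class GroupResult:
    """One experimental group's values and mean +/- SEM summary.

    ``n`` counts retained (post-Grubbs) values only; ``sem`` is the sample
    SD of the retained values over sqrt(n).
    """

    label: str
    raw_values: np.ndarray
    normalized_values: np.ndarray
    mean: float
    sem: float
    n: int
    excluded_indices: list[int] = field(default_factory=list)


@dataclass
class TestReport:
    """Result of one hypothesis test.

    ``df`` is a tuple for ANOVA (between, within) and a scalar otherwise.
    ``tukey`` holds pairwise rows ``{'pair': (i, j), 'mean_diff': ...,
    'p_adj': ...}`` when applicable.
    """

    test: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    tukey: list[dict] | None = None


@dataclass
class NormalizedValues:
    """Values on a normalized scale plus how to treat them downstream.

    ``mode`` is ``percent_difference`` normally; when the baseline is zero
    the percent scale is undefined, the absolute differences are returned
    instead (``mode='absolute_difference'``) and ``use_chi_squared`` directs
    significance testing to the count-based chi-squared path.
    """

    values: np.ndarray
    mode: str
    use_chi_squared: bool = False


def percent_of_control(
    values: np.ndarray, control_values: np.ndarray
) -> np.ndarray:
    """Each value as a percentage of the control-group mean (100 = control)."""
    values = np.asarray(values, dtype=np.float64)
    control = np.asarray(control_values, dtype=np.float64)
    if control.size == 0:
        raise ValueError("control group is empty")
    mean = float(control.mean())
    if mean <= 0:
        raise ValueError(
            f"control mean must be positive for percent-of-control "
            f"normalization (got {mean}); for zero controls use "
            "percent_difference / chi_squared_counts"
        )
    return 100.0 * values / mean


def percent_difference(values: np.ndarray, baseline: float) -> NormalizedValues:
    """100 x (value - baseline) / baseline relative to a scalar baseline.

    A zero baseline makes the percent scale undefined: the absolute
    differences are returned flagged for the chi-squared route instead.
    """
    values = np.asarray(values, dtype=np.float64)
    if baseline < 0:
        raise ValueError(f"baseline must be non-negative, got {baseline}")
    if baseline == 0:
        warnings.warn(
            "baseline is zero: percent difference undefined; returning "
            "absolute differences and flagging the chi-squared route",
            stacklevel=2,
        )
        return NormalizedValues(
            values=values.copy(), mode="absolute_difference", use_chi_squared=True
        )
    return NormalizedValues(
        values=100.0 * (values - baseline) / baseline, mode="percent_difference"
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    ``G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))`` with ``t`` the
    upper ``alpha / (2n)`` quantile of Student's t with n-2 df.
    """
    if n < 3:
        raise ValueError(f"Grubbs' test requires n >= 3, got {n}")
    t = sst.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_exclude(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iterative two-sided Grubbs outlier exclusion.

    Each iteration computes ``G = max |x - mean| / sd`` and removes the one
    most extreme point if G exceeds the critical value, repeating until no
    rejection (or fewer than 3 points remain).  Returns the retained values
    and the excluded indices into the *original* array.  Fewer than 3
    values, or zero variance, is a no-op.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 3:
        warnings.warn(
            f"Grubbs' test needs n >= 3 (got {values.size}); no exclusion",
            stacklevel=2,
        )
        return values.copy(), []
    indices = np.arange(values.size)
    retained = values.copy()
    excluded: list[int] = []
    while retained.size >= 3:
        sd = retained.std(ddof=1)
        if sd == 0:
            break
        deviations = np.abs(retained - retained.mean())
        worst = int(np.argmax(deviations))
        g = deviations[worst] / sd
        if g <= grubbs_critical_value(retained.size, alpha):
            break
        excluded.append(int(indices[worst]))
        retained = np.delete(retained, worst)
        indices = np.delete(indices, worst)
    return retained, excluded


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> TestReport:
    """Two-tailed two-sample t-test (Student by default, Welch by flag)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    res = sst.ttest_ind(a, b, equal_var=not welch)
    return TestReport(
        test="welch_ttest" if welch else "student_ttest",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def one_way_anova_tukey(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    tukey: bool = True,
) -> TestReport:
    """One-way ANOVA F-test with optional Tukey HSD pairwise comparisons.

    F has (k-1, N-k) degrees of freedom; Tukey adjusted p-values come from
    the studentized-range distribution.  Degenerate all-identical groups
    yield F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    for label, g in zip(labels, arrays):
        if g.size < 2:
            raise ValueError(f"group {label!r} has n = {g.size} < 2")
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    f_stat, p = sst.f_oneway(*arrays)
    if np.isnan(f_stat):  # zero within- and between-group variance
        f_stat, p = 0.0, 1.0
    report = TestReport(
        test="one_way_anova",
        statistic=float(f_stat),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(p),
    )
    if tukey:
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
        hsd = sst.tukey_hsd(*arrays) if ss_within > 0 else None
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(np.mean(arrays[i]) - np.mean(arrays[j]))
                if hsd is not None:
                    p_adj = float(hsd.pvalue[i, j])
                else:  # no within-group variance: means equal <=> p = 1
                    p_adj = 1.0 if diff == 0 else 0.0
                rows.append(
                    {"pair": (labels[i], labels[j]), "mean_diff": diff,
                     "p_adj": p_adj}
                )
        report.tukey = rows
    return report


def chi_squared_counts(table: np.ndarray) -> TestReport:
    """Pearson's chi-squared test of independence on a count table.

    ``X^2 = sum (O - E)^2 / E`` with expectations from the row/column
    margins and ``df = (rows - 1)(cols - 1)``; no continuity correction.
    Used for presence/absence counts when controls measure zero.
    """
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be 2-D with at least 2 rows and 2 columns")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must contain non-negative integer counts")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total <= 0:
        raise ValueError("table has no counts")
    expected = row @ col / total
    if np.any(expected == 0):
        raise ValueError(
            "degenerate margin: an expected count is 0; drop the empty "
            "row/column before testing"
        )
    x2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return TestReport(
        test="pearson_chi_squared",
        statistic=x2,
        df=float(df),
        p_value=float(sst.chi2.sf(x2, df)),
    )


def summarize_group(
    label: str,
    raw_values: np.ndarray,
    control_values: np.ndarray | None = None,
    grubbs_alpha: float | None = 0.05,
) -> GroupResult:
    """Mean +/- SEM summary of one group after outlier exclusion.

    Grubbs exclusion runs on the raw values; if ``control_values`` is given
    the retained values are reported as percent of the control mean,
    otherwise on their raw scale.
    """
    raw_values = np.asarray(raw_values, dtype=np.float64)
    if grubbs_alpha is not None and raw_values.size >= 3:
        retained, excluded = grubbs_exclude(raw_values, grubbs_alpha)
    else:
        retained, excluded = raw_values.copy(), []
    if control_values is not None:
        normalized = percent_of_control(retained, control_values)
    else:
        normalized = retained
    n = normalized.size
    mean = float(normalized.mean()) if n else float("nan")
    sem = float(normalized.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return GroupResult(
        label=label,
        raw_values=raw_values,
        normalized_values=normalized,
        mean=mean,
        sem=sem,
        n=n,
        excluded_indices=excluded,
    )
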