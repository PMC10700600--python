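"""Group-level statistics: normality-gated paired tests, unpaired t-test,
percent differences, and per-group summaries.

Method agreement (prediction vs ground truth) uses a paired t-test when
the Shapiro-Wilk test does not reject normality of the paired
differences at alpha, otherwise the Wilcoxon signed-rank test.  Group
differences (case vs control) use the two-sided pooled-variance
(Student) unpaired t-test.  Percent difference is reported relative to
the control mean, both to one decimal and rounded to the nearest
integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volumetry import SubjectRecord

__all__ = ["TestResult", "PercentDifference", "gated_paired_test",
           "unpaired_test", "percent_difference", "group_summary"]


@dataclass(frozen=True)
class TestResult:
    test_name: str              # paired_t | wilcoxon_signed_rank | unpaired_t | degenerate
    statistic: Optional[float]
    p_value: Optional[float]
    n: Optional[int] = None
    n1: Optional[int] = None
    n2: Optional[int] = None
    normality_p: Optional[float] = None


def gated_paired_test(values_a, values_b, alpha: float = 0.05) -> TestResult:
    """Paired comparison with a Shapiro-Wilk normality gate on differences.

    If the differences are compatible with normality (SW p >= alpha) a
    paired t-test is used, otherwise the Wilcoxon signed-rank test; the
    chosen branch is recorded in ``test_name``.  Zero-variance
    differences yield a degenerate report without a fabricated p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D series of equal length required")
    if len(a) < 3:
        raise ValueError("paired test requires n >= 3")
    d = a - b
    if np.ptp(d) == 0:
        return TestResult(test_name="degenerate", statistic=None,
                          p_value=None, n=len(d))
    sw_stat, sw_p = stats.shapiro(d)
    if sw_p >= alpha:
        t_stat, p = stats.ttest_rel(a, b)
        return TestResult(test_name="paired_t", statistic=float(t_stat),
                          p_value=float(p), n=len(d), normality_p=float(sw_p))
    w_stat, p = stats.wilcoxon(a, b)
    return TestResult(test_name="wilcoxon_signed_rank", statistic=float(w_stat),
                      p_value=float(p), n=len(d), normality_p=float(sw_p))


def unpaired_test(group_a, group_b) -> TestResult:
    """Two-sided pooled-variance (Student) unpaired t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("unpaired test requires n >= 2 per group")
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(test_name="unpaired_t", statistic=float(t_stat),
                      p_value=float(p), n1=len(a), n2=len(b))


@dataclass(frozen=True)
class PercentDifference:
    """Relative reduction of the case mean vs the control mean, percent."""

    percent: float
    one_decimal: float
    nearest_int: int


def percent_difference(mean_control: float,
                       mean_case: float) -> PercentDifference:
    """(control - case) / control * 100; positive = case reduced."""
    if mean_control <= 0:
        raise ValueError("control mean must be > 0")
    pct = (mean_control - mean_case) / mean_control * 100.0
    return PercentDifference(percent=pct, one_decimal=round(pct, 1),
                             nearest_int=int(round(pct)))


def group_summary(records: Sequence[SubjectRecord],
                  value: str = "v_norm") -> pd.DataFrame:
    """Per-group n, mean, sample SD (n-1), and median over accepted records.

    SD is reported as NaN for single-subject groups (undefined), never 0.
    """
    accepted = [r for r in records if r.qc_status == "accepted"]
    groups = sorted({r.group for r in records})
    rows = []
    for group in groups:
        vals = np.array([getattr(r, value) for r in accepted
                         if r.group == group], dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {group!r} has no accepted records")
        rows.append(dict(
            group=group, n=int(vals.size), mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            median=float(np.median(vals))))
    return pd.DataFrame(rows).set_index("group")
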