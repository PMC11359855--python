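"""Group summaries and the two-sample Student's t-test.

Reporter-assay results are reported as mean ± standard error per group
(typically triplicates) and compared between transduced and control
conditions with the classical pooled-variance Student's t-test,
two-sided.  The standard error uses the n-1 sample standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "TTestResult", "summarize_group", "student_t_test", "compare_groups"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± standard error of one group of psq measurements.

    ``se`` is ``sd / sqrt(n)`` with the (n-1)-denominator sample sd; it is
    ``None`` for a single measurement, where the standard error is
    undefined.
    """

    label: str
    n: int
    mean: float
    se: float | None


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t-test outcome.

    With zero pooled variance the statistic degenerates: equal means give
    ``t = 0, p = 1``; unequal means give an infinite ``t`` (signed) and
    ``p = 0``, flagged by ``infinite_t``.
    """

    t_statistic: float
    df: int
    p_value: float

    @property
    def infinite_t(self) -> bool:
        return math.isinf(self.t_statistic)


def summarize_group(values, label: str = "group") -> GroupSummary:
    """Arithmetic mean and standard error of a list of measurements."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError(f"group {label!r} has no values to summarize")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
    return GroupSummary(label=label, n=int(vals.size), mean=mean, se=se)


def student_t_test(a, b) -> TTestResult:
    """Two-sided pooled-variance Student's t-test between two groups.

    ``t = (mean_a - mean_b) / (s_p * sqrt(1/n1 + 1/n2))`` with the pooled
    variance ``s_p^2 = ((n1-1) s_a^2 + (n2-1) s_b^2) / (n1 + n2 - 2)`` and
    ``df = n1 + n2 - 2`` degrees of freedom.
    """
    va = np.asarray(list(a), dtype=np.float64)
    vb = np.asarray(list(b), dtype=np.float64)
    if va.size < 2 or vb.size < 2:
        raise ValueError(
            f"each group needs at least 2 values, got {va.size} and {vb.size}"
        )
    n1, n2 = va.size, vb.size
    df = int(n1 + n2 - 2)
    diff = float(va.mean() - vb.mean())
    sp2 = ((n1 - 1) * va.var(ddof=1) + (n2 - 1) * vb.var(ddof=1)) / df
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(t_statistic=0.0, df=df, p_value=1.0)
        return TTestResult(
            t_statistic=math.copysign(math.inf, diff), df=df, p_value=0.0
        )
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t_statistic=float(t), df=df, p_value=min(p, 1.0))


def compare_groups(
    results: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "total_area_psq",
) -> tuple[list[GroupSummary], TTestResult]:
    """Summarize a two-group results table and test the group difference.

    The table must contain exactly two group labels; summaries are
    returned in first-appearance order and the t-test compares the first
    group minus the second.
    """
    labels = list(dict.fromkeys(results[group_col]))
    if len(labels) != 2:
        raise ValueError(
            f"expected exactly 2 groups in column {group_col!r}, got {labels}"
        )
    values = {
        lab: results.loc[results[group_col] == lab, value_col].to_numpy(dtype=float)
        for lab in labels
    }
    summaries = [summarize_group(values[lab], label=str(lab)) for lab in labels]
    for s in summaries:
        if s.n < 2:
            raise ValueError(
                f"group {s.label!r} has only {s.n} measurement(s); "
                "at least 2 per group are required for the t-test"
            )
    test = student_t_test(values[labels[0]], values[labels[1]])
    return summaries, test
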