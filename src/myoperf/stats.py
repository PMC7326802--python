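"""Group statistics: mean ± SD summaries, Student's t-tests, linear regression.

The statistical layer mirrors a conventional small-animal imaging
analysis: groups are summarised as mean ± sample SD, two-group contrasts
use the classical Student's t-test (pooled variance when unpaired,
difference-based when paired; Welch available behind a flag), and
cross-tracer agreement is assessed by ordinary least squares with the
Pearson correlation and its t-distribution p-value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "RegressionResult",
    "summarize",
    "t_test",
    "linear_regression",
    "r_to_p",
    "write_stats_report_json",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, and sample SD (ddof=1; None when n == 1)."""

    n: int
    mean: float
    sd: float | None

    def __str__(self) -> str:
        sd = "NA" if self.sd is None else f"{self.sd:.4g}"
        return f"{self.mean:.4g} ± {sd} (n={self.n})"


@dataclass(frozen=True)
class TestResult:
    """Two-sided t-test outcome."""

    statistic: float
    degrees_of_freedom: float
    p_value: float
    paired: bool
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit y = a*x + b with Pearson r and its two-sided p-value."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


def summarize(values) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else None
    return GroupSummary(n=int(v.size), mean=float(v.mean()), sd=sd)


def t_test(a, b, paired: bool = False, equal_var: bool = True) -> TestResult:
    """Student's t-test between two groups.

    Unpaired uses the pooled-variance statistic (set ``equal_var=False``
    for Welch); paired tests the within-pair differences.  Degenerate
    inputs (zero-variance differences or pooled variance) are flagged:
    an exactly-zero mean difference yields t=0, p=1, otherwise the
    statistic is infinite with p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        d = a - b
        if np.std(d, ddof=1) == 0.0:
            if d.mean() == 0.0:
                return TestResult(0.0, float(a.size - 1), 1.0, True, degenerate=True)
            return TestResult(math.copysign(math.inf, d.mean()), float(a.size - 1), 0.0, True, degenerate=True)
        res = sps.ttest_rel(a, b)
        return TestResult(float(res.statistic), float(res.df), float(res.pvalue), True)
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        df = float(a.size + b.size - 2)
        if diff == 0.0:
            return TestResult(0.0, df, 1.0, False, degenerate=True)
        return TestResult(math.copysign(math.inf, diff), df, 0.0, False, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), False)


def r_to_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transform
    ``t = r * sqrt((n - 2) / (1 - r**2))`` with n - 2 degrees of freedom."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 2:
        raise ValueError("regression needs n >= 2")
    if np.all(x == x[0]):
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    p = float(res.pvalue) if x.size >= 3 else float("nan")
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=p,
        n=int(x.size),
    )


def write_stats_report_json(path: str | Path, contrasts: dict, regressions: dict) -> None:
    """Stats report: per contrast {groups, n, means, sds, paired, t, df, p};
    per regression {a, b, r, p, n}."""
    payload = {"contrasts": contrasts, "regressions": regressions}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (GroupSummary, TestResult, RegressionResult)):
        return asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
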