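"""Replicate summaries and group comparisons for the reporting layer.

Boxplot summaries follow the Tukey convention: hinges are Tukey fourths
(first/third quartiles), whiskers reach the most extreme data point
within 1.5 x IQR of its hinge, points beyond are outliers. Group tests
are Welch's unequal-variance t-test and one/two-way ANOVA (Type II sums
of squares for the two-way layout, robust to unbalanced replicate
counts). The statistics are implemented from their closed forms here so
library routines can serve as independent cross-checks in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class GroupSample:
    """Labelled group of replicate values."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.values):
            raise ValidationError(f"group {self.label}: non-finite value")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    lower_hinge: float
    upper_hinge: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    term: str = ""

    @property
    def significance_stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Per-comparison star scheme: * <0.05, ** <0.01, *** <0.001."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_array(sample) -> np.ndarray:
    values = sample.values if isinstance(sample, GroupSample) else sample
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty group")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite value in group")
    return arr


def _tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    depth = (math.floor((n + 1) / 2) + 1) / 2
    lo = 0.5 * (x[math.floor(depth) - 1] + x[math.ceil(depth) - 1])
    hi = 0.5 * (x[n - math.floor(depth)] + x[n - math.ceil(depth)])
    return float(lo), float(hi)


def boxplot_summary(values, quartile_method: str = "tukey") -> BoxplotSummary:
    """Five-number boxplot summary with 1.5 x IQR whiskers.

    ``quartile_method`` is ``"tukey"`` (hinges/fourths, the default) or
    ``"linear"`` (linear-interpolation quartiles as in numpy's default
    percentile).
    """
    x = np.sort(_as_array(values))
    median = float(np.median(x))
    if quartile_method == "tukey":
        lower, upper = _tukey_hinges(x)
    elif quartile_method == "linear":
        lower, upper = (float(np.percentile(x, 25)),
                        float(np.percentile(x, 75)))
    else:
        raise ConfigurationError(
            f"unknown quartile method {quartile_method!r}")
    iqr = upper - lower
    lo_fence = lower - 1.5 * iqr
    hi_fence = upper + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return BoxplotSummary(
        median=median, lower_hinge=lower, upper_hinge=upper,
        lower_whisker=float(inside.min()), upper_whisker=float(inside.max()),
        outliers=outliers)


def welch_t(a, b) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Uses the Welch-Satterthwaite degrees of freedom; degenerate inputs
    (either group < 2 values, or both variances zero) are refused.
    """
    xa, xb = _as_array(a), _as_array(b)
    if len(xa) < 2 or len(xb) < 2:
        raise ValidationError("Welch t-test needs >= 2 values per group")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    se2 = va / len(xa) + vb / len(xb)
    if se2 == 0:
        raise ValidationError("zero variance in both groups")
    t = (xa.mean() - xb.mean()) / math.sqrt(se2)
    df = se2 ** 2 / (
        (va / len(xa)) ** 2 / (len(xa) - 1)
        + (vb / len(xb)) ** 2 / (len(xb) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(test_name="welch_t", statistic=float(t), df=float(df),
                      p_value=float(p))


# ---------------------------------------------------------------------------
# ANOVA

def _dummies(levels: np.ndarray) -> tuple[np.ndarray, int]:
    """Treatment-coded dummy columns (first level dropped)."""
    uniq = np.unique(levels)
    cols = np.column_stack([(levels == u).astype(float) for u in uniq[1:]]) \
        if len(uniq) > 1 else np.empty((len(levels), 0))
    return cols, len(uniq)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _interaction(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    if da.shape[1] == 0 or db.shape[1] == 0:
        return np.empty((da.shape[0], 0))
    return np.concatenate(
        [da[:, [i]] * db for i in range(da.shape[1])], axis=1)


def anova(values, factors: dict[str, Sequence]) -> list[TestResult]:
    """One- or two-way fixed-effects ANOVA.

    One factor: classic one-way F. Two factors: F per factor and for the
    interaction, with Type II sums of squares (each main effect adjusted
    for the other, the interaction adjusted for both), which matches the
    common default for unbalanced replicate counts. A constant response
    is reported as F = 0, p = 1 by convention.
    """
    y = _as_array(values)
    n = len(y)
    if not 1 <= len(factors) <= 2:
        raise ConfigurationError("anova supports 1 or 2 factors")
    fl = {}
    for name, levels in factors.items():
        arr = np.asarray(levels)
        if len(arr) != n:
            raise ValidationError(f"factor {name}: length mismatch")
        if len(np.unique(arr)) < 2:
            raise ValidationError(f"factor {name} has a single level")
        fl[name] = arr

    if len(fl) == 1:
        (name, levels), = fl.items()
        return [_oneway(y, levels, term=name)]

    (na, la), (nb, lb) = fl.items()
    da, a = _dummies(la)
    db, b = _dummies(lb)
    dab = _interaction(da, db)
    ones = np.ones((n, 1))
    rss_full = _rss(y, np.concatenate([ones, da, db, dab], axis=1))
    rss_ab = _rss(y, np.concatenate([ones, da, db], axis=1))
    rss_a = _rss(y, np.concatenate([ones, da], axis=1))
    rss_b = _rss(y, np.concatenate([ones, db], axis=1))
    df_resid = n - (1 + da.shape[1] + db.shape[1] + dab.shape[1])
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    mse = rss_full / df_resid
    # perfect-fit / constant-response regime: classify each term's SS as
    # zero or nonzero relative to the total variation instead of dividing
    # by a zero (or numerically-zero) MSE
    tss = float(((y - y.mean()) ** 2).sum())
    tiny = 1e-12 * max(tss, 1.0)
    out = []
    for term, ss, dfn in ((na, rss_b - rss_ab, a - 1),
                          (nb, rss_a - rss_ab, b - 1),
                          (f"{na}:{nb}", rss_ab - rss_full, (a - 1) * (b - 1))):
        ss = max(ss, 0.0)
        if mse <= tiny / max(df_resid, 1):
            f, p = (0.0, 1.0) if ss <= tiny else (float("inf"), 0.0)
        else:
            f = (ss / dfn) / mse
            p = float(sps.f.sf(f, dfn, df_resid))
        out.append(TestResult(test_name="anova_2way", statistic=float(f),
                              df=(float(dfn), float(df_resid)),
                              p_value=p, term=term))
    return out


def _oneway(y: np.ndarray, levels: np.ndarray, term: str) -> TestResult:
    uniq = np.unique(levels)
    n = len(y)
    k = len(uniq)
    if n - k < 1:
        raise ValidationError("no residual degrees of freedom")
    grand = y.mean()
    ss_between = sum(
        (levels == u).sum() * (y[levels == u].mean() - grand) ** 2
        for u in uniq)
    ss_within = sum(
        ((y[levels == u] - y[levels == u].mean()) ** 2).sum() for u in uniq)
    dfn, dfd = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("anova_1way", 0.0, (float(dfn), float(dfd)),
                              1.0, term=term)
        return TestResult("anova_1way", float("inf"),
                          (float(dfn), float(dfd)), 0.0, term=term)
    f = (ss_between / dfn) / (ss_within / dfd)
    return TestResult("anova_1way", float(f), (float(dfn), float(dfd)),
                      float(sps.f.sf(f, dfn, dfd)), term=term)


def timepoint_ratio(day_late, day_early) -> float:
    """Ratio of group means (late / early timepoint)."""
    late, early = _as_array(day_late), _as_array(day_early)
    if early.mean() <= 0 or late.mean() <= 0:
        raise ValidationError("timepoint ratio requires positive group means")
    return float(late.mean() / early.mean())
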