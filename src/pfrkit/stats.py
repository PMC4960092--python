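"""Method-comparison statistics for paired physiological measurements.

Covers the comparisons run when validating one measurement technique against
another on the same subjects: ordinary least-squares regression, Pearson
correlation with Fisher-z confidence intervals, Bland-Altman bias and limits
of agreement (with a summary mode that works from a printed bias and SD when
raw pairs are unavailable), intraclass correlation for observer
repeatability, one-way ANOVA, and the relative-underestimation percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InputError

__all__ = [
    "RegressionResult",
    "CorrelationResult",
    "BlandAltmanResult",
    "ICCResult",
    "linear_regression",
    "pearson_ci",
    "bland_altman",
    "bland_altman_summary",
    "icc",
    "one_way_anova",
    "relative_underestimation",
]

#: limits-of-agreement multiplier; exactly 1.96, not a t quantile
LOA_MULTIPLIER = 1.96


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n: int


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int | None = None
    ci_bias: tuple[float, float] | None = None
    ci_loa_low: tuple[float, float] | None = None
    ci_loa_high: tuple[float, float] | None = None


@dataclass
class ICCResult:
    icc: float
    form: str          # 'ICC(2,1)' agreement or 'ICC(3,1)' consistency
    n_subjects: int
    n_raters: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least-squares line with the Pearson correlation of the pairs.

    A constant ``y`` is a flat but well-defined line (slope 0, r reported as
    0 by convention); a constant ``x`` leaves the slope undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise InputError("need at least three pairs")
    if np.ptp(x) == 0:
        raise DegenerateDataError("x is constant: slope undefined")
    if np.ptp(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r=0.0, n=x.size)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), n=x.size)


def pearson_ci(r: float, n: int, level: float = 0.95) -> CorrelationResult:
    """Fisher-z confidence interval for a correlation coefficient.

    CI = tanh(atanh(r) -/+ z_crit / sqrt(n - 3)).
    """
    if not -1.0 < r < 1.0:
        raise DegenerateDataError("|r| = 1 has a degenerate Fisher-z interval")
    if n < 4:
        raise InputError("Fisher-z interval needs n >= 4")
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return CorrelationResult(r=float(r), ci_low=float(np.tanh(z - half)),
                             ci_high=float(np.tanh(z + half)), n=int(n), level=level)


def bland_altman_summary(bias: float, sd_diff: float, n: int | None = None,
                         level: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman limits from a reported bias and SD of the differences.

    Limits of agreement are bias +/- 1.96 sd. When ``n`` is given, confidence
    intervals use SE(bias) = sd/sqrt(n), the approximate SE(limit) =
    sd*sqrt(3/n), and a t(n-1) quantile.
    """
    if sd_diff < 0:
        raise InputError("sd_diff must be non-negative")
    lo = bias - LOA_MULTIPLIER * sd_diff
    hi = bias + LOA_MULTIPLIER * sd_diff
    res = BlandAltmanResult(bias=float(bias), sd_diff=float(sd_diff),
                            loa_low=float(lo), loa_high=float(hi), n=n)
    if n is not None:
        if n < 2:
            raise InputError("confidence intervals need n >= 2")
        tcrit = sps.t.ppf(0.5 + level / 2.0, n - 1)
        se_bias = sd_diff / np.sqrt(n)
        se_loa = sd_diff * np.sqrt(3.0 / n)
        res.ci_bias = (float(bias - tcrit * se_bias), float(bias + tcrit * se_bias))
        res.ci_loa_low = (float(lo - tcrit * se_loa), float(lo + tcrit * se_loa))
        res.ci_loa_high = (float(hi - tcrit * se_loa), float(hi + tcrit * se_loa))
    return res


def bland_altman(a, b, level: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman comparison of paired measurements: differences d = a - b.

    Bias is mean(d); the SD uses the sample (n-1) convention; limits of
    agreement are bias +/- 1.96 sd with t-based confidence intervals.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired inputs must be 1-D and equal length")
    if a.size < 2:
        raise InputError("need at least two pairs")
    d = a - b
    return bland_altman_summary(float(d.mean()), float(d.std(ddof=1)),
                                n=a.size, level=level)


def icc(ratings, form: str = "ICC(2,1)") -> ICCResult:
    """Intraclass correlation from a complete subjects x raters table.

    ``ICC(2,1)``: two-way random effects, absolute agreement, single
    measures — sensitive to systematic rater offsets. ``ICC(3,1)``: two-way
    mixed, consistency — offsets forgiven.
    """
    import pingouin as pg

    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError("ratings must be a 2-D table with >= 2 subjects and >= 2 raters")
    if np.isnan(table).any():
        raise InputError("ratings table must be complete (no missing cells)")
    if form not in ("ICC(2,1)", "ICC(3,1)"):
        raise InputError(f"unsupported ICC form {form!r}")
    ns, nr = table.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(ns), nr),
        "rater": np.tile(np.arange(nr), ns),
        "score": table.ravel(),
    })
    import warnings as _warnings
    with _warnings.catch_warnings():
        # perfect-agreement tables make pingouin's internal F ratios divide by zero
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(data=long, targets="subject", raters="rater",
                                 ratings="score")
    # McGraw & Wong labels: absolute agreement (A,1) == ICC(2,1), consistency (C,1) == ICC(3,1)
    key = "ICC(A,1)" if form == "ICC(2,1)" else "ICC(C,1)"
    value = float(res.loc[res["Type"] == key, "ICC"].iloc[0])
    return ICCResult(icc=value, form=form, n_subjects=ns, n_raters=nr)


def one_way_anova(groups) -> tuple[float, float]:
    """One-way analysis of variance across two or more groups: (F, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InputError("need at least two groups")
    if any(g.size < 2 for g in arrays):
        raise InputError("each group needs at least two values")
    within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    means = [g.mean() for g in arrays]
    if within == 0 and np.ptp(means) > 0:
        raise DegenerateDataError(
            "zero within-group variance with unequal means: F is unbounded")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def relative_underestimation(reference_mean: float, test_mean: float) -> tuple[float, int]:
    """Percent by which ``test_mean`` falls below ``reference_mean``.

    Returns the raw percentage and its nearest-integer rounding.
    """
    if reference_mean <= 0:
        raise InputError("reference mean must be positive")
    pct = 100.0 * (reference_mean - test_mean) / reference_mean
    return float(pct), int(round(pct))
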