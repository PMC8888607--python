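"""Agreement statistics for comparing muscle-mass estimation methods.

Given paired per-muscle values from two methods (e.g. body-mass-normalised
masses from dissection vs from volumetric modelling), this module provides:

* Bland–Altman agreement: bias = mean(a − b), its t-based confidence
  interval, and the limits of agreement bias ± 1.96·SD of the differences.
  When a bias is reported as ``bias ± h``, h is the 95% CI half-width of
  the bias — not the limits of agreement, which are reported separately.
* A two-sided Mann–Whitney U test with the rank-sum-based first-sample W
  statistic (exact enumeration for small tie-free samples, otherwise a
  tie- and continuity-corrected normal approximation).
* "Within range" summaries: the percentage of muscles whose estimate lands
  inside the reference mean±1SD, mean±2SD, [min, max], and
  [min−20%, max+20%] intervals.
* Ordinary least-squares regression of estimates on reference values with
  adjusted R².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PairedSeries",
    "BlandAltmanResult",
    "MWUResult",
    "RangeSummary",
    "RegressionFit",
    "bland_altman",
    "mann_whitney_u",
    "within_range_summary",
    "ols_fit",
    "compare_methods",
]

#: largest sample size for which the exact MWU null distribution is enumerated
EXACT_MWU_MAX_N = 8


@dataclass(frozen=True)
class PairedSeries:
    """Per-muscle paired values from two methods."""

    labels: tuple
    a: np.ndarray
    b: np.ndarray

    def __init__(self, labels: Sequence[str], a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        labels = tuple(labels)
        if not (len(labels) == len(a) == len(b)):
            raise ValueError("labels, a, b must have equal length")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError("paired series must not contain missing values")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def __len__(self):
        return len(self.labels)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    bias_ci: tuple
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


@dataclass(frozen=True)
class MWUResult:
    W: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n_x: int
    n_y: int


@dataclass(frozen=True)
class RangeSummary:
    median: float
    min: float
    max: float
    pct_within_1sd: float
    pct_within_2sd: float
    pct_within_range: float
    pct_within_range_20: float
    n_muscles: int


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    n: int


def bland_altman(series: PairedSeries, ci_level: float = 0.95) -> BlandAltmanResult:
    """Bland–Altman agreement between the two methods of a paired series.

    Differences d = a − b; bias = mean(d); limits of agreement =
    bias ± 1.96·SD(d); CI of the bias uses the t distribution with n−1 df.
    """
    n = len(series)
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = series.a - series.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = stats.t.ppf(0.5 + ci_level / 2, n - 1) * sd / np.sqrt(n)
    return BlandAltmanResult(
        bias=bias,
        bias_ci=(bias - half, bias + half),
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=n,
    )


def mann_whitney_u(x, y, alternative: str = "two-sided") -> MWUResult:
    """Two-sided Mann–Whitney U test.

    W is the U statistic of the first sample (the rank-sum convention used
    by standard statistical environments, so printed W values are directly
    comparable).  The p-value is exact (full enumeration of rank
    assignments) when both samples have ≤8 observations and there are no
    ties; otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = max(len(x), len(y)) <= EXACT_MWU_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return MWUResult(
        W=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if exact else "normal_approx",
        n_x=len(x),
        n_y=len(y),
    )


def within_range_summary(estimates: dict, reference: dict) -> RangeSummary:
    """Fraction of muscles whose estimate falls inside reference intervals.

    Parameters
    ----------
    estimates : dict
        muscle name -> estimated value (e.g. normalised mass).
    reference : dict
        muscle name -> sequence of ≥2 reference measurements.

    For each muscle the reference measurements define four nested-ish
    intervals — mean±1SD, mean±2SD, [min, max], and [min−20%·min,
    max+20%·max] — and the summary reports the percentage of muscles whose
    estimate lies in each, plus the median/min/max of the estimates
    normalised by the per-muscle reference median.
    """
    import warnings as _warnings

    rows = []
    normalized = []
    for name, est in estimates.items():
        ref = np.asarray(reference.get(name, ()), dtype=float)
        if ref.size < 2:
            _warnings.warn(f"muscle {name!r} excluded: needs >=2 reference values", stacklevel=2)
            continue
        mean, sd = ref.mean(), ref.std(ddof=1)
        lo, hi = ref.min(), ref.max()
        rows.append(
            (
                mean - sd <= est <= mean + sd,
                mean - 2 * sd <= est <= mean + 2 * sd,
                lo <= est <= hi,
                lo - 0.2 * abs(lo) <= est <= hi + 0.2 * abs(hi),
            )
        )
        med = np.median(ref)
        if med != 0:
            normalized.append(est / med)
    if not rows:
        raise ValueError("no muscle had sufficient reference data")
    arr = np.array(rows, dtype=float)
    pct = 100.0 * arr.mean(axis=0)
    normalized = np.array(normalized) if normalized else np.array([np.nan])
    return RangeSummary(
        median=float(np.median(normalized)),
        min=float(normalized.min()),
        max=float(normalized.max()),
        pct_within_1sd=float(pct[0]),
        pct_within_2sd=float(pct[1]),
        pct_within_range=float(pct[2]),
        pct_within_range_20=float(pct[3]),
        n_muscles=len(rows),
    )


def ols_fit(series: PairedSeries) -> RegressionFit:
    """OLS regression of the second method (b) on the first (a)."""
    n = len(series)
    if n < 3:
        raise ValueError("regression needs at least 3 pairs")
    if np.ptp(series.a) == 0:
        raise ValueError("x values are constant; regression undefined")
    if np.ptp(series.b) == 0:
        # constant response: flat line, no variance explained
        return RegressionFit(
            slope=0.0,
            intercept=float(series.b[0]),
            r2=0.0,
            adjusted_r2=1.0 - (n - 1) / (n - 2),
            n=n,
        )
    X = sm.add_constant(series.a)
    fit = sm.OLS(series.b, X).fit()
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        n=n,
    )


def compare_methods(series: PairedSeries, ci_level: float = 0.95) -> dict:
    """Full agreement report for one method pair: Bland–Altman, Mann–Whitney
    U, and the regression fit, as a JSON-serialisable dict."""
    ba = bland_altman(series, ci_level)
    mwu = mann_whitney_u(series.a, series.b)
    fit = ols_fit(series) if len(series) >= 3 and np.ptp(series.a) > 0 else None
    out = {
        "n": len(series),
        "bland_altman": {
            "bias": ba.bias,
            "bias_ci": list(ba.bias_ci),
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
            "sd_diff": ba.sd_diff,
        },
        "mann_whitney_u": {"W": mwu.W, "p_value": mwu.p_value, "method": mwu.method},
    }
    if fit is not None:
        out["regression"] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r2": fit.r2,
            "adjusted_r2": fit.adjusted_r2,
        }
    return out
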