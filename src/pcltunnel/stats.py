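"""Cohort statistics: correlations, best-fit TTL equations, safety rate, ICC.

This layer mirrors a standard orthopaedic morphometry workflow:

* normality screening (Kolmogorov-Smirnov with estimated parameters, i.e.
  the Lilliefors correction) gates the choice between Pearson and Spearman
  correlation, with strength labels at |r| cut points 0.1 / 0.3 / 0.7;
* ordinary least squares gives the "Y = aX + b" prediction equations for
  tunnel length from tunnel angle (or tunnel height), with r² and residual
  SD;
* the safety rate is the probability that drilling to the predicted TTL
  does not overshoot the true tunnel exit by more than the 8-mm safe
  distance to the popliteal artery — reported both as an empirical residual
  proportion and as the normal-model tail Phi(safe / residual SD);
* reproducibility of repeated measurement sessions is summarised by the
  intraclass correlation coefficient ICC(2,1): two-way random effects,
  absolute agreement, single measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "CorrelationResult",
    "RegressionFit",
    "SafetyEstimate",
    "IccResult",
    "Prediction",
    "normality_test",
    "correlate",
    "fit_linear",
    "predict_ttl",
    "safety_rate",
    "compare_groups",
    "icc",
]

STRENGTH_CUTS = (0.1, 0.3, 0.7)
ICC_CUTS = (0.50, 0.75, 0.90)
ALPHA = 0.05


def _as_clean_array(x, name="values") -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if np.isnan(a).any():
        raise ValueError(f"{name} contain missing values")
    return a


# ---------------------------------------------------------------------------
# normality and correlation


class NormalityResult(NamedTuple):
    statistic: float
    p_value: float
    is_normal: bool


def normality_test(
    values, alpha: float = ALPHA, lilliefors_correction: bool = True
) -> NormalityResult:
    """One-sample KS test of normality with sample mean/SD.

    With ``lilliefors_correction`` (default) the p-value accounts for the
    estimated parameters; otherwise the naive KS p-value against the fitted
    normal is returned.
    """
    a = _as_clean_array(values)
    if len(a) < 4:
        raise ValueError("normality test needs at least 4 observations")
    if np.ptp(a) == 0:
        raise ValueError("constant input has no defined normality test")
    if lilliefors_correction:
        stat, p = lilliefors(a, dist="norm")
    else:
        stat, p = sps.kstest(a, "norm", args=(a.mean(), a.std(ddof=1)))
    return NormalityResult(float(stat), float(p), bool(p >= alpha))


def strength_label(r: float) -> str:
    """Correlation strength on |r|: [0.1, 0.3) weak, [0.3, 0.7) moderate,
    [0.7, 1] strong, below 0.1 negligible (cut points closed on the left)."""
    a = abs(r)
    if a >= STRENGTH_CUTS[2]:
        return "strong"
    if a >= STRENGTH_CUTS[1]:
        return "moderate"
    if a >= STRENGTH_CUTS[0]:
        return "weak"
    return "negligible"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    method: Literal["pearson", "spearman"]
    strength: str
    n: int


def correlate(x, y, alpha: float = ALPHA) -> CorrelationResult:
    """Pearson correlation if both variables pass the normality screen,
    Spearman otherwise (matching the mixed-method convention of
    morphometric correlation tables)."""
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 4:
        raise ValueError("correlation needs at least 4 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero-variance input")
    both_normal = (
        normality_test(xa, alpha).is_normal and normality_test(ya, alpha).is_normal
    )
    if both_normal:
        r, p = sps.pearsonr(xa, ya)
        method = "pearson"
    else:
        r, p = sps.spearmanr(xa, ya)
        method = "spearman"
    return CorrelationResult(float(r), float(p), method, strength_label(float(r)), len(xa))


# ---------------------------------------------------------------------------
# regression and prediction


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int
    predictor: str = "TTA"
    stratum: str = "pooled"

    def equation(self, ndigits: int = 2) -> str:
        return f"Y = {round(self.slope, ndigits)}X + {round(self.intercept, ndigits)}"


def fit_linear(x, y, predictor: str = "TTA", stratum: str = "pooled") -> RegressionFit:
    """Ordinary least squares y = slope*x + intercept.

    ``residual_sd`` is sqrt(SSE / (n - 2)), the scale used by the
    normal-model safety rate.
    """
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(xa) == 0:
        raise ValueError("constant predictor")
    res = sps.linregress(xa, ya)
    resid = ya - (res.slope * xa + res.intercept)
    sse = float(resid @ resid)
    residual_sd = math.sqrt(sse / (len(xa) - 2)) if len(xa) > 2 else 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        residual_sd=residual_sd,
        n=len(xa),
        predictor=predictor,
        stratum=stratum,
    )


class Prediction(NamedTuple):
    value: float
    extrapolated: bool


def predict_ttl(
    fit: RegressionFit | tuple[float, float],
    x: float,
    guard: tuple[float, float] = (35.0, 65.0),
) -> Prediction:
    """TTL predicted from the fitted equation, flagged when ``x`` falls
    outside the guard band (default 35-65 deg, bracketing the studied
    40-60 deg tunnel angles)."""
    slope, intercept = (
        (fit.slope, fit.intercept) if isinstance(fit, RegressionFit) else fit
    )
    return Prediction(
        value=float(slope * x + intercept),
        extrapolated=not (guard[0] <= x <= guard[1]),
    )


# ---------------------------------------------------------------------------
# safety rate


@dataclass(frozen=True)
class SafetyEstimate:
    safe_distance: float
    safety_rate: float
    method: Literal["empirical", "normal_model"]
    residual_sd: float
    n: int
    degenerate: bool = False


def safety_rate(
    fit: RegressionFit,
    x,
    actual_ttl,
    safe_distance: float = 8.0,
    method: Literal["empirical", "normal_model"] = "empirical",
) -> SafetyEstimate:
    """Probability that drilling guided by the prediction equation stays safe.

    A drilling overshoot occurs when the predicted TTL exceeds the actual
    TTL by more than ``safe_distance`` mm (the adopted clearance between the
    pin exit and the popliteal artery).  ``empirical`` counts the
    observations directly; ``normal_model`` assumes centred normal residuals
    and returns Phi(safe_distance / residual_sd).
    """
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(actual_ttl, "actual_ttl")
    if len(xa) != len(ya):
        raise ValueError("x and actual_ttl must have equal length")
    if safe_distance < 0:
        raise ValueError("safe_distance must be >= 0")
    predicted = fit.slope * xa + fit.intercept
    overshoot = predicted - ya
    if method == "empirical":
        rate = float(np.mean(overshoot <= safe_distance))
        degenerate = False
    elif method == "normal_model":
        if fit.residual_sd == 0:
            rate, degenerate = 1.0, True
        else:
            rate = float(sps.norm.cdf(safe_distance / fit.residual_sd))
            degenerate = False
    else:
        raise ValueError(f"unknown method {method!r}")
    return SafetyEstimate(
        safe_distance=safe_distance,
        safety_rate=rate,
        method=method,
        residual_sd=fit.residual_sd,
        n=len(xa),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# group comparison


class TTestResult(NamedTuple):
    statistic: float
    p_value: float
    significant: bool


def compare_groups(a, b, alpha: float = ALPHA) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance)."""
    aa, ba = _as_clean_array(a, "group a"), _as_clean_array(b, "group b")
    if len(aa) < 2 or len(ba) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = sps.ttest_ind(aa, ba, equal_var=True)
    return TTestResult(float(t), float(p), bool(p < alpha))


# ---------------------------------------------------------------------------
# intraclass correlation


def icc_category(value: float) -> str:
    """Agreement bands: < 0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good,
    > 0.90 excellent."""
    if value > ICC_CUTS[2]:
        return "excellent"
    if value >= ICC_CUTS[1]:
        return "good"
    if value >= ICC_CUTS[0]:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class IccResult:
    icc: float
    category: str
    model: str = "ICC(2,1) two-way random, absolute agreement, single measure"
    n_subjects: int = 0
    n_raters: int = 0


def icc(ratings) -> IccResult:
    """ICC(2,1) from the two-way ANOVA mean squares.

    ``ratings`` is an (n subjects x k raters/sessions) array without missing
    values.  With mean squares MSR (rows), MSC (columns) and MSE,

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("ratings must be a 2D subjects x raters table")
    if np.isnan(m).any():
        raise ValueError("ratings contain missing values")
    n, k = m.shape
    if n < 5:
        raise ValueError("ICC needs at least 5 subjects")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((m - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = 0.0 if denom == 0 else (msr - mse) / denom
    return IccResult(icc=float(value), category=icc_category(float(value)),
                     n_subjects=n, n_raters=k)
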