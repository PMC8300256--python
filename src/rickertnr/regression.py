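"""OLS trend fitting, outlier exclusion and LOWESS smoothing.

This is the statistical engine behind the program assessment: every trend
in the pipeline (growth rate vs time, vs surgeries, vs census population,
pregnancy proportion vs month) is an ordinary least-squares line with a
two-sided t-test on the slope (df = n − 2).

When growth rate is regressed on abundance, the fitted line's y-intercept
estimates the maximum per-capita rate of increase r_m and its x-intercept
estimates the carrying capacity K — so the x-intercept is only reported
for negative slopes, where a finite positive crossing exists and K is
meaningful.

Outlier screening follows the common residual-analysis convention:
internally studentized residuals, a fixed threshold (default 2.0), and a
single exclusion round followed by one refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import AnalysisPreconditionError, DataValidationError

__all__ = [
    "RegressionFit",
    "fit_linear",
    "fit_with_outlier_exclusion",
    "lowess_curve",
    "proportion_trend",
]


@dataclass
class RegressionFit:
    """An OLS line with slope inference.

    ``x_intercept`` (−intercept/slope) is present only when the slope is
    negative. ``excluded`` lists (x, y) points removed by outlier
    screening; ``n_used + len(excluded)`` equals the number of points
    supplied. ``smoother`` optionally carries a LOWESS curve.
    """

    slope: float
    intercept: float
    p_value: float
    stderr_slope: float
    n_used: int
    x_intercept: Optional[float] = None
    excluded: list[tuple[float, float]] = field(default_factory=list)
    smoother: Optional[list[tuple[float, float]]] = None
    notes: list[str] = field(default_factory=list)

    @property
    def significant_decline(self) -> bool:
        """True when the slope is negative at p < 0.05 (two-sided)."""
        return self.slope < 0 and self.p_value < 0.05

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def _as_arrays(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DataValidationError("x and y must be 1-d sequences of equal length")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise DataValidationError("x and y must be finite")
    return xa, ya


def _ols(xa: np.ndarray, ya: np.ndarray):
    X = sm.add_constant(xa)
    with warnings.catch_warnings():
        # a perfectly collinear/noise-free fit triggers harmless runtime
        # warnings inside the t-test machinery
        warnings.simplefilter("ignore")
        return sm.OLS(ya, X).fit()


def _fit(xa: np.ndarray, ya: np.ndarray, excluded: list[tuple[float, float]],
         notes: list[str]) -> RegressionFit:
    res = _ols(xa, ya)
    intercept, slope = float(res.params[0]), float(res.params[1])
    # snap numerically-zero slopes (constant response) so float dust never
    # manufactures a spurious x-intercept
    span = float(xa.max() - xa.min())
    snapped = abs(slope) * span < 1e-9 * (1.0 + float(np.ptp(ya)))
    if snapped:
        slope = 0.0
    p = float(res.pvalues[1])
    if snapped or not np.isfinite(p):
        # zero-residual or constant-response degenerate cases
        p = 0.0 if slope != 0 else 1.0
    se = float(res.bse[1])
    x_int = -intercept / slope if slope < 0 else None
    return RegressionFit(
        slope=slope, intercept=intercept, p_value=p, stderr_slope=se,
        n_used=len(xa), x_intercept=x_int, excluded=excluded, notes=notes,
    )


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Least-squares line y = a + b·x with a two-sided slope t-test.

    Requires ≥ 3 points and ≥ 2 distinct x values.
    """
    xa, ya = _as_arrays(x, y)
    if len(xa) < 3:
        raise AnalysisPreconditionError(
            f"need at least 3 points for a regression, got {len(xa)}"
        )
    if np.unique(xa).size < 2:
        raise AnalysisPreconditionError("all x values identical; no trend defined")
    return _fit(xa, ya, excluded=[], notes=[])


def fit_with_outlier_exclusion(
    x: Sequence[float], y: Sequence[float], threshold: float = 2.0
) -> RegressionFit:
    """Fit, drop points with |internally studentized residual| > threshold,
    refit once on the remainder.

    A single exclusion round only — never iterated. If exclusion would
    leave fewer than 3 points, the unexcluded fit is returned with a
    warning note.
    """
    if threshold <= 0:
        raise DataValidationError("outlier threshold must be positive")
    xa, ya = _as_arrays(x, y)
    base = fit_linear(xa, ya)
    res = _ols(xa, ya)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        student = OLSInfluence(res).resid_studentized_internal
    student = np.nan_to_num(np.asarray(student, dtype=float), nan=0.0)
    mask = np.abs(student) <= threshold
    if mask.all():
        return base
    if mask.sum() < 3 or np.unique(xa[mask]).size < 2:
        base.notes.append(
            "outlier exclusion skipped: would leave fewer than 3 usable points"
        )
        return base
    excluded = [(float(a), float(b)) for a, b in zip(xa[~mask], ya[~mask])]
    return _fit(xa[mask], ya[mask], excluded=excluded,
                notes=[f"excluded {len(excluded)} outlier(s) at |t_i| > {threshold:g}"])


def lowess_curve(
    x: Sequence[float],
    y: Sequence[float],
    bandwidth: float = 2.0 / 3.0,
    robust_iters: int = 3,
) -> list[tuple[float, float]]:
    """Locally weighted scatterplot smoothing evaluated at the input x.

    ``bandwidth`` is the fraction of points in each local window (0, 1];
    ``robust_iters`` is the number of robustifying reweighting passes.
    Returns (x, fitted) pairs sorted by x.
    """
    if not 0 < bandwidth <= 1:
        raise DataValidationError("bandwidth must be in (0, 1]")
    if robust_iters < 0:
        raise DataValidationError("robust_iters must be >= 0")
    xa, ya = _as_arrays(x, y)
    if len(xa) < 5:
        raise AnalysisPreconditionError("need at least 5 points for LOWESS")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant y divides by zero inside
        fitted = _sm_lowess(ya, xa, frac=bandwidth, it=robust_iters, return_sorted=True)
    return [(float(a), float(b)) for a, b in fitted]


def proportion_trend(
    numerators: Sequence[int],
    denominators: Sequence[int],
    time: Sequence[float],
) -> RegressionFit:
    """OLS of a proportion (numerator/denominator) on time.

    Periods with a zero denominator are skipped (their proportion is
    undefined), reducing ``n_used``; at least 3 usable periods required.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    t = np.asarray(time, dtype=float)
    if not (len(num) == len(den) == len(t)):
        raise DataValidationError("numerators, denominators, time must align")
    if ((num < 0) | (den < 0)).any() or (num > den).any():
        raise DataValidationError("need 0 <= numerator <= denominator")
    usable = den > 0
    if usable.sum() < 3:
        raise AnalysisPreconditionError(
            f"need at least 3 periods with a nonzero denominator, "
            f"got {int(usable.sum())}"
        )
    fit = fit_linear(t[usable], num[usable] / den[usable])
    skipped = int((~usable).sum())
    if skipped:
        fit.notes.append(f"skipped {skipped} period(s) with zero denominator")
    return fit
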