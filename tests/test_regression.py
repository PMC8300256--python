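"""OLS engine vs a hand-written normal-equation oracle, outlier
screening, LOWESS behaviour and proportion trends."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rickertnr.errors import AnalysisPreconditionError, DataValidationError
from rickertnr.regression import (
    fit_linear,
    fit_with_outlier_exclusion,
    lowess_curve,
    proportion_trend,
)


def ols_oracle(x, y):
    """Closed-form simple OLS via the normal equations, independent of
    the implementation under test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    df = n - 2
    se = math.sqrt((resid**2).sum() / df / sxx) if df > 0 else float("nan")
    if se == 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        t = slope / se
        p = 2 * stats.t.sf(abs(t), df)
    return slope, intercept, p


class TestFitLinear:
    def test_exact_line(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        y = [2 - 0.5 * xi for xi in x]
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(-0.5)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.x_intercept == pytest.approx(4.0)
        assert fit.n_used == 5

    def test_constant_response_has_zero_slope_and_no_x_intercept(self):
        fit = fit_linear([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert fit.x_intercept is None
        assert fit.p_value == 1.0

    def test_x_intercept_absent_for_positive_slope(self):
        fit = fit_linear([0, 1, 2], [0.0, 1.0, 2.0])
        assert fit.slope > 0
        assert fit.x_intercept is None

    def test_too_few_points(self):
        with pytest.raises(AnalysisPreconditionError):
            fit_linear([0, 1], [0, 1])

    def test_degenerate_x(self):
        with pytest.raises(AnalysisPreconditionError):
            fit_linear([2, 2, 2], [0, 1, 2])

    @settings(max_examples=100, deadline=None)
    @given(data=st.data())
    def test_matches_normal_equation_oracle(self, data):
        n = data.draw(st.integers(min_value=3, max_value=30))
        # integer-grid x keeps the design well conditioned so the two
        # computations are comparable at tight tolerance
        x = [v / 10 for v in data.draw(
            st.lists(st.integers(-1000, 1000), min_size=n, max_size=n, unique=True)
        )]
        # round y to a measurement-like precision: sub-denormal dust makes
        # the closed form underflow before the pinv-based fit does
        y = [round(v, 6) for v in data.draw(
            st.lists(st.floats(-100, 100), min_size=n, max_size=n)
        )]
        fit = fit_linear(x, y)
        slope, intercept, p = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-8, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-10)
        assert fit.p_value == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_p_value_invariant_under_affine_x_rescaling(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 1.0 - 0.2 * x + rng.normal(0, 0.5, 15)
        p1 = fit_linear(x, y).p_value
        p2 = fit_linear(3.7 * x - 1900.0, y).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestOutlierExclusion:
    @staticmethod
    def _line_with_outliers(n_outliers):
        x = np.arange(12, dtype=float)
        y = 2.0 - 0.5 * x
        noise = np.array([0.05, -0.05, 0.02, -0.02, 0.04, -0.04,
                          0.03, -0.03, 0.01, -0.01, 0.05, -0.05])
        y = y + noise
        for i in range(n_outliers):
            y[4 + i] += 10.0  # ~10 residual SDs off the line
        return x, y

    @pytest.mark.parametrize("n_outliers", [1, 2])
    def test_planted_outliers_excluded_and_line_recovered(self, n_outliers):
        x, y = self._line_with_outliers(n_outliers)
        fit = fit_with_outlier_exclusion(x, y, threshold=2.0)
        assert len(fit.excluded) == n_outliers
        assert fit.n_used + len(fit.excluded) == len(x)
        assert fit.slope == pytest.approx(-0.5, abs=0.02)
        assert fit.intercept == pytest.approx(2.0, abs=0.1)

    def test_clean_data_excludes_nothing(self):
        x = np.arange(10, dtype=float)
        y = 1.0 + 0.3 * x
        fit = fit_with_outlier_exclusion(x, y, threshold=2.0)
        base = fit_linear(x, y)
        assert fit.excluded == []
        assert fit.slope == base.slope and fit.intercept == base.intercept

    def test_infinite_threshold_equals_plain_fit(self, rng):
        x = rng.uniform(0, 10, 20)
        y = rng.normal(0, 1, 20)
        loose = fit_with_outlier_exclusion(x, y, threshold=1e12)
        base = fit_linear(x, y)
        assert loose.slope == base.slope
        assert loose.excluded == []

    def test_refuses_to_exclude_below_three_points(self):
        # 3 points, one extreme: exclusion would leave 2 -> keep base fit
        fit = fit_with_outlier_exclusion([0, 1, 2], [0.0, 0.1, 50.0], threshold=0.1)
        assert fit.n_used == 3
        assert any("skipped" in n for n in fit.notes)

    def test_single_round_only(self):
        # staircase data where iterating exclusion would keep peeling
        # points; one round must be performed, never more
        x = np.arange(10, dtype=float)
        y = np.zeros(10)
        y[9] = 8.0
        y[8] = 4.0
        fit = fit_with_outlier_exclusion(x, y, threshold=2.0)
        assert fit.n_used >= 8


class TestLowess:
    def test_linear_data_reproduced(self):
        x = np.arange(10, dtype=float)
        y = 1.0 + 0.5 * x
        curve = lowess_curve(x, y, bandwidth=0.8, robust_iters=0)
        for cx, cy in curve[2:-2]:  # interior points
            assert cy == pytest.approx(1.0 + 0.5 * cx, abs=1e-6)

    def test_full_bandwidth_on_line_equals_ols(self):
        x = np.linspace(0, 1, 12)
        y = 3.0 - 2.0 * x
        curve = lowess_curve(x, y, bandwidth=1.0, robust_iters=0)
        fit = fit_linear(x, y)
        for cx, cy in curve:
            assert cy == pytest.approx(fit.predict(cx), abs=1e-8)

    def test_parabola_shape_preserved(self):
        x = np.linspace(-1, 1, 41)
        y = x**2
        curve = lowess_curve(x, y, bandwidth=0.3, robust_iters=0)
        fitted = [cy for _, cy in curve]
        mid = len(fitted) // 2
        eps = 1e-9
        assert all(a >= b - eps for a, b in zip(fitted[:mid], fitted[1:mid + 1]))
        assert all(b <= a + eps for b, a in zip(fitted[mid:-1], fitted[mid + 1:]))

    def test_bandwidth_validation(self):
        x = list(range(6))
        with pytest.raises(DataValidationError):
            lowess_curve(x, x, bandwidth=0.0)
        with pytest.raises(DataValidationError):
            lowess_curve(x, x, bandwidth=1.5)

    def test_needs_five_points(self):
        with pytest.raises(AnalysisPreconditionError):
            lowess_curve([0, 1, 2, 3], [0, 1, 2, 3])


class TestProportionTrend:
    def test_all_pregnant_gives_flat_unit_proportion(self):
        n = [5, 7, 3, 6]
        fit = proportion_trend(n, n, [0, 1, 2, 3])
        assert fit.slope == 0.0
        assert fit.intercept == pytest.approx(1.0)

    def test_zero_denominator_period_skipped(self):
        fit = proportion_trend([1, 2, 0, 3], [10, 10, 0, 10], [0, 1, 2, 3])
        assert fit.n_used == 3
        assert any("zero denominator" in n for n in fit.notes)

    def test_recovers_generating_slope_within_three_se(self, rng):
        # replicated so the check is about coverage, not one lucky draw:
        # under a correct fit, ~99% of replicates land within 3 SE
        months = np.arange(36)
        true = 0.4 - 0.008 * months
        hits = 0
        for _ in range(10):
            num = rng.binomial(500, true)
            fit = proportion_trend(num, [500] * 36, months)
            hits += abs(fit.slope - (-0.008)) < 3 * fit.stderr_slope
        assert hits >= 8

    def test_too_few_usable_periods(self):
        with pytest.raises(AnalysisPreconditionError):
            proportion_trend([1, 0, 1], [2, 0, 2], [0, 1, 2])
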