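import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import climepi as c
from climepi.exceptions import InsufficientDataError, InvalidParameterError


def brute_force_ols(years, values, origin):
    """Normal-equations oracle: solve [n, St; St, Stt] b = [Sv; Stv]."""
    t = np.asarray(years, float) - origin
    v = np.asarray(values, float)
    A = np.array([[len(t), t.sum()], [t.sum(), (t * t).sum()]])
    b = np.array([v.sum(), (t * v).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return slope, intercept


class TestFitSegment:
    def test_exact_line_recovered(self):
        s = c.AnnualSeries(np.arange(1990, 2001), 2.0 * np.arange(11))
        fit = c.fit_segment(s, 1990, 2000)
        assert np.isclose(fit.slope, 2.0) and np.isclose(fit.sse, 0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 40)
            years = np.arange(1950, 1950 + n)
            values = rng.normal(size=n)
            s = c.AnnualSeries(years, values)
            fit = c.fit_segment(s, 1950, 1950 + n - 1)
            slope, intercept = brute_force_ols(years, values, 1950)
            assert np.isclose(fit.slope, slope)
            assert np.isclose(fit.intercept, intercept)
            # OLS-with-intercept residuals sum to ~0
            assert abs(fit.residuals.sum()) < 1e-8

    def test_constant_series_has_zero_slope_and_sse(self):
        s = c.AnnualSeries(np.arange(2000, 2010), np.full(10, 4.2))
        fit = c.fit_segment(s, 2000, 2009)
        assert np.isclose(fit.slope, 0.0) and np.isclose(fit.sse, 0.0)

    def test_window_and_size_errors(self):
        s = c.AnnualSeries(np.arange(2000, 2010), np.arange(10.0))
        with pytest.raises(InvalidParameterError):
            c.fit_segment(s, 1990, 2005)
        with pytest.raises(InsufficientDataError):
            c.fit_segment(s, 2000, 2001)


class TestPiecewiseFit:
    def test_perfect_v_gives_zero_rmse_only_at_kink(self, v_series):
        pre, post, rmse = c.piecewise_fit(v_series, 1995)
        assert np.isclose(rmse, 0.0, atol=1e-10)
        assert np.isclose(pre.slope, -0.2) and np.isclose(post.slope, 0.2)
        for other in (1992, 1998):
            assert c.piecewise_fit(v_series, other)[2] > 1e-6

    def test_symmetric_v_slopes_are_exact_negatives(self, v_series):
        pre, post, _ = c.piecewise_fit(v_series, 1995)
        assert np.isclose(pre.slope, -post.slope)

    def test_rmse_matches_direct_residual_oracle(self):
        rng = np.random.default_rng(1)
        years = np.arange(1960, 2000)
        for _ in range(100):
            s = c.AnnualSeries(years, rng.normal(size=40))
            b = int(rng.integers(1965, 1995))
            pre, post, rmse = c.piecewise_fit(s, b)
            # recompute from scratch with the oracle fits
            sse = 0.0
            n = 0
            for y0, y1 in ((1960, b), (b, 1999)):
                slope, intercept = brute_force_ols(
                    np.arange(y0, y1 + 1), s.window(y0, y1).values, y0
                )
                resid = s.window(y0, y1).values - (
                    intercept + slope * (np.arange(y0, y1 + 1) - y0)
                )
                sse += (resid**2).sum()
                n += y1 - y0 + 1
            assert np.isclose(rmse, np.sqrt(sse / n))

    def test_break_year_belongs_to_both_segments(self, v_series):
        pre, post, _ = c.piecewise_fit(v_series, 1995)
        assert pre.end_year == 1995 and post.start_year == 1995
        assert pre.n_points + post.n_points == len(v_series) + 1


class TestScanBreakpoints:
    def test_scan_matches_exhaustive_recomputation(self, incidence_spec):
        s = c.gen_incidence_series(incidence_spec, c.AR1Params(0.3, 0.15), seed=11)
        scan = c.scan_breakpoints(s, 1990, 2000)
        expected = np.array([c.piecewise_fit(s, b)[2] for b in range(1990, 2001)])
        np.testing.assert_array_equal(scan.rmse_by_year, expected)
        assert scan.best_year == 1990 + int(np.argmin(expected))
        assert np.isclose(scan.min_rmse, expected.min())

    def test_noiseless_kink_found_exactly(self, v_series):
        scan = c.scan_breakpoints(v_series, 1990, 2000)
        assert scan.best_year == 1995 and np.isclose(scan.min_rmse, 0.0, atol=1e-10)

    def test_single_candidate_degenerate_scan(self, v_series):
        scan = c.scan_breakpoints(v_series, 1993, 1993)
        assert scan.best_year == 1993 and len(scan.candidate_years) == 1

    def test_empty_candidate_range_rejected(self, v_series):
        with pytest.raises(InvalidParameterError):
            c.scan_breakpoints(v_series, 2000, 1990)

    def test_tie_breaks_to_earliest_year(self):
        # constant series: every candidate fits perfectly (rmse 0)
        s = c.AnnualSeries(np.arange(1980, 2011), np.full(31, 2.0))
        scan = c.scan_breakpoints(s, 1990, 2000)
        assert scan.best_year == 1990

    def test_bootstrap_halfwidth_is_deterministic_and_nonnegative(self, incidence_spec):
        s = c.gen_incidence_series(incidence_spec, c.AR1Params(0.3, 0.15), seed=12)
        a = c.scan_breakpoints(s, 1990, 2000, n_bootstrap=200, seed=5)
        b = c.scan_breakpoints(s, 1990, 2000, n_bootstrap=200, seed=5)
        assert a.uncertainty_halfwidth == b.uncertainty_halfwidth
        assert a.uncertainty_halfwidth >= 0


class TestSegmentSummary:
    def test_median_of_small_window(self):
        s = c.AnnualSeries(np.arange(2000, 2005), np.array([1.0, 2, 3, 4, 5]))
        median, _ = c.segment_summary(s, 2000, 2004)
        assert median == 3.0

    def test_trend_per_decade_is_ten_times_annual_slope(self):
        s = c.AnnualSeries(np.arange(1997, 2012), 0.104 * np.arange(15))
        _, trend = c.segment_summary(s, 1997, 2011)
        assert np.isclose(trend, 1.04)

    def test_even_window_median_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=10)
        s = c.AnnualSeries(np.arange(2000, 2010), values)
        median, _ = c.segment_summary(s, 2000, 2009)
        srt = np.sort(values)
        assert np.isclose(median, 0.5 * (srt[4] + srt[5]))


class TestInvariances:
    @settings(max_examples=20, deadline=None)
    @given(
        offset=st.floats(-100, 100, allow_nan=False),
        shift=st.integers(-50, 50),
    )
    def test_value_offset_and_year_shift_invariance(self, offset, shift):
        rng = np.random.default_rng(abs(shift) + 3)
        base = c.AnnualSeries(np.arange(1960, 2000), rng.normal(size=40))
        scan0 = c.scan_breakpoints(base, 1970, 1990)
        shifted = c.AnnualSeries(base.years + shift, base.values + offset)
        scan1 = c.scan_breakpoints(shifted, 1970 + shift, 1990 + shift)
        assert scan1.best_year == scan0.best_year + shift
        np.testing.assert_allclose(scan1.rmse_by_year, scan0.rmse_by_year, atol=1e-9)
        fit0 = c.fit_segment(base, 1960, 1999)
        fit1 = c.fit_segment(shifted, 1960 + shift, 1999 + shift)
        assert np.isclose(fit0.slope, fit1.slope)
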