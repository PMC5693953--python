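"""Piecewise-linear breakpoint analysis of annual series.

A single change-point splits the series into two linear regimes.  The break
year is selected by scanning candidate years and minimizing the pooled root
mean squared error of two independent ordinary-least-squares fits; the break
year belongs to *both* segments, so segment reports read like
"1963-1997" and "1997-2011".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, InvalidParameterError
from .series import AnnualSeries

MIN_SEGMENT_POINTS = 3


@dataclass
class SegmentFit:
    """OLS fit of value on year over an inclusive window.

    ``intercept`` is the fitted value at ``start_year``; ``slope`` is in
    data units per year.
    """

    start_year: int
    end_year: int
    slope: float
    intercept: float
    residuals: np.ndarray
    sse: float

    @property
    def n_points(self) -> int:
        return int(self.residuals.size)

    def predict(self, years: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * (np.asarray(years) - self.start_year)


@dataclass
class BreakpointScan:
    """RMSE of the two-segment fit at every candidate break year."""

    candidate_years: np.ndarray
    rmse_by_year: np.ndarray
    best_year: int
    min_rmse: float
    uncertainty_halfwidth: float | None = None


def fit_segment(series: AnnualSeries, start_year: int, end_year: int) -> SegmentFit:
    """Ordinary least squares of value on year over ``[start_year, end_year]``."""
    sub = series.window(start_year, end_year)
    if len(sub) < MIN_SEGMENT_POINTS:
        raise InsufficientDataError(
            f"segment [{start_year}, {end_year}] has {len(sub)} points; "
            f"need >= {MIN_SEGMENT_POINTS}"
        )
    t = (sub.years - start_year).astype(float)
    v = sub.values
    tb, vb = t.mean(), v.mean()
    sxx = float(np.sum((t - tb) ** 2))
    sxy = float(np.sum((t - tb) * (v - vb)))
    slope = sxy / sxx
    intercept = vb - slope * tb
    resid = v - (intercept + slope * t)
    return SegmentFit(
        start_year=start_year,
        end_year=end_year,
        slope=slope,
        intercept=intercept,
        residuals=resid,
        sse=float(np.sum(resid**2)),
    )


def piecewise_fit(
    series: AnnualSeries, break_year: int
) -> tuple[SegmentFit, SegmentFit, float]:
    """Two independent OLS fits split at ``break_year`` (in both segments).

    Returns ``(pre_fit, post_fit, rmse)`` with
    ``rmse = sqrt((sse1 + sse2) / (n1 + n2))`` — the break-year residual of
    each segment enters the pool, and the denominator is the raw point
    count (no degrees-of-freedom correction).
    """
    pre = fit_segment(series, series.start_year, break_year)
    post = fit_segment(series, break_year, series.end_year)
    n = pre.n_points + post.n_points
    rmse = float(np.sqrt((pre.sse + post.sse) / n))
    return pre, post, rmse


def scan_breakpoints(
    series: AnnualSeries,
    first_candidate: int,
    last_candidate: int,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> BreakpointScan:
    """Evaluate :func:`piecewise_fit` at every candidate year, pick the argmin.

    Ties break toward the earliest candidate.  With ``n_bootstrap > 0`` a
    parametric bootstrap around the best-fit piecewise signal (AR(1) refit
    to the residuals) yields ``uncertainty_halfwidth``: the rounded standard
    deviation of the bootstrap best years.
    """
    if first_candidate > last_candidate:
        raise InvalidParameterError("empty candidate range")
    candidates = np.arange(first_candidate, last_candidate + 1)
    rmse = np.array([piecewise_fit(series, int(b))[2] for b in candidates])
    best_idx = int(np.argmin(rmse))  # np.argmin returns the first minimum
    best_year = int(candidates[best_idx])
    scan = BreakpointScan(
        candidate_years=candidates,
        rmse_by_year=rmse,
        best_year=best_year,
        min_rmse=float(rmse[best_idx]),
    )
    if n_bootstrap > 0:
        scan.uncertainty_halfwidth = _bootstrap_halfwidth(
            series, scan, n_bootstrap, seed
        )
    return scan


def segment_summary(
    series: AnnualSeries, start_year: int, end_year: int
) -> tuple[float, float]:
    """(median of raw values, OLS trend in units per decade) over the window."""
    sub = series.window(start_year, end_year)
    fit = fit_segment(series, start_year, end_year)
    return float(np.median(sub.values)), fit.slope * 10.0


# ---------------------------------------------------------------------------
# bootstrap uncertainty


def _piecewise_signal(series: AnnualSeries, break_year: int) -> np.ndarray:
    """Fitted piecewise signal, one value per year (break year = mean of the
    two segment predictions)."""
    pre, post, _ = piecewise_fit(series, break_year)
    years = series.years
    values = np.where(
        years < break_year,
        pre.predict(years),
        post.predict(years),
    )
    i_b = break_year - series.start_year
    values[i_b] = 0.5 * (pre.predict(np.array([break_year]))[0] + post.predict(np.array([break_year]))[0])
    return values


def _bootstrap_halfwidth(
    series: AnnualSeries,
    scan: BreakpointScan,
    n_bootstrap: int,
    seed: int | None,
) -> float:
    from .surrogate import estimate_ar1_values  # deferred: surrogate imports us

    signal = _piecewise_signal(series, scan.best_year)
    resid = series.values - signal
    params = estimate_ar1_values(resid)
    rng = np.random.default_rng(seed)

    from .synthetic import ar1_ensemble_values

    noise = ar1_ensemble_values(
        params.phi, params.sigma_e, len(series), (n_bootstrap,), rng
    )
    sims = signal[:, None] + noise  # (n_years, B)

    # vectorized re-scan: pooled SSE per candidate for every bootstrap series
    years = series.years.astype(float)
    best = np.full(n_bootstrap, scan.candidate_years[0], dtype=int)
    best_sse = np.full(n_bootstrap, np.inf)
    for b in scan.candidate_years:
        sse = _segment_sse(years, sims, years[0], float(b)) + _segment_sse(
            years, sims, float(b), years[-1]
        )
        better = sse < best_sse  # strict: ties stay at the earlier year
        best[better] = b
        best_sse[better] = sse[better]
    return float(round(np.std(best)))


def _segment_sse(
    years: np.ndarray, sims: np.ndarray, start: float, end: float
) -> np.ndarray:
    """OLS SSE over an inclusive year window for each column of ``sims``."""
    m = (years >= start) & (years <= end)
    t = years[m]
    v = sims[m]  # (n_seg, B)
    tc = t - t.mean()
    vc = v - v.mean(axis=0)
    sxx = np.sum(tc**2)
    sxy = tc @ vc
    syy = np.sum(vc**2, axis=0)
    return syy - sxy**2 / sxx
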