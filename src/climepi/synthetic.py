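"""Seeded synthetic data generators.

Every downstream stage of the analysis (breakpoint scan, red-noise
Monte-Carlo tests, SSA, gridded trend/correlation maps) is exercised on
synthetic inputs with planted structure:

* an incidence-like annual series = piecewise-linear trend + AR(1) noise,
  with a planted break year;
* a multidecadal-oscillation index = sinusoid (period ~60-80 yr) + AR(1)
  noise, standing in for an AMO-style sea-surface-temperature index;
* a monthly gridded field whose summer (JJA) means carry a planted regional
  trend and a planted correlation with a driver series, standing in for a
  reanalysis sea-level-pressure field.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError, InvalidParameterError
from .series import AnnualSeries

#: number of months in the summer season the correlation calibration targets
SEASON_LENGTH = 3


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class AR1Params:
    """First-order autoregressive ("red noise") process parameters.

    x_t = mean + phi * (x_{t-1} - mean) + e_t,   e_t ~ N(0, sigma_e^2)

    The stationary variance is sigma_e^2 / (1 - phi^2).
    """

    phi: float
    sigma_e: float
    mean: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1.0:
            raise InvalidParameterError(f"|phi| must be < 1, got {self.phi}")
        if self.sigma_e < 0.0:
            raise InvalidParameterError(f"sigma_e must be >= 0, got {self.sigma_e}")

    @property
    def stationary_variance(self) -> float:
        return self.sigma_e**2 / (1.0 - self.phi**2)

    @property
    def stationary_sd(self) -> float:
        return math.sqrt(self.stationary_variance)


@dataclass(frozen=True)
class PiecewiseTrendSpec:
    """Two linear segments meeting continuously at ``break_year``.

    ``intercept`` is the signal value at ``start_year``; slopes are in data
    units per year.
    """

    start_year: int
    end_year: int
    break_year: int
    intercept: float
    slope_pre: float
    slope_post: float

    def __post_init__(self) -> None:
        if not (self.start_year < self.break_year < self.end_year):
            raise InvalidParameterError(
                f"need start_year < break_year < end_year, got "
                f"{self.start_year}, {self.break_year}, {self.end_year}"
            )

    def signal(self) -> AnnualSeries:
        """The noiseless piecewise-linear signal."""
        years = np.arange(self.start_year, self.end_year + 1)
        t = years - self.start_year
        t_break = self.break_year - self.start_year
        value_at_break = self.intercept + self.slope_pre * t_break
        values = np.where(
            years <= self.break_year,
            self.intercept + self.slope_pre * t,
            value_at_break + self.slope_post * (t - t_break),
        )
        return AnnualSeries(years, values)


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid with a monthly time axis.

    Latitudes and longitudes are cell-center coordinates spaced
    ``resolution`` degrees apart, ascending, with longitudes in
    [-180, 180).  The time axis is every listed month of every year in
    ``[start_year, end_year]``.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float
    start_year: int
    end_year: int
    months: tuple[int, ...] = tuple(range(1, 13))

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise InvalidParameterError("resolution must be > 0")
        if self.lat_min > self.lat_max or self.lon_min > self.lon_max:
            raise InvalidParameterError("grid bounds must be ordered")
        if not (-180.0 <= self.lon_min and self.lon_max < 180.0):
            raise InvalidParameterError("longitudes must lie in [-180, 180)")
        if self.start_year > self.end_year:
            raise InvalidParameterError("start_year must be <= end_year")
        if not self.months or any(m < 1 or m > 12 for m in self.months):
            raise InvalidParameterError("months must be a non-empty subset of 1..12")

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.resolution)) + 1
        return self.lat_min + self.resolution * np.arange(n)

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.resolution)) + 1
        return self.lon_min + self.resolution * np.arange(n)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def times(self) -> list[tuple[int, int]]:
        """Ordered (year, month) pairs of the time axis."""
        return [(int(y), int(m)) for y in self.years for m in self.months]


# ---------------------------------------------------------------------------
# AR(1) simulation kernel


def ar1_values(
    n: int,
    params: AR1Params,
    rng: np.random.Generator,
    size: tuple[int, ...] = (),
) -> np.ndarray:
    """Simulate AR(1) paths of length ``n``; output shape ``(n, *size)``.

    The initial state is drawn from the stationary distribution, so the
    whole path is stationary.  ``params.phi`` and ``params.sigma_e`` may be
    scalars or arrays broadcastable to ``size`` (one process per slot).
    """
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    phi = np.broadcast_to(np.asarray(params.phi, dtype=float), size)
    sigma = np.broadcast_to(np.asarray(params.sigma_e, dtype=float), size)
    if np.any(np.abs(phi) >= 1.0):
        raise InvalidParameterError("|phi| must be < 1")
    out = np.empty((n,) + size, dtype=float)
    sd0 = sigma / np.sqrt(1.0 - phi**2)
    out[0] = rng.standard_normal(size) * sd0
    innov = rng.standard_normal((n - 1,) + size)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + sigma * innov[t - 1]
    return out + params.mean


def ar1_ensemble_values(
    phi: np.ndarray,
    sigma_e: np.ndarray,
    n: int,
    size: tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean AR(1) ensemble with per-slot parameters, shape ``(n, *size)``."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float), size)
    sigma = np.broadcast_to(np.asarray(sigma_e, dtype=float), size)
    out = np.empty((n,) + size, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd0 = np.where(sigma > 0, sigma / np.sqrt(1.0 - phi**2), 0.0)
    out[0] = rng.standard_normal(size) * sd0
    innov = rng.standard_normal((n - 1,) + size)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + sigma * innov[t - 1]
    return out


# ---------------------------------------------------------------------------
# 1-D generators


def gen_ar1(
    n: int,
    params: AR1Params,
    seed: int,
    start_year: int = 0,
    units: str = "",
) -> AnnualSeries:
    """Annual AR(1) series of length ``n`` starting at ``start_year``."""
    rng = np.random.default_rng(seed)
    return AnnualSeries(start_year + np.arange(n), ar1_values(n, params, rng), units=units)


def gen_incidence_series(
    spec: PiecewiseTrendSpec,
    noise: AR1Params,
    seed: int,
    floor_at_zero: bool = False,
    units: str = "incidences/100,000",
) -> AnnualSeries:
    """Piecewise-linear signal plus AR(1) noise.

    ``floor_at_zero`` clips negative values to zero (incidence rates are
    non-negative).  Clipping is off by default because it distorts the AR(1)
    structure the surrogate tests are calibrated against.
    """
    signal = spec.signal()
    rng = np.random.default_rng(seed)
    values = signal.values + ar1_values(len(signal), noise, rng)
    if floor_at_zero:
        values = np.maximum(values, 0.0)
    return AnnualSeries(signal.years, values, units=units)


def phase_for_upcrossing(start_year: int, period: float, crossing_year: float) -> float:
    """Phase (radians) placing an ascending zero of the sinusoid at ``crossing_year``."""
    return float((-2.0 * math.pi * (crossing_year - start_year) / period) % (2.0 * math.pi))


def gen_oscillation_series(
    start_year: int,
    end_year: int,
    period: float,
    amplitude: float,
    phase: float,
    noise: AR1Params,
    seed: int,
    units: str = "",
) -> AnnualSeries:
    """Sinusoid ``amplitude * sin(2*pi*(t - start_year)/period + phase)`` + AR(1) noise."""
    if period <= 0:
        raise InvalidParameterError(f"period must be > 0, got {period}")
    if end_year <= start_year:
        raise InvalidParameterError("end_year must be > start_year")
    years = np.arange(start_year, end_year + 1)
    signal = amplitude * np.sin(2.0 * np.pi * (years - start_year) / period + phase)
    rng = np.random.default_rng(seed)
    values = signal + ar1_values(len(years), noise, rng)
    return AnnualSeries(years, values, units=units)


# ---------------------------------------------------------------------------
# gridded generator


def gen_gridded_field(
    grid: GridSpec,
    driver: AnnualSeries,
    corr_pattern: np.ndarray | float,
    trend_pattern: np.ndarray | float,
    noise: AR1Params,
    seed: int,
    climatology: float = 0.0,
    monthly_noise_sd: float | None = None,
    units: str = "",
):
    """Monthly gridded field with planted trend and driver correlation.

    At each cell the annual anomaly is::

        trend_pattern * elapsed_decades + alpha * z + eta

    where ``z`` is the standardized driver and ``eta`` is AR(1) noise with
    parameters ``noise``.  Monthly values are the annual anomaly plus
    ``climatology`` plus independent N(0, monthly_noise_sd) noise
    (``monthly_noise_sd`` defaults to ``noise.sigma_e``).  ``alpha`` is
    scaled per cell so the summer (3-month) mean series has expected
    correlation approximately ``corr_pattern`` with the driver.

    Returns a :class:`climepi.spatial.GriddedFieldSeries`.
    """
    from .spatial import GriddedFieldSeries  # local import to avoid a cycle

    lats, lons = grid.lats, grid.lons
    shape = (lats.size, lons.size)
    corr = np.broadcast_to(np.asarray(corr_pattern, dtype=float), shape).copy()
    trend = np.broadcast_to(np.asarray(trend_pattern, dtype=float), shape).copy()
    if np.any(np.abs(corr) > 1.0):
        raise InvalidParameterError("corr_pattern values must lie in [-1, 1]")

    years = grid.years
    if driver.start_year > years[0] or driver.end_year < years[-1]:
        raise AlignmentError("driver series does not cover the grid's year span")
    z = driver.window(int(years[0]), int(years[-1])).standardized()

    if monthly_noise_sd is None:
        monthly_noise_sd = noise.sigma_e
    if monthly_noise_sd < 0:
        raise InvalidParameterError("monthly_noise_sd must be >= 0")

    # noise variance of a seasonal (3-month) mean at a cell: the annual AR(1)
    # anomaly is common to all months of the year, the monthly noise averages
    # down by the season length.
    v = noise.stationary_variance + monthly_noise_sd**2 / SEASON_LENGTH
    if v > 0:
        if np.any(np.abs(corr) >= 1.0):
            raise InvalidParameterError(
                "corr_pattern magnitude 1 is unattainable with non-zero noise"
            )
        alpha = np.sign(corr) * np.sqrt(corr**2 * v / (1.0 - corr**2))
    else:
        alpha = corr.copy()

    rng = np.random.default_rng(seed)
    n_years = years.size
    elapsed_decades = (years - years[0]) / 10.0
    eta = ar1_ensemble_values(noise.phi, noise.sigma_e, n_years, shape, rng)
    annual = (
        elapsed_decades[:, None, None] * trend[None, :, :]
        + z[:, None, None] * alpha[None, :, :]
        + eta
    )

    n_months = len(grid.months)
    values = np.repeat(annual, n_months, axis=0) + climatology
    if monthly_noise_sd > 0:
        values = values + rng.normal(0.0, monthly_noise_sd, size=values.shape)

    times = np.array(grid.times, dtype=np.int64)
    return GriddedFieldSeries(
        lats=lats,
        lons=lons,
        years=times[:, 0],
        months=times[:, 1],
        values=values,
        units=units,
    )
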