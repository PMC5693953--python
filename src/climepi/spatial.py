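"""Gridded-field handling: seasonal means, domain subsetting, index
extraction, and per-gridpoint trend / correlation maps with Monte-Carlo
significance masks.

The field container is a plain (time, lat, lon) array with integer year and
month coordinates; NetCDF I/O goes through xarray.  Significance at each
cell uses the same red-noise surrogate logic as the 1-D tests
(:mod:`climepi.surrogate`), fitted cell by cell and simulated in one
vectorized batch.  No multiplicity correction is applied across cells: the
mask answers the per-gridpoint question, as is conventional for contoured
significance on climate maps, and spatially correlated fields will show
clustered false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import (
    AlignmentError,
    DomainError,
    InsufficientDataError,
    InvalidParameterError,
)
from .series import AnnualSeries
from .surrogate import invert_detrended_ar1, studentized_trend_statistic
from .synthetic import ar1_ensemble_values

DEFAULT_MAP_SURROGATES = 1_000
MIN_TREND_YEARS = 10
JJA = (6, 7, 8)


@dataclass
class GriddedFieldSeries:
    """A (time, lat, lon) field with integer year/month time coordinates.

    ``months is None`` marks an annual field (one time step per year, e.g.
    after seasonal averaging).
    """

    lats: np.ndarray
    lons: np.ndarray
    years: np.ndarray
    values: np.ndarray
    months: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.years = np.asarray(self.years, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.months is not None:
            self.months = np.asarray(self.months, dtype=np.int64)
            if self.months.shape != self.years.shape:
                raise InvalidParameterError("months and years must align")
        for coord, name in ((self.lats, "lats"), (self.lons, "lons")):
            if coord.ndim != 1 or (coord.size > 1 and not np.all(np.diff(coord) > 0)):
                raise InvalidParameterError(f"{name} must be 1-D strictly ascending")
        expected = (self.years.size, self.lats.size, self.lons.size)
        if self.values.shape != expected:
            raise InvalidParameterError(
                f"values shape {self.values.shape} != (time, lat, lon) {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("field contains missing or non-finite values")

    @property
    def is_annual(self) -> bool:
        return self.months is None

    # -- NetCDF I/O --------------------------------------------------------

    def to_xarray(self) -> xr.Dataset:
        coords = {
            "time": np.arange(self.years.size),
            "lat": self.lats,
            "lon": self.lons,
        }
        ds = xr.Dataset(
            {
                "field": (("time", "lat", "lon"), self.values),
                "year": (("time",), self.years),
            },
            coords=coords,
        )
        if self.months is not None:
            ds["month"] = (("time",), self.months)
        ds["field"].attrs["units"] = self.units
        return ds

    def to_netcdf(self, path: str | Path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "GriddedFieldSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
        months = ds["month"].values if "month" in ds else None
        return cls(
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            years=ds["year"].values,
            months=months,
            values=ds["field"].values,
            units=str(ds["field"].attrs.get("units", "")),
        )


@dataclass
class FieldMap:
    """A lat x lon statistic map with a Monte-Carlo significance mask."""

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray
    significance_mask: np.ndarray
    confidence_level_pct: float
    statistic_name: str
    units: str = ""

    def __post_init__(self) -> None:
        expected = (len(self.lats), len(self.lons))
        if self.values.shape != expected or self.significance_mask.shape != expected:
            raise InvalidParameterError("map shapes inconsistent with coordinates")

    def to_netcdf(self, path: str | Path) -> None:
        ds = xr.Dataset(
            {
                "stat": (("lat", "lon"), self.values),
                "significant": (("lat", "lon"), self.significance_mask.astype(np.int8)),
            },
            coords={"lat": self.lats, "lon": self.lons},
        )
        ds["stat"].attrs["units"] = self.units
        ds["stat"].attrs["statistic"] = self.statistic_name
        ds.attrs["confidence_level_pct"] = float(self.confidence_level_pct)
        ds.to_netcdf(path, engine="scipy")

    def to_csv(self, path: str | Path) -> None:
        lat_grid, lon_grid = np.meshgrid(self.lats, self.lons, indexing="ij")
        pd.DataFrame(
            {
                "lat": lat_grid.ravel(),
                "lon": lon_grid.ravel(),
                "stat": self.values.ravel(),
                "significant": self.significance_mask.ravel().astype(int),
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# seasonal averaging / subsetting / index extraction


def seasonal_annual_mean(
    field: GriddedFieldSeries, months: tuple[int, ...] = JJA
) -> GriddedFieldSeries:
    """Per-year unweighted mean over the listed months at every cell.

    Years missing any requested month are dropped.
    """
    if field.is_annual:
        raise InvalidParameterError("field is already annual")
    if len(months) == 0:
        raise InvalidParameterError("month selection must be non-empty")
    month_set = set(int(m) for m in months)
    if not month_set <= set(range(1, 13)):
        raise InvalidParameterError("months must lie in 1..12")
    years_out, slabs = [], []
    for year in np.unique(field.years):
        sel = (field.years == year) & np.isin(field.months, list(month_set))
        if sel.sum() != len(month_set):
            continue
        years_out.append(year)
        slabs.append(field.values[sel].mean(axis=0))
    if not years_out:
        raise DomainError("no year contains all requested months")
    return GriddedFieldSeries(
        lats=field.lats,
        lons=field.lons,
        years=np.array(years_out),
        values=np.stack(slabs),
        months=None,
        units=field.units,
    )


def subset_domain(
    field: GriddedFieldSeries,
    lat_min: float = 40.0,
    lat_max: float = 70.0,
    lon_min: float = -35.0,
    lon_max: float = 35.0,
) -> GriddedFieldSeries:
    """Inclusive-bounds lat/lon box subsetting."""
    lat_sel = (field.lats >= lat_min) & (field.lats <= lat_max)
    lon_sel = (field.lons >= lon_min) & (field.lons <= lon_max)
    if not lat_sel.any() or not lon_sel.any():
        raise DomainError(
            f"box [{lat_min},{lat_max}]x[{lon_min},{lon_max}] does not "
            "intersect the grid"
        )
    return replace(
        field,
        lats=field.lats[lat_sel],
        lons=field.lons[lon_sel],
        values=field.values[:, lat_sel][:, :, lon_sel],
    )


def domain_mean_index(
    field: GriddedFieldSeries,
    lat_min: float,
    lat_max: float,
    lon_min: float,
    lon_max: float,
) -> AnnualSeries:
    """Cosine-latitude-weighted spatial mean of an annual field over a box."""
    if not field.is_annual:
        raise InvalidParameterError(
            "domain_mean_index expects an annual field; apply "
            "seasonal_annual_mean first"
        )
    sub = subset_domain(field, lat_min, lat_max, lon_min, lon_max)
    w = np.cos(np.deg2rad(sub.lats))
    weights = np.broadcast_to(w[:, None], (sub.lats.size, sub.lons.size))
    index = np.tensordot(sub.values, weights, axes=([1, 2], [0, 1])) / weights.sum()
    return AnnualSeries(sub.years, index, units=field.units)


# ---------------------------------------------------------------------------
# cell-wise statistics with Monte-Carlo masks


def _cellwise_ar1(resid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column AR(1) fit of (T, C) residuals; same rules as
    :func:`climepi.surrogate.estimate_ar1_values` with constant columns
    degrading to (phi=0, sigma=0)."""
    t = resid.shape[0]
    a = resid[:-1] - resid[:-1].mean(axis=0)
    b = resid[1:] - resid[1:].mean(axis=0)
    denom = np.sqrt(np.sum(a**2, axis=0) * np.sum(b**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(denom > 0, np.sum(a * b, axis=0) / denom, 0.0)
    r1 = r1 + (1.0 + 3.0 * r1) / t  # small-sample bias correction
    phi = np.clip(r1, 0.0, 0.99)
    sd = resid.std(axis=0, ddof=1)
    sigma = sd * np.sqrt(1.0 - phi**2)
    return phi, sigma


def _cellwise_trend_p(
    data: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed per-year slopes and two-sided MC p-values per column of a
    (T, C) matrix."""
    t_len, n_cells = data.shape
    t = np.arange(t_len) - (t_len - 1) / 2.0
    sxx = t @ t
    slopes = t @ (data - data.mean(axis=0)) / sxx
    resid = data - data.mean(axis=0) - np.outer(t, slopes)
    # detrending-aware AR(1) fit per cell (see climepi.surrogate)
    ss = np.sum(resid**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(ss > 0, np.sum(resid[:-1] * resid[1:], axis=0) / ss, 0.0)
    phi, sigma = invert_detrended_ar1(r1, ss / (t_len - 1), t_len)
    sigma = np.where(ss > 0, sigma, 0.0)
    # studentized comparison, as in climepi.surrogate.trend_significance
    tau_obs = studentized_trend_statistic(data)
    sims = ar1_ensemble_values(phi, sigma, t_len, (n_surrogates, n_cells), rng)
    tau_null = studentized_trend_statistic(
        sims.reshape(t_len, n_surrogates * n_cells)
    ).reshape(n_surrogates, n_cells)
    with np.errstate(invalid="ignore"):
        exceed = np.abs(tau_null) >= np.abs(tau_obs)[None, :]
    # noise-free cells: tau_obs = +/-inf beats every finite surrogate
    p = (1 + np.sum(exceed, axis=0)) / (n_surrogates + 1)
    return slopes, p


def _standardize_time(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    sd = np.sqrt(np.sum(xc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, xc / sd, 0.0)


def _cellwise_corr_p(
    index: np.ndarray, data: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed Pearson r and MC p-values of an index against each column
    of (T, C) data, under independent AR(1) surrogates of both sides."""
    t_len, n_cells = data.shape
    r_obs = _standardize_time(index[:, None])[:, 0] @ _standardize_time(data)
    phi_i, sigma_i = _cellwise_ar1(index[:, None] - index.mean())
    phi_c, sigma_c = _cellwise_ar1(data - data.mean(axis=0))
    sims_i = ar1_ensemble_values(phi_i, sigma_i, t_len, (n_surrogates, 1), rng)
    sims_c = ar1_ensemble_values(phi_c, sigma_c, t_len, (n_surrogates, n_cells), rng)
    zi = _standardize_time(sims_i.reshape(t_len, n_surrogates))
    zc_flat = _standardize_time(sims_c.reshape(t_len, -1)).reshape(
        t_len, n_surrogates, n_cells
    )
    null = np.einsum("ts,tsc->sc", zi, zc_flat)
    p = (1 + np.sum(np.abs(null) >= np.abs(r_obs)[None, :], axis=0)) / (
        n_surrogates + 1
    )
    return r_obs, p


def trend_map(
    field: GriddedFieldSeries,
    start_year: int,
    end_year: int,
    n_surrogates: int = DEFAULT_MAP_SURROGATES,
    seed: int | None = None,
    cl: float = 95.0,
) -> FieldMap:
    """Per-cell OLS trend (units/decade) with a red-noise significance mask.

    Each cell gets its own AR(1) fit to its detrended series; the mask marks
    cells whose |slope| exceeds the two-sided ``cl``% surrogate envelope.
    """
    if not field.is_annual:
        raise InvalidParameterError("trend_map expects an annual field")
    sel = (field.years >= start_year) & (field.years <= end_year)
    if sel.sum() < MIN_TREND_YEARS:
        raise InsufficientDataError(
            f"window [{start_year}, {end_year}] has {int(sel.sum())} years; "
            f"need >= {MIN_TREND_YEARS}"
        )
    data = field.values[sel].reshape(int(sel.sum()), -1)
    rng = np.random.default_rng(seed)
    slopes, p = _cellwise_trend_p(data, n_surrogates, rng)
    shape = (field.lats.size, field.lons.size)
    alpha = 1.0 - cl / 100.0
    return FieldMap(
        lats=field.lats,
        lons=field.lons,
        values=(slopes * 10.0).reshape(shape),
        significance_mask=(p <= alpha).reshape(shape),
        confidence_level_pct=cl,
        statistic_name="trend",
        units=f"{field.units}/decade" if field.units else "units/decade",
    )


def correlation_map(
    index: AnnualSeries,
    field: GriddedFieldSeries,
    n_surrogates: int = DEFAULT_MAP_SURROGATES,
    seed: int | None = None,
    cl: float = 95.0,
) -> FieldMap:
    """Per-cell Pearson correlation of an annual index with an annual field,
    with a red-noise significance mask."""
    if not field.is_annual:
        raise InvalidParameterError("correlation_map expects an annual field")
    if index.years.size != field.years.size or not np.array_equal(
        index.years, field.years
    ):
        raise AlignmentError("index and field must share identical years")
    data = field.values.reshape(field.years.size, -1)
    rng = np.random.default_rng(seed)
    r_obs, p = _cellwise_corr_p(index.values, data, n_surrogates, rng)
    shape = (field.lats.size, field.lons.size)
    alpha = 1.0 - cl / 100.0
    return FieldMap(
        lats=field.lats,
        lons=field.lons,
        values=r_obs.reshape(shape),
        significance_mask=(p <= alpha).reshape(shape),
        confidence_level_pct=cl,
        statistic_name="correlation",
        units="",
    )
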