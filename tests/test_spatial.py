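import numpy as np
import pytest

import climepi as c
from climepi.exceptions import (
    AlignmentError,
    DomainError,
    InsufficientDataError,
    InvalidParameterError,
)
from climepi.spatial import JJA, GriddedFieldSeries


class TestSeasonalAnnualMean:
    def test_constant_field_stays_constant(self, small_field):
        const = GriddedFieldSeries(
            lats=small_field.lats,
            lons=small_field.lons,
            years=small_field.years,
            months=small_field.months,
            values=np.full_like(small_field.values, 3.5),
        )
        annual = c.seasonal_annual_mean(const, JJA)
        np.testing.assert_allclose(annual.values, 3.5)
        assert annual.is_annual

    def test_june_july_august_arithmetic_mean(self, small_grid):
        times = np.array(small_grid.times)
        values = np.zeros((times.shape[0], 4, 5))
        values[times[:, 1] == 6] = 1.0
        values[times[:, 1] == 7] = 2.0
        values[times[:, 1] == 8] = 3.0
        f = GriddedFieldSeries(
            small_grid.lats, small_grid.lons, times[:, 0], values, months=times[:, 1]
        )
        annual = c.seasonal_annual_mean(f, JJA)
        np.testing.assert_allclose(annual.values, 2.0)

    def test_matches_per_cell_loop_oracle(self, small_field):
        annual = c.seasonal_annual_mean(small_field, JJA)
        for yi, year in enumerate(annual.years):
            for i in range(small_field.lats.size):
                for j in range(small_field.lons.size):
                    vals = [
                        small_field.values[t, i, j]
                        for t in range(small_field.years.size)
                        if small_field.years[t] == year
                        and small_field.months[t] in JJA
                    ]
                    assert np.isclose(annual.values[yi, i, j], np.mean(vals))

    def test_years_missing_a_month_are_dropped(self, small_field):
        keep = ~((small_field.years == 2001) & (small_field.months == 7))
        trimmed = GriddedFieldSeries(
            small_field.lats,
            small_field.lons,
            small_field.years[keep],
            small_field.values[keep],
            months=small_field.months[keep],
        )
        annual = c.seasonal_annual_mean(trimmed, JJA)
        assert 2001 not in annual.years

    def test_empty_month_selection_rejected(self, small_field):
        with pytest.raises(InvalidParameterError):
            c.seasonal_annual_mean(small_field, ())


class TestSubsetAndIndex:
    def test_full_box_is_identity(self, small_field):
        sub = c.subset_domain(small_field, 40, 43, -2, 2)
        np.testing.assert_array_equal(sub.values, small_field.values)

    def test_single_cell_box(self, small_field):
        sub = c.subset_domain(small_field, 41, 41, 0, 0)
        assert sub.values.shape[1:] == (1, 1)
        np.testing.assert_array_equal(
            sub.values[:, 0, 0], small_field.values[:, 1, 2]
        )

    def test_inclusive_bounds_cell_count_on_fine_registry(self):
        # 0.75-degree registry: latitudes 40.0 .. 70.0 inclusive -> 41 rows
        grid = c.GridSpec(0.0, 87.0, -90.0, 90.0, 0.75, 2000, 2001)
        driver = c.gen_ar1(2, c.AR1Params(0.0, 1.0), seed=0, start_year=2000)
        f = c.gen_gridded_field(
            grid, driver, 0.0, 0.0, c.AR1Params(0.0, 0.0), seed=0, monthly_noise_sd=0.0
        )
        sub = c.subset_domain(f, 40.0, 70.0, -35.0, 35.0)
        # integer-arithmetic oracle: cells at lat = 0.75*k, lon = -90 + 0.75*j
        n_lat = int(np.floor(70.0 / 0.75)) - int(np.ceil(40.0 / 0.75)) + 1
        n_lon = int(np.floor((35.0 + 90.0) / 0.75)) - int(np.ceil((-35.0 + 90.0) / 0.75)) + 1
        assert sub.values.shape[1:] == (n_lat, n_lon)

    def test_empty_intersection_rejected(self, small_field):
        with pytest.raises(DomainError):
            c.subset_domain(small_field, -50, -40, 0, 1)

    def test_constant_field_index_ignores_weights(self, small_field):
        const = GriddedFieldSeries(
            small_field.lats,
            small_field.lons,
            np.array([2000, 2001, 2002]),
            np.full((3, 4, 5), 7.0),
        )
        idx = c.domain_mean_index(const, 40, 43, -2, 2)
        np.testing.assert_allclose(idx.values, 7.0)

    def test_two_row_cosine_weighting_closed_form(self):
        lats = np.array([40.0, 60.0])
        field = GriddedFieldSeries(
            lats,
            np.array([0.0]),
            np.array([2000]),
            np.array([[[1.0], [2.0]]]),
        )
        idx = c.domain_mean_index(field, 40, 60, 0, 0)
        w1, w2 = np.cos(np.deg2rad(40.0)), np.cos(np.deg2rad(60.0))
        assert np.isclose(idx.values[0], (w1 * 1.0 + w2 * 2.0) / (w1 + w2))

    def test_planted_uniform_driver_reproduced_affinely(self, small_grid):
        driver = c.gen_ar1(3, c.AR1Params(0.0, 1.0), seed=1, start_year=2000)
        f = c.gen_gridded_field(
            small_grid, driver, 1.0, 0.0, c.AR1Params(0.0, 0.0), seed=2, monthly_noise_sd=0.0
        )
        annual = c.seasonal_annual_mean(f, JJA)
        idx = c.domain_mean_index(annual, 40, 43, -2, 2)
        assert np.isclose(abs(np.corrcoef(idx.values, driver.values)[0, 1]), 1.0)

    def test_subset_then_average_equals_average_then_subset(self, small_field):
        a = c.seasonal_annual_mean(c.subset_domain(small_field, 41, 43, -1, 1), JJA)
        b = c.subset_domain(c.seasonal_annual_mean(small_field, JJA), 41, 43, -1, 1)
        np.testing.assert_allclose(a.values, b.values)


class TestTrendMap:
    def _annual_field(self, values, start_year=1990):
        n_t, n_lat, n_lon = values.shape
        return GriddedFieldSeries(
            lats=np.arange(40.0, 40.0 + n_lat),
            lons=np.arange(0.0, 0.0 + n_lon),
            years=np.arange(start_year, start_year + n_t),
            values=values,
        )

    def test_planted_uniform_trend_recovered_exactly_and_significant(self):
        t = np.arange(20)
        values = np.broadcast_to(
            (0.1 * t)[:, None, None], (20, 3, 4)
        ).copy()
        fmap = c.trend_map(self._annual_field(values), 1990, 2009, n_surrogates=200, seed=1)
        np.testing.assert_allclose(fmap.values, 1.0, atol=1e-10)
        assert fmap.significance_mask.all()

    def test_slopes_match_per_cell_loop_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(15, 3, 4))
        field = self._annual_field(values)
        fmap = c.trend_map(field, 1990, 2004, n_surrogates=200, seed=3)
        for i in range(3):
            for j in range(4):
                slope = np.polyfit(field.years, values[:, i, j], 1)[0]
                assert np.isclose(fmap.values[i, j], slope * 10.0)

    def test_time_reversal_negates_every_trend(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(15, 3, 4))
        f1 = self._annual_field(values)
        f2 = self._annual_field(values[::-1])
        m1 = c.trend_map(f1, 1990, 2004, n_surrogates=200, seed=5)
        m2 = c.trend_map(f2, 1990, 2004, n_surrogates=200, seed=5)
        np.testing.assert_allclose(m1.values, -m2.values, atol=1e-10)

    def test_short_window_rejected(self):
        values = np.zeros((8, 2, 2))
        with pytest.raises(InsufficientDataError):
            c.trend_map(self._annual_field(values), 1990, 1997)


class TestCorrelationMap:
    def test_perfectly_driven_field_correlates_at_one(self, small_grid):
        driver = c.gen_ar1(3, c.AR1Params(0.0, 1.0), seed=6, start_year=2000)
        f = c.gen_gridded_field(
            small_grid, driver, 1.0, 0.0, c.AR1Params(0.0, 0.0), seed=7, monthly_noise_sd=0.0
        )
        annual = c.seasonal_annual_mean(f, JJA)
        fmap = c.correlation_map(driver, annual, n_surrogates=200, seed=8)
        np.testing.assert_allclose(fmap.values, 1.0, atol=1e-10)

    def test_r_values_match_per_cell_loop_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(30, 3, 4))
        field = GriddedFieldSeries(
            np.arange(40.0, 43.0), np.arange(0.0, 4.0),
            np.arange(1980, 2010), values,
        )
        index = c.AnnualSeries(np.arange(1980, 2010), rng.normal(size=30))
        fmap = c.correlation_map(index, field, n_surrogates=200, seed=10)
        for i in range(3):
            for j in range(4):
                r = np.corrcoef(index.values, values[:, i, j])[0, 1]
                assert np.isclose(fmap.values[i, j], r)

    def test_year_mismatch_rejected(self):
        values = np.zeros((30, 2, 2)) + np.random.default_rng(0).normal(size=(30, 2, 2))
        field = GriddedFieldSeries(
            np.arange(40.0, 42.0), np.arange(0.0, 2.0),
            np.arange(1980, 2010), values,
        )
        index = c.AnnualSeries(np.arange(1981, 2011), np.zeros(30) + 1.0)
        with pytest.raises(AlignmentError):
            c.correlation_map(index, field)


class TestNetCDFIO:
    def test_field_round_trip(self, small_field, tmp_path):
        path = tmp_path / "field.nc"
        small_field.to_netcdf(path)
        back = GriddedFieldSeries.from_netcdf(path)
        np.testing.assert_allclose(back.values, small_field.values)
        np.testing.assert_array_equal(back.years, small_field.years)
        np.testing.assert_array_equal(back.months, small_field.months)
        assert back.units == small_field.units

    def test_fieldmap_round_trip_attributes(self, tmp_path):
        import xarray as xr

        fmap = c.FieldMap(
            lats=np.array([40.0, 41.0]),
            lons=np.array([0.0, 1.0, 2.0]),
            values=np.arange(6.0).reshape(2, 3),
            significance_mask=np.array([[True, False, True], [False, True, False]]),
            confidence_level_pct=95.0,
            statistic_name="trend",
            units="mb/decade",
        )
        path = tmp_path / "map.nc"
        fmap.to_netcdf(path)
        with xr.open_dataset(path, engine="scipy") as ds:
            assert ds.attrs["confidence_level_pct"] == 95.0
            np.testing.assert_allclose(ds["stat"].values, fmap.values)
            np.testing.assert_array_equal(
                ds["significant"].values.astype(bool), fmap.significance_mask
            )
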