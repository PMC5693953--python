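import numpy as np
import pytest

import climepi as c


@pytest.fixture
def incidence_spec():
    """Piecewise incidence signal: decline then rise, break at 1997."""
    return c.PiecewiseTrendSpec(
        1963, 2011, 1997, intercept=0.951, slope_pre=-0.023, slope_post=0.104
    )


@pytest.fixture
def incidence_noise():
    return c.AR1Params(phi=0.3, sigma_e=0.15)


@pytest.fixture
def v_series():
    """Noiseless symmetric V with kink at 1995."""
    spec = c.PiecewiseTrendSpec(
        1980, 2010, 1995, intercept=3.0, slope_pre=-0.2, slope_post=0.2
    )
    return spec.signal()


@pytest.fixture
def small_grid():
    """4 x 5 grid, 3 years of monthly data."""
    return c.GridSpec(
        lat_min=40.0,
        lat_max=43.0,
        lon_min=-2.0,
        lon_max=2.0,
        resolution=1.0,
        start_year=2000,
        end_year=2002,
    )


@pytest.fixture
def small_field(small_grid):
    rng = np.random.default_rng(7)
    times = np.array(small_grid.times)
    values = rng.normal(0.0, 1.0, size=(times.shape[0], 4, 5))
    from climepi.spatial import GriddedFieldSeries

    return GriddedFieldSeries(
        lats=small_grid.lats,
        lons=small_grid.lons,
        years=times[:, 0],
        months=times[:, 1],
        values=values,
        units="mb",
    )
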