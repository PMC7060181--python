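import numpy as np
import pytest
import xarray as xr

from cropshift import (
    GriddedField,
    ScenarioSpec,
    crop_season_panel,
    make_area_scenario,
    make_calendar,
    make_climate,
    make_weights,
)


def grid_coords(nlat=4, nlon=4, res=0.5, lat0=40.25, lon0=0.25):
    return {
        "lat": lat0 + res * np.arange(nlat),
        "lon": lon0 + res * np.arange(nlon),
    }


def field_2d(values, units="ha", name="area", **kw):
    """A (lat, lon) GriddedField from a 2-D array."""
    values = np.asarray(values, dtype=float)
    coords = grid_coords(nlat=values.shape[0], nlon=values.shape[1], **kw)
    da = xr.DataArray(values, coords=coords, dims=("lat", "lon"))
    return GriddedField(da, units=units, name=name)


@pytest.fixture(scope="session")
def small_spec():
    """A fast scenario: 10x10 cells, full 40-year record."""
    return ScenarioSpec(scenario="static", nlat=10, nlon=10, seed=321)


@pytest.fixture(scope="session")
def migration_panel():
    """Season panel plus weights for a fast migration scenario."""
    spec = ScenarioSpec(scenario="migration", nlat=12, nlon=12, seed=77)
    climate = make_climate(spec)
    panel, _ = make_area_scenario(spec)
    season = crop_season_panel(climate, make_calendar(spec), spec.years)
    return season, make_weights(panel, "dynamic"), make_weights(panel, "static")


@pytest.fixture(scope="session")
def small_setup(small_spec):
    """Climate, panel, calendar, season panel and weights for the fast scenario."""
    climate = make_climate(small_spec)
    panel, truth = make_area_scenario(small_spec)
    calendar = make_calendar(small_spec)
    season = crop_season_panel(climate, calendar, small_spec.years)
    dynamic = make_weights(panel, "dynamic")
    static = make_weights(panel, "static")
    return {
        "spec": small_spec,
        "climate": climate,
        "panel": panel,
        "truth": truth,
        "calendar": calendar,
        "season": season,
        "dynamic": dynamic,
        "static": static,
    }
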