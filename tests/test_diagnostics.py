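import numpy as np
import pytest
import xarray as xr
from scipy import stats

from cropshift import (
    build_area_panel,
    cell_trend,
    cell_trend_map,
    centroid_shift,
    make_yields,
    quadratic_term_test,
    significant_area_fraction,
    weighted_centroid,
    weighted_quantile,
    yield_extreme_comparison,
)
from cropshift.diagnostics import _haversine_km, _initial_bearing_deg

from conftest import field_2d, grid_coords
from test_area_weights import area_field


def closed_form_ols(t, y):
    """Textbook OLS slope/p/r2 computed from sums, independent of scipy."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    tc = t - t.mean()
    yc = y - y.mean()
    slope = (tc * yc).sum() / (tc**2).sum()
    resid = yc - slope * tc
    se = np.sqrt((resid**2).sum() / (n - 2) / (tc**2).sum())
    tstat = slope / se
    p = 2 * stats.t.sf(abs(tstat), n - 2)
    r2 = 1 - (resid**2).sum() / (yc**2).sum()
    return slope, p, r2


class TestCellTrend:
    def test_perfect_line(self):
        t = np.arange(10)
        res = cell_trend(1 + 0.1 * t, t)
        assert res.slope == pytest.approx(0.1)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_series(self):
        res = cell_trend(np.full(8, 5.0), np.arange(8))
        assert res.slope == pytest.approx(0.0)

    def test_five_point_closed_form(self):
        t = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 4, 3, 5, 7], float)
        slope, p, r2 = closed_form_ols(t, y)
        res = cell_trend(y, t)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_too_few_years_masked(self):
        res = cell_trend(np.array([1.0, 2.0, np.nan]), np.arange(3))
        assert np.isnan(res.slope)

    def test_map_matches_per_cell_oracle(self):
        rng = np.random.default_rng(1)
        years = np.arange(1990, 2010)
        vals = rng.normal(10, 2, (20, 3, 4))
        vals[5, 0, 0] = np.nan
        vals[:, 1, 2] = np.nan
        da = xr.DataArray(
            vals, coords={"year": years, **grid_coords(3, 4)}, dims=("year", "lat", "lon")
        )
        ds = cell_trend_map(da)
        for i in range(3):
            for j in range(4):
                ok = np.isfinite(vals[:, i, j])
                if ok.sum() < 3:
                    assert np.isnan(ds["slope"].values[i, j])
                    continue
                slope, p, r2 = closed_form_ols(years[ok], vals[ok, i, j])
                assert ds["slope"].values[i, j] == pytest.approx(slope, abs=1e-10)
                assert ds["p_value"].values[i, j] == pytest.approx(p, abs=1e-10)
                assert ds["r_squared"].values[i, j] == pytest.approx(r2, abs=1e-10)


class TestQuadraticTermTest:
    def test_pure_linear_has_no_quadratic_evidence(self):
        t = np.arange(1990, 2000).astype(float)
        assert quadratic_term_test(1 + 0.1 * t, t) == 1.0

    def test_exact_parabola_is_certain(self):
        t = np.arange(10).astype(float)
        assert quadratic_term_test(t**2, t) == 0.0

    def test_matches_statsmodels_formula(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        t = np.arange(1973, 2013).astype(float)
        y = 10 + 0.03 * (t - t.mean()) + rng.normal(0, 0.5, t.size)
        tc = t - t.mean()
        X = sm.add_constant(np.column_stack([tc, tc**2]))
        p_sm = sm.OLS(y, X).fit().pvalues[2]
        assert quadratic_term_test(y, t) == pytest.approx(p_sm, abs=1e-10)

    def test_too_few_points_masked(self):
        assert np.isnan(quadratic_term_test(np.array([1.0, 2.0, 3.0]), np.arange(3)))


class TestSignificantAreaFraction:
    def trend_ds(self, slopes, ps):
        coords = grid_coords(1, len(slopes))
        return xr.Dataset(
            {
                "slope": (("lat", "lon"), [slopes]),
                "p_value": (("lat", "lon"), [ps]),
            },
            coords=coords,
        )

    def test_all_cells_significant_warming(self):
        ds = self.trend_ds([0.1, 0.2], [0.01, 0.02])
        areas = field_2d([[1.0, 1.0]])
        assert significant_area_fraction(ds, areas) == pytest.approx(100.0)

    def test_none_significant(self):
        ds = self.trend_ds([0.1, 0.2], [0.5, 0.9])
        areas = field_2d([[1.0, 1.0]])
        assert significant_area_fraction(ds, areas) == pytest.approx(0.0)

    def test_half_area_significant(self):
        ds = self.trend_ds([0.1, 0.2], [0.01, 0.5])
        areas = field_2d([[1.0, 1.0]])
        assert significant_area_fraction(ds, areas) == pytest.approx(50.0)

    def test_direction_and_complement_bound(self):
        rng = np.random.default_rng(2)
        slopes = rng.normal(0, 1, 25).reshape(5, 5)
        ps = rng.uniform(0, 1, 25).reshape(5, 5)
        ds = xr.Dataset(
            {"slope": (("lat", "lon"), slopes), "p_value": (("lat", "lon"), ps)},
            coords=grid_coords(5, 5),
        )
        areas = field_2d(rng.uniform(0, 10, (5, 5)))
        warm = significant_area_fraction(ds, areas, direction="warming")
        cool = significant_area_fraction(ds, areas, direction="cooling")
        assert warm + cool <= 100.0 + 1e-9

    def test_zero_area_rejected(self):
        ds = self.trend_ds([0.1], [0.01])
        with pytest.raises(ValueError):
            significant_area_fraction(ds, field_2d([[0.0]]))


class TestCentroid:
    def test_symmetric_area_centers_on_parallel(self):
        areas = field_2d(np.ones((3, 3)))
        lat, lon = weighted_centroid(areas)
        assert lat == pytest.approx(float(areas.data["lat"].values[1]))

    def test_single_cell(self):
        vals = np.zeros((3, 3))
        vals[2, 1] = 5.0
        areas = field_2d(vals)
        lat, lon = weighted_centroid(areas)
        assert lat == pytest.approx(float(areas.data["lat"].values[2]))
        assert lon == pytest.approx(float(areas.data["lon"].values[1]))

    def test_weighted_mean_arithmetic(self):
        da = xr.DataArray(
            [[10.0], [30.0]], coords={"lat": [0.0, 4.0], "lon": [0.0]}, dims=("lat", "lon")
        )
        lat, lon = weighted_centroid(da)
        assert lat == pytest.approx(3.0)
        assert lon == pytest.approx(0.0)

    def test_longitude_translation_equivariance(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, (4, 4))
        a = field_2d(vals, lon0=0.25)
        b = field_2d(vals, lon0=10.25)
        lat_a, lon_a = weighted_centroid(a)
        lat_b, lon_b = weighted_centroid(b)
        assert lat_b == pytest.approx(lat_a)
        assert lon_b == pytest.approx(lon_a + 10.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="zero total area"):
            weighted_centroid(field_2d(np.zeros((2, 2))))


class TestCentroidShift:
    def panel_with_moving_area(self, lat_from, lat_to):
        years = list(range(1973, 2013))
        lats = [0.0, 1.0]
        vals = np.zeros((len(years), 2, 1))
        for i, y in enumerate(years):
            vals[i, 0 if y < 2000 else 1, 0] = 10.0
        da = xr.DataArray(
            vals, coords={"year": years, "lat": lats, "lon": [5.0]}, dims=("year", "lat", "lon")
        )
        total = type(field_2d([[1.0]]))(da, units="ha", name="a")
        return build_area_panel(total, xr.zeros_like(da))

    def test_identical_windows_no_displacement(self, small_setup):
        track = centroid_shift(
            small_setup["panel"], window_start=(1973, 1977), window_end=(1973, 1977)
        )
        assert track.displacement_km == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_north_at_equator(self):
        panel = self.panel_with_moving_area(0.0, 1.0)
        track = centroid_shift(panel)
        assert track.displacement_km == pytest.approx(2 * np.pi * 6371.0 / 360.0, rel=1e-4)
        assert track.bearing_deg == pytest.approx(0.0, abs=1e-9)

    def test_eastward_shift_has_bearing_90(self):
        assert _initial_bearing_deg(0.0, 0.0, 0.0, 3.0) == pytest.approx(90.0)

    def test_haversine_against_law_of_cosines(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            lat1, lat2 = rng.uniform(-60, 60, 2)
            lon1, lon2 = rng.uniform(-120, 120, 2)
            got = _haversine_km(lat1, lon1, lat2, lon2)
            p1, p2 = np.radians([lat1, lat2])
            expect = 6371.0 * np.arccos(
                np.clip(
                    np.sin(p1) * np.sin(p2)
                    + np.cos(p1) * np.cos(p2) * np.cos(np.radians(lon2 - lon1)),
                    -1,
                    1,
                )
            )
            assert got == pytest.approx(expect, abs=1e-6)


class TestWeightedQuantile:
    def test_cumulative_area_definition(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([1.0, 1.0, 1.0, 1.0])
        assert weighted_quantile(v, w, 0.5) == 2.0
        assert weighted_quantile(v, w, 0.75) == 3.0
        assert weighted_quantile(v, w, 0.9) == 4.0


class TestYieldExtremes:
    def maps(self, yields, temps, areas):
        n = len(yields)
        mk = lambda v: xr.DataArray([v], coords=grid_coords(1, n), dims=("lat", "lon"))
        return mk(yields), mk(temps), mk(areas)

    def test_uniform_yields_no_differences(self):
        y, t, a = self.maps([5.0] * 20, list(range(20)), [1.0] * 20)
        comp = yield_extreme_comparison(y, t, a, n_boot=50, seed=0)
        assert comp.pct_diff_hot == pytest.approx(0.0)
        assert comp.pct_diff_cold == pytest.approx(0.0)

    def test_hot_bin_at_half_yield(self):
        temps = np.arange(20.0)
        yields = np.full(20, 6.0)
        yields[temps > 18.0] = 3.0  # the single hottest cell is the hot bin
        y, t, a = self.maps(list(yields), list(temps), [1.0] * 20)
        comp = yield_extreme_comparison(y, t, a, n_boot=50, seed=0)
        assert comp.pct_diff_hot == pytest.approx(-50.0)

    def test_area_scale_invariance(self):
        rng = np.random.default_rng(5)
        yields = rng.uniform(2, 8, 30)
        temps = rng.uniform(5, 25, 30)
        areas = rng.uniform(0.5, 3, 30)
        y, t, a = self.maps(list(yields), list(temps), list(areas))
        y2, t2, a2 = self.maps(list(yields), list(temps), list(2 * areas))
        c1 = yield_extreme_comparison(y, t, a, n_boot=40, seed=9)
        c2 = yield_extreme_comparison(y2, t2, a2, n_boot=40, seed=9)
        assert c1.mean_yield_mid == pytest.approx(c2.mean_yield_mid)
        assert c1.pct_diff_hot == pytest.approx(c2.pct_diff_hot)
        assert c1.p_hot == pytest.approx(c2.p_hot)

    def test_bins_partition_positive_area(self):
        rng = np.random.default_rng(6)
        temps = rng.uniform(0, 30, 50)
        areas = rng.uniform(0, 2, 50)
        lo = weighted_quantile(temps, areas, 0.05)
        hi = weighted_quantile(temps, areas, 0.95)
        ok = areas > 0
        cold = ok & (temps <= lo)
        hot = ok & (temps > hi)
        mid = ok & ~cold & ~hot
        assert (areas[cold].sum() + areas[mid].sum() + areas[hot].sum()) == pytest.approx(
            areas[ok].sum()
        )

    def test_gaussian_yield_surface_has_lower_hot_tail(self):
        temps = np.linspace(5, 30, 40)
        da_t = xr.DataArray([list(temps)], coords=grid_coords(1, 40), dims=("lat", "lon"))
        yields = make_yields(da_t, optimum=15.0, breadth=4.0)
        areas = xr.DataArray([[1.0] * 40], coords=grid_coords(1, 40), dims=("lat", "lon"))
        comp = yield_extreme_comparison(yields.data, da_t, areas, n_boot=60, seed=1)
        assert comp.pct_diff_hot < -50.0
        assert comp.p_hot < 0.05
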