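"""Synthetic gridded climates, calendars, area panels, and yield surfaces.

Every generator is a pure, seeded function of its scenario specification, so
the full analysis can be exercised at desk scale against known truth. The
default configuration emulates the data regime of the real analysis: a
half-degree grid over a 10-degree mid-latitude band, 40 analysis years
(1973-2012, with one spin-up year of climate for winter seasons), monthly
temperatures with a latitudinal gradient, sinusoidal seasonality (flipped in
the southern hemisphere), a linear warming trend, and independent
cell-month Gaussian noise.

Area scenarios
--------------
* ``static``: a Gaussian-in-latitude rainfed area surface, constant in time.
  No migration signal; the adaptation test should find no evidence.
* ``migration``: the same surface whose latitude center moves poleward at a
  constant velocity — crops tracking cooler conditions.
* ``expansion``: the surface gains area each year in cells warmer than the
  current area-weighted 95th-percentile temperature, mimicking expansion
  into even warmer environments (the soybean-like regime, whose observed
  harvested areas grew on the order of 2% per year into warm regions).
* ``irrigation_expansion``: total area is static but the irrigated fraction
  rises toward its maximum in the hottest decile of cultivated cells, so the
  *rainfed* distribution cools without any cell changing total area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .area_weights import AreaPanel
from .grids import Grid, GriddedField
from .season_temp import CropCalendar

__all__ = [
    "ScenarioSpec",
    "ScenarioTruth",
    "SCENARIOS",
    "make_climate",
    "make_area_scenario",
    "make_calendar",
    "make_yields",
]

SCENARIOS = ("static", "migration", "expansion", "irrigation_expansion")


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study condition.

    Defaults give a 20x20 half-degree grid (≈400 cells) over 35-45 N,
    years 1973-2012, 0.03 degC/yr warming, a 0.5 degC/degree-latitude
    gradient, 8 degC seasonal amplitude, and 0.5 degC cell-month noise.
    """

    scenario: str = "static"
    nlat: int = 20
    nlon: int = 20
    resolution_deg: float = 0.5
    lat_start: float = 35.25  # southernmost cell center
    lon_start: float = 0.25
    year_start: int = 1973
    year_end: int = 2012
    base_temp: float = 30.0  # degC at the equator before the gradient
    warming_rate: float = 0.03  # degC per year
    lat_gradient: float = 0.5  # degC cooling per degree |latitude|
    seasonal_amplitude: float = 8.0  # degC
    noise_sd: float = 0.5  # degC, iid per cell-month
    spatial_smoothing: float = 0.0  # gaussian sigma in cells; 0 disables
    migration_velocity: float = 0.05  # degrees latitude per year (migration only)
    area_peak: float = 1000.0  # ha at the Gaussian center
    area_center_lat: float | None = None  # None: per-scenario default (see center_lat)
    area_sigma_deg: float = 2.0
    expansion_rate: float = 0.025  # fraction of total area added per year (expansion)
    irrigation_max: float = 0.9  # final irrigated fraction in the hot decile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("need at least 3 analysis years")

    @property
    def grid(self) -> Grid:
        return Grid.regular(self.resolution_deg, self.lat_start, self.lon_start, self.nlat, self.nlon)

    @property
    def center_lat(self) -> float:
        """Latitude of the initial crop-belt center.

        An expanding crop needs warmer land to spread into, so its belt sits
        in the poleward half of the domain; a migrating belt starts toward
        the equatorward side so it has room to move poleward.
        """
        if self.area_center_lat is not None:
            return self.area_center_lat
        return 41.0 if self.scenario == "expansion" else 38.5

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


@dataclass
class ScenarioTruth:
    """Generator-side ground truth for verifying the analysis."""

    expected_label: str
    true_counterfactual_slope: float  # degC/yr the frozen-area model should see
    centroid_displacement_deg: float  # latitudinal rainfed-centroid shift, degrees


def _deterministic_monthly(spec: ScenarioSpec, years: np.ndarray) -> np.ndarray:
    """Noise-free monthly temperature (year, month, lat, lon)."""
    grid = spec.grid
    lat = grid.lat_centers
    months = np.arange(1, 13)
    hemis = np.where(lat >= 0, 1.0, -1.0)
    seasonal = spec.seasonal_amplitude * np.cos(2.0 * np.pi * (months - 7) / 12.0)
    t = (
        spec.base_temp
        - spec.lat_gradient * np.abs(lat)[None, None, :, None]
        + seasonal[None, :, None, None] * hemis[None, None, :, None]
        + spec.warming_rate * (years - spec.year_start)[:, None, None, None]
    )
    return np.broadcast_to(t, (years.size, 12, spec.nlat, spec.nlon)).copy()


def make_climate(spec: ScenarioSpec, include_spinup: bool = True) -> GriddedField:
    """Monthly temperature series, seeded and reproducible.

    With ``include_spinup`` the series starts one year before the first
    analysis year so winter (year-wrapping) seasons are computable.
    """
    first = spec.year_start - 1 if include_spinup else spec.year_start
    years = np.arange(first, spec.year_end + 1)
    t = _deterministic_monthly(spec, years)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=t.shape)
        if spec.spatial_smoothing > 0:
            from scipy.ndimage import gaussian_filter

            noise = gaussian_filter(noise, sigma=(0, 0, spec.spatial_smoothing, spec.spatial_smoothing))
        t = t + noise
    grid = spec.grid
    da = xr.DataArray(
        t,
        coords={
            "year": years,
            "month": np.arange(1, 13),
            "lat": grid.lat_centers,
            "lon": grid.lon_centers,
        },
        dims=("year", "month", "lat", "lon"),
        attrs={"units": "degC"},
    )
    return GriddedField(da, units="degC", name="tmp")


def _climatology_mean_temp(spec: ScenarioSpec) -> np.ndarray:
    """Deterministic annual-mean temperature map at the first analysis year."""
    lat = spec.grid.lat_centers
    t = spec.base_temp - spec.lat_gradient * np.abs(lat)
    return np.broadcast_to(t[:, None], (spec.nlat, spec.nlon)).copy()


def _gaussian_area(spec: ScenarioSpec, center_lat: float) -> np.ndarray:
    lat = spec.grid.lat_centers
    a = spec.area_peak * np.exp(-((lat - center_lat) ** 2) / (2.0 * spec.area_sigma_deg**2))
    return np.broadcast_to(a[:, None], (spec.nlat, spec.nlon)).copy()


def _area_weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values.ravel(), kind="stable")
    v = values.ravel()[order]
    w = weights.ravel()[order]
    cw = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cw, q - 1e-12)])


def make_area_scenario(spec: ScenarioSpec) -> tuple[AreaPanel, ScenarioTruth]:
    """Annual total/irrigated/rainfed area panel plus its ground truth."""
    years = np.arange(spec.year_start, spec.year_end + 1)
    ny = years.size
    tclim = _climatology_mean_temp(spec)
    total = np.empty((ny, spec.nlat, spec.nlon))
    irr = np.zeros_like(total)

    if spec.scenario == "static":
        total[:] = _gaussian_area(spec, spec.center_lat)
        label = "no_evidence"
    elif spec.scenario == "migration":
        for i, y in enumerate(years):
            c = spec.center_lat + spec.migration_velocity * (y - spec.year_start)
            total[i] = _gaussian_area(spec, c)
        label = "adaptive_migration"
    elif spec.scenario == "expansion":
        a = _gaussian_area(spec, spec.center_lat)
        for i in range(ny):
            total[i] = a
            warm_bound = _area_weighted_quantile(tclim, a, 0.95)
            # >= so growth continues once the bound saturates at the hottest land
            hot = tclim >= warm_bound
            if hot.any():
                a = a.copy()
                a[hot] += spec.expansion_rate * a.sum() / hot.sum()
        label = "niche_expansion"
    elif spec.scenario == "irrigation_expansion":
        a = _gaussian_area(spec, spec.center_lat)
        total[:] = a
        cultivated = a > 0.01 * spec.area_peak
        decile = _area_weighted_quantile(tclim[cultivated], a[cultivated], 0.90)
        hot = cultivated & (tclim > decile)
        ramp = spec.irrigation_max * (years - spec.year_start) / max(ny - 1, 1)
        irr[:, hot] = ramp[:, None]
        label = "adaptive_migration"
    else:  # pragma: no cover
        raise ValueError(spec.scenario)

    grid = spec.grid
    coords = {"year": years, "lat": grid.lat_centers, "lon": grid.lon_centers}
    total_da = xr.DataArray(total, coords=coords, dims=("year", "lat", "lon"), attrs={"units": "ha"})
    irr_da = xr.DataArray(irr, coords=coords, dims=("year", "lat", "lon"), attrs={"units": "1"})
    rain = (total_da * (1.0 - irr_da)).assign_attrs({"units": "ha"})
    panel = AreaPanel(
        crop=spec.scenario, total_area=total_da, irrigated_fraction=irr_da, rainfed_area=rain
    )

    # latitudinal displacement of the constructed surface over the full period
    if spec.scenario == "migration":
        disp = spec.migration_velocity * (ny - 1)
    elif spec.scenario == "static":
        disp = 0.0
    else:
        lat = grid.lat_centers
        rainv = rain.values

        def _lat_centroid(block: np.ndarray) -> float:
            w = block.sum(axis=(0, 2))
            return float(np.sum(lat * w) / w.sum())

        disp = _lat_centroid(rainv[-1:]) - _lat_centroid(rainv[:1])
    truth = ScenarioTruth(
        expected_label=label,
        true_counterfactual_slope=spec.warming_rate,
        centroid_displacement_deg=disp,
    )
    return panel, truth


def make_calendar(spec: ScenarioSpec, wrap: bool = False, two_season: bool = False) -> CropCalendar:
    """Spatially constant crop calendar.

    Non-wrapping: plant day 120, harvest day 270 (a summer crop). Wrapping:
    plant 335, harvest 60 of the next year (a winter-crop analogue). With
    ``two_season`` every cell carries both seasons.
    """
    grid = spec.grid
    shape = (spec.nlat, spec.nlon)
    seasons = []
    if two_season:
        seasons = [(120.0, 270.0), (335.0, 60.0)]
    elif wrap:
        seasons = [(335.0, 60.0)]
    else:
        seasons = [(120.0, 270.0)]
    plant = np.stack([np.full(shape, p) for p, _ in seasons])
    harvest = np.stack([np.full(shape, h) for _, h in seasons])
    coords = {
        "season": np.arange(len(seasons)),
        "lat": grid.lat_centers,
        "lon": grid.lon_centers,
    }
    dims = ("season", "lat", "lon")
    return CropCalendar(
        crop=spec.scenario,
        plant_doy=xr.DataArray(plant, coords=coords, dims=dims),
        harvest_doy=xr.DataArray(harvest, coords=coords, dims=dims),
    )


def make_yields(
    temps: GriddedField | xr.DataArray,
    optimum: float = 15.0,
    breadth: float = 4.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    y_max: float = 8.0,
) -> GriddedField:
    """Gaussian temperature-response yield surface (tonnes/ha), seeded.

    yield = y_max * exp(-(T - optimum)^2 / (2 breadth^2)) + Normal(0, noise_sd),
    clipped at zero. Yields therefore fall off in both temperature tails.
    """
    da = temps.data if isinstance(temps, GriddedField) else temps
    y = y_max * np.exp(-((da.values - optimum) ** 2) / (2.0 * breadth**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.clip(y, 0.0, None)
    out = xr.DataArray(y, coords=da.coords, dims=da.dims, attrs={"units": "t/ha"})
    return GriddedField(out, units="t/ha", name="yield")
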