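"""Growing-season mean temperatures from monthly gridded climate.

Monthly means are interpolated to daily values on a fixed 365-day calendar
(leap days ignored): each monthly value is anchored at its month's midpoint
day, daily values vary linearly between consecutive anchors, and days before
the first / after the last available anchor hold the nearest anchor value.
The growing-season mean is then the arithmetic mean of daily temperatures
from the planting day through the harvest day inclusive. A season whose
planting day falls after its harvest day wraps the calendar year; such a
season is labeled by its *harvest* year and never uses data after the
harvest day of that year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .grids import GriddedField

__all__ = [
    "CropCalendar",
    "SeasonTempPanel",
    "monthly_to_daily",
    "season_mean",
    "crop_season_panel",
    "interpolate_daily_series",
]

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: Day-of-year (1-based, continuous) of each month's midpoint on a 365-day year.
MONTH_MIDPOINTS = np.concatenate(([0], np.cumsum(MONTH_LENGTHS)))[:-1] + MONTH_LENGTHS / 2.0
DAYS_PER_YEAR = 365


@dataclass
class CropCalendar:
    """Per-cell planting/harvest days for the 1-2 growing seasons of one crop.

    ``plant_doy`` and ``harvest_doy`` are (season, lat, lon) arrays in
    [1, 365]; NaN marks a season absent from a cell. Calendars are constant
    in time.
    """

    crop: str
    plant_doy: xr.DataArray
    harvest_doy: xr.DataArray

    def __post_init__(self) -> None:
        if self.plant_doy.shape != self.harvest_doy.shape:
            raise ValueError("plant/harvest shapes differ")
        for da in (self.plant_doy, self.harvest_doy):
            v = da.values[np.isfinite(da.values)]
            if v.size and (v.min() < 1 or v.max() > 365):
                raise ValueError("day-of-year outside [1, 365]")

    @property
    def n_seasons(self) -> int:
        return self.plant_doy.sizes["season"]

    def wraps(self) -> np.ndarray:
        """Boolean (season, lat, lon): True where the season crosses New Year."""
        return (self.plant_doy > self.harvest_doy).values


@dataclass
class SeasonTempPanel:
    """Per-cell annual growing-season mean temperature (degC) for one crop."""

    crop: str
    data: xr.DataArray  # dims (year, lat, lon); NaN = masked

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].values


def _anchor_days(n_years: int) -> np.ndarray:
    """Global continuous day coordinate of every monthly anchor in the series."""
    years = np.arange(n_years)[:, None] * DAYS_PER_YEAR
    return (years + MONTH_MIDPOINTS[None, :]).ravel()


def interpolate_daily_series(monthly: np.ndarray) -> np.ndarray:
    """Linearly interpolate a (n_years, 12, ...) monthly series to daily values.

    Returns (n_years * 365, ...). Daily value d (1-based within the series) is
    interpolated between the bracketing monthly anchors; outside the anchored
    range it holds the nearest anchor. NaN months poison the days whose
    interpolation touches them.
    """
    monthly = np.asarray(monthly, dtype=float)
    n_years = monthly.shape[0]
    anchors = _anchor_days(n_years)
    flat = monthly.reshape(n_years * 12, *monthly.shape[2:])
    days = np.arange(1, n_years * DAYS_PER_YEAR + 1, dtype=float)
    # bracketing anchor index for each day (same for every cell)
    hi = np.searchsorted(anchors, days)
    hi = np.clip(hi, 1, len(anchors) - 1)
    lo = hi - 1
    frac = (days - anchors[lo]) / (anchors[hi] - anchors[lo])
    frac = np.clip(frac, 0.0, 1.0)  # boundary hold outside the anchored range
    shape_tail = (1,) * (flat.ndim - 1)
    frac = frac.reshape(-1, *shape_tail)
    return (1.0 - frac) * flat[lo] + frac * flat[hi]


def monthly_to_daily(monthly: np.ndarray, year_index: int) -> np.ndarray:
    """Daily temperatures (365, ...) for one year of a (n_years, 12, ...) series.

    The whole series is interpolated so that December/January neighbors are
    available; at the series ends the nearest anchor value is held constant.
    """
    daily = interpolate_daily_series(monthly)
    start = year_index * DAYS_PER_YEAR
    return daily[start : start + DAYS_PER_YEAR]


def season_mean(daily: np.ndarray, plant_doy: int, harvest_doy: int) -> float:
    """Mean temperature from planting through harvest day inclusive.

    ``daily`` holds 730 values: the prior calendar year followed by the
    labeled (harvest) year. A wrapping season (plant > harvest) uses days
    plant..365 of the prior year plus days 1..harvest of the labeled year;
    otherwise only the labeled year is used. Any missing day masks the result.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.shape[0] != 2 * DAYS_PER_YEAR:
        raise ValueError("daily series must span two consecutive calendar years (730 days)")
    p, h = int(plant_doy), int(harvest_doy)
    if not (1 <= p <= 365 and 1 <= h <= 365):
        raise ValueError("day-of-year outside [1, 365]")
    if p <= h:
        span = daily[DAYS_PER_YEAR + p - 1 : DAYS_PER_YEAR + h]
    else:
        span = np.concatenate([daily[p - 1 : DAYS_PER_YEAR], daily[DAYS_PER_YEAR : DAYS_PER_YEAR + h]])
    if np.any(~np.isfinite(span)):
        return float("nan")
    return float(span.mean())


def crop_season_panel(
    monthly_temps: GriddedField, calendar: CropCalendar, years: range
) -> SeasonTempPanel:
    """Growing-season mean temperature per cell-year, averaged over seasons.

    ``monthly_temps`` must cover every labeled year, plus the preceding year
    whenever the calendar contains wrapping seasons. Cells with two seasons
    get the unweighted mean of the per-season means; cells with no valid
    season are masked.
    """
    da = monthly_temps.data
    temp_years = da["year"].values
    labeled = np.array(list(years))
    need_prior = bool(np.any(calendar.wraps() & np.isfinite(calendar.plant_doy.values)))
    first_needed = labeled[0] - 1 if need_prior else labeled[0]
    if temp_years[0] > first_needed or temp_years[-1] < labeled[-1]:
        raise ValueError(
            f"temperature series {temp_years[0]}-{temp_years[-1]} does not cover "
            f"required years {first_needed}-{labeled[-1]}"
        )

    nlat, nlon = da.sizes["lat"], da.sizes["lon"]
    monthly = da.transpose("year", "month", "lat", "lon").values.reshape(
        len(temp_years), 12, nlat * nlon
    )
    daily = interpolate_daily_series(monthly)  # (n_days, ncell)

    # prefix sums for O(1) inclusive range means, with NaN accounting
    bad = ~np.isfinite(daily)
    filled = np.where(bad, 0.0, daily)
    cs = np.concatenate([np.zeros((1, filled.shape[1])), np.cumsum(filled, axis=0)])
    cbad = np.concatenate([np.zeros((1, filled.shape[1]), dtype=int), np.cumsum(bad, axis=0)])

    def span_mean(i0: np.ndarray, i1: np.ndarray, cellsel: np.ndarray) -> np.ndarray:
        """Mean of daily[i0..i1] (0-based inclusive) per selected cell."""
        length = (i1 - i0 + 1).astype(float)
        s = cs[i1 + 1, cellsel] - cs[i0, cellsel]
        nbad = cbad[i1 + 1, cellsel] - cbad[i0, cellsel]
        out = s / length
        out[nbad > 0] = np.nan
        return out

    cells = np.arange(nlat * nlon)
    year_offset = {y: int(y - temp_years[0]) * DAYS_PER_YEAR for y in labeled}

    acc = np.zeros((len(labeled), nlat * nlon))
    cnt = np.zeros((len(labeled), nlat * nlon), dtype=int)
    plant = calendar.plant_doy.values.reshape(calendar.n_seasons, -1)
    harvest = calendar.harvest_doy.values.reshape(calendar.n_seasons, -1)
    for s in range(calendar.n_seasons):
        valid = np.isfinite(plant[s]) & np.isfinite(harvest[s])
        if not valid.any():
            continue
        p = plant[s, valid].astype(int)
        h = harvest[s, valid].astype(int)
        sel = cells[valid]
        wrap = p > h
        for iy, y in enumerate(labeled):
            off = year_offset[y]
            i0 = np.where(wrap, off - DAYS_PER_YEAR + p - 1, off + p - 1)
            i1 = off + h - 1
            m = span_mean(i0, i1, sel)
            ok = np.isfinite(m)
            acc[iy, sel[ok]] += m[ok]
            cnt[iy, sel[ok]] += 1

    with np.errstate(invalid="ignore"):
        panel = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    out = xr.DataArray(
        panel.reshape(len(labeled), nlat, nlon),
        coords={"year": labeled, "lat": da["lat"].values, "lon": da["lon"].values},
        dims=("year", "lat", "lon"),
        attrs={"units": "degC"},
    )
    return SeasonTempPanel(crop=calendar.crop, data=out)
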