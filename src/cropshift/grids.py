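"""Regular lat/lon raster model and NetCDF I/O shared by every pipeline stage.

Conventions
-----------
* Latitude ascends from south, longitude ascends from -180; a grid cell is the
  half-open box centered on its (lat, lon) center.
* Missing cells are carried as NaN in memory and as a per-variable fill value
  (-9999) on disk; masks round-trip exactly.
* Files use the NetCDF classic model (written/read through the scipy backend)
  with dimensions drawn from (year, month, lat, lon) and a ``units`` attribute
  on every variable (``degC``, ``ha``, ``1``, ``day_of_year``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = [
    "Grid",
    "GriddedField",
    "read_gridded_series",
    "write_gridded_series",
    "upscale",
    "mask_top_area_fraction",
]

#: Fill value written to disk for masked cells, all variables.
FILL_VALUE = -9999.0

#: Canonical dimension order for all fields.
DIM_ORDER = ("year", "month", "lat", "lon")

_LAT_ALIASES = ("lat", "latitude")
_LON_ALIASES = ("lon", "longitude")


def _check_regular(centers: np.ndarray, what: str) -> float:
    """Return the common spacing of ``centers`` or raise for irregular axes."""
    centers = np.asarray(centers, dtype=float)
    if centers.size < 1:
        raise ValueError(f"unsupported grid: empty {what} axis")
    if centers.size == 1:
        return np.nan
    steps = np.diff(centers)
    if np.any(steps <= 0):
        raise ValueError(f"unsupported grid: {what} centers must be strictly ascending")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"unsupported grid: irregular {what} spacing {steps}")
    return float(steps[0])


@dataclass(frozen=True)
class Grid:
    """A regular lat/lon grid defined by its cell centers.

    Parameters
    ----------
    resolution_deg:
        Edge length of a cell in degrees.
    lat_centers, lon_centers:
        Cell-center coordinates, strictly ascending, equally spaced by
        ``resolution_deg``.
    """

    resolution_deg: float
    lat_centers: np.ndarray = field(repr=False)
    lon_centers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        dlat = _check_regular(lat, "lat")
        dlon = _check_regular(lon, "lon")
        for d in (dlat, dlon):
            if np.isfinite(d) and not np.isclose(d, self.resolution_deg, rtol=1e-6):
                raise ValueError(
                    f"unsupported grid: spacing {d} != resolution {self.resolution_deg}"
                )
        half = self.resolution_deg / 2.0
        if np.any(np.abs(lat) > 90.0 - half + 1e-9):
            raise ValueError("unsupported grid: latitude centers exceed the polar cap")

    @classmethod
    def regular(
        cls, resolution_deg: float, lat_start: float, lon_start: float, nlat: int, nlon: int
    ) -> "Grid":
        """Build a grid from the southernmost/westernmost cell center."""
        return cls(
            resolution_deg,
            lat_start + resolution_deg * np.arange(nlat),
            lon_start + resolution_deg * np.arange(nlon),
        )

    @classmethod
    def from_coords(cls, lat: np.ndarray, lon: np.ndarray) -> "Grid":
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        dlat = _check_regular(lat, "lat")
        dlon = _check_regular(lon, "lon")
        res = next((d for d in (dlat, dlon) if np.isfinite(d)), 0.5)
        return cls(res, lat, lon)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)


@dataclass
class GriddedField:
    """One gridded variable with declared units and a NaN-encoded mask.

    ``data`` is an :class:`xarray.DataArray` whose dims are an ordered subset
    of ``(year, month, lat, lon)``; NaN marks masked cells.
    """

    data: xr.DataArray
    units: str
    name: str = "value"

    def __post_init__(self) -> None:
        extra = set(self.data.dims) - set(DIM_ORDER)
        if extra:
            raise ValueError(f"unsupported dims {sorted(extra)}")
        order = [d for d in DIM_ORDER if d in self.data.dims]
        self.data = self.data.transpose(*order).astype(float)
        self.data.attrs["units"] = self.units
        self.validate()

    @property
    def grid(self) -> Grid:
        return Grid.from_coords(self.data["lat"].values, self.data["lon"].values)

    @property
    def mask(self) -> xr.DataArray:
        """True where the cell is valid."""
        return self.data.notnull()

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    def validate(self) -> None:
        v = self.data.values
        finite = v[np.isfinite(v)]
        if self.units == "1" and finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("fraction field outside [0, 1]")
        if self.units == "ha" and finite.size and finite.min() < -1e-9:
            raise ValueError("area field must be non-negative")
        if self.units == "day_of_year" and finite.size and (
            finite.min() < 1 - 1e-9 or finite.max() > 365 + 1e-9
        ):
            raise ValueError("day-of-year field outside [1, 365]")


def _normalize_coords(da: xr.DataArray) -> xr.DataArray:
    ren = {}
    for alias in _LAT_ALIASES:
        if alias in da.dims and alias != "lat":
            ren[alias] = "lat"
    for alias in _LON_ALIASES:
        if alias in da.dims and alias != "lon":
            ren[alias] = "lon"
    if ren:
        da = da.rename(ren)
    for ax in ("lat", "lon"):
        if ax in da.dims and da[ax].size > 1 and da[ax].values[0] > da[ax].values[-1]:
            da = da.isel({ax: slice(None, None, -1)})
    return da


def read_gridded_series(path: str | os.PathLike, variable: str) -> GriddedField:
    """Read one variable from a classic-model NetCDF file.

    The file must carry regular ascending (or descending, then flipped)
    lat/lon axes; optional ``year`` and ``month`` dimensions are preserved.

    Raises
    ------
    KeyError
        If ``variable`` is not present ("variable not found").
    ValueError
        If the grid spacing is irregular ("unsupported grid").
    """
    with xr.open_dataset(path, engine="scipy", mask_and_scale=True) as ds:
        if variable not in ds:
            raise KeyError(
                f"variable not found: {variable!r}; file has {sorted(ds.data_vars)}"
            )
        da = _normalize_coords(ds[variable]).load()
    units = str(da.attrs.get("units", ""))
    Grid.from_coords(da["lat"].values, da["lon"].values)  # spacing check
    return GriddedField(da, units=units, name=variable)


def write_gridded_series(fieldobj: GriddedField, path: str | os.PathLike) -> None:
    """Write a field to classic-model NetCDF; masked cells become FILL_VALUE."""
    if fieldobj.data.size == 0:
        raise ValueError("empty field")
    ds = fieldobj.data.to_dataset(name=fieldobj.name)
    enc = {fieldobj.name: {"_FillValue": FILL_VALUE, "dtype": "f8"}}
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC", encoding=enc)


def _coarse_coords(centers: np.ndarray, factor: int) -> np.ndarray:
    return centers.reshape(-1, factor).mean(axis=1)


def upscale(
    fieldobj: GriddedField,
    factor: int,
    method: str,
    weights: GriddedField | xr.DataArray | None = None,
) -> GriddedField:
    """Coarsen a field by an integer factor in both spatial dimensions.

    ``method`` must match the variable: ``sum`` conserves totals (areas),
    ``mean`` for intensive variables, ``area_fraction_mean`` computes a
    weighted mean of fractions (weights = areas), and ``circular_doy_mean``
    averages day-of-year values on the 365-day circle with supplied weights,
    rounding to the nearest whole day in [1, 365].
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    da = fieldobj.data
    nlat, nlon = da.sizes["lat"], da.sizes["lon"]
    if nlat % factor or nlon % factor:
        raise ValueError(
            f"grid shape ({nlat}, {nlon}) not divisible by factor {factor}"
        )
    if method in ("area_fraction_mean", "circular_doy_mean") and weights is None:
        raise ValueError(f"method {method!r} requires a weight field")
    wda = weights.data if isinstance(weights, GriddedField) else weights

    coarse = {"lat": factor, "lon": factor}
    if method == "sum":
        out = da.coarsen(**coarse).sum(skipna=True, keep_attrs=True)
        out = out.where(da.notnull().coarsen(**coarse).sum() > 0)
    elif method == "mean":
        out = da.coarsen(**coarse).mean(skipna=True, keep_attrs=True)
    elif method == "area_fraction_mean":
        w = wda.where(da.notnull(), 0.0)
        num = (da * w).fillna(0.0).coarsen(**coarse).sum()
        den = w.coarsen(**coarse).sum()
        out = (num / den.where(den > 0)).assign_attrs(da.attrs)
    elif method == "circular_doy_mean":
        ang = 2.0 * np.pi * da / 365.0
        w = wda.where(da.notnull(), 0.0)
        x = (np.cos(ang) * w).fillna(0.0).coarsen(**coarse).sum()
        y = (np.sin(ang) * w).fillna(0.0).coarsen(**coarse).sum()
        den = w.coarsen(**coarse).sum()
        theta = np.arctan2(y, x)
        doy = np.round(theta * 365.0 / (2.0 * np.pi)) % 365
        doy = doy.where(doy != 0, 365.0)
        out = doy.where(den > 0).assign_attrs(da.attrs)
    else:
        raise ValueError(f"unknown upscale method {method!r}")

    out = out.assign_coords(
        lat=_coarse_coords(da["lat"].values, factor),
        lon=_coarse_coords(da["lon"].values, factor),
    )
    return GriddedField(out, units=fieldobj.units, name=fieldobj.name)


def mask_top_area_fraction(mean_area: GriddedField | xr.DataArray, fraction: float) -> xr.DataArray:
    """Select the smallest set of largest-area cells covering ``fraction`` of total area.

    Cells are ranked by mean area descending (ties broken by ascending lat
    index, then lon index) and the shortest prefix whose cumulative area
    reaches ``fraction`` x total is retained. Returns a boolean (lat, lon)
    mask. Cells with zero or masked area are never selected.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    da = mean_area.data if isinstance(mean_area, GriddedField) else mean_area
    area = np.nan_to_num(da.values, nan=0.0)
    if np.any(area < 0):
        raise ValueError("areas must be non-negative")
    total = area.sum()
    if total <= 0:
        raise ValueError("no cultivated cells")
    flat = area.ravel()
    ilat, ilon = np.unravel_index(np.arange(flat.size), area.shape)
    order = np.lexsort((ilon, ilat, -flat))
    csum = np.cumsum(flat[order])
    # smallest prefix with cumulative area >= fraction * total
    k = int(np.searchsorted(csum, fraction * total - 1e-12 * total) + 1)
    chosen = order[:k]
    chosen = chosen[flat[chosen] > 0]
    keep = np.zeros(flat.size, dtype=bool)
    keep[chosen] = True
    return xr.DataArray(
        keep.reshape(area.shape), coords={"lat": da["lat"], "lon": da["lon"]}, dims=("lat", "lon")
    )
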