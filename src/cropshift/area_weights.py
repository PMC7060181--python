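"""Rainfed harvested-area panels and regression weight sets.

The observed ("dynamic") weights are the per-cell, per-year rainfed harvested
areas: total harvested area times the rainfed fraction, where the rainfed
fraction is one minus the irrigated fraction. The counterfactual ("static")
weights freeze each cell at its mean rainfed area over a reference window
(1973-1977 by default), isolating the climate trend from area change.

Irrigated fractions through time are built by scaling a base-year (circa
2000) fraction by the ratio of area equipped for irrigation (AEI) in each
year to AEI in the base year; between AEI observations the ratio is linearly
interpolated, beyond the observed range it is linearly extrapolated from the
two nearest observations, and the resulting fraction is clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GriddedField

__all__ = [
    "AreaPanel",
    "WeightSet",
    "irrigated_fraction_series",
    "build_area_panel",
    "make_weights",
]

DEFAULT_STATIC_WINDOW = (1973, 1977)
AEI_BASE_YEAR = 2000


@dataclass
class AreaPanel:
    """Per-cell annual harvested areas for one crop (hectares).

    ``rainfed_area = total_area * (1 - irrigated_fraction)`` holds by
    construction; all three arrays share dims (year, lat, lon).
    """

    crop: str
    total_area: xr.DataArray
    irrigated_fraction: xr.DataArray
    rainfed_area: xr.DataArray

    @property
    def years(self) -> np.ndarray:
        return self.total_area["year"].values


@dataclass
class WeightSet:
    """Regression weights: hectares per cell, per year if dynamic.

    Static weights carry dims (lat, lon) and apply unchanged to every
    analysis year; dynamic weights carry (year, lat, lon).
    """

    mode: str  # "dynamic" | "static"
    weights: xr.DataArray
    reference_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("dynamic", "static"):
            raise ValueError(f"unknown weight mode {self.mode!r}")
        finite = self.weights.values[np.isfinite(self.weights.values)]
        if finite.size and finite.min() < -1e-9:
            raise ValueError("weights must be non-negative")
        if not finite.size or not (finite > 0).any():
            raise ValueError("weight set has no positive weight")

    def for_years(self, years: np.ndarray) -> xr.DataArray:
        """Weights broadcast to (year, lat, lon) over ``years``."""
        if self.mode == "dynamic":
            return self.weights.sel(year=years)
        return self.weights.expand_dims(year=years)


def irrigated_fraction_series(
    base_fraction: float | np.ndarray | xr.DataArray,
    aei_ratio: pd.Series,
    years: range,
    base_year: int = AEI_BASE_YEAR,
) -> xr.DataArray:
    """Scale a base-year irrigated fraction through time by AEI ratios.

    fraction(y) = clamp(base_fraction * ratio(y) / ratio(base_year), 0, 1),
    where ratio(y) linearly interpolates between observed years and linearly
    extrapolates from the two nearest observations outside the observed span.

    ``aei_ratio`` is a Series indexed by observation year. Returns a
    DataArray with a leading ``year`` dim (plus the dims of base_fraction).
    """
    obs = aei_ratio.dropna().sort_index()
    if len(obs) < 2:
        raise ValueError("need at least two observed AEI ratio years")
    oy = obs.index.to_numpy(dtype=float)
    ov = obs.to_numpy(dtype=float)

    def ratio_at(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        r = np.interp(y, oy, ov)
        lo_slope = (ov[1] - ov[0]) / (oy[1] - oy[0])
        hi_slope = (ov[-1] - ov[-2]) / (oy[-1] - oy[-2])
        r = np.where(y < oy[0], ov[0] + lo_slope * (y - oy[0]), r)
        r = np.where(y > oy[-1], ov[-1] + hi_slope * (y - oy[-1]), r)
        return r

    r0 = float(ratio_at(np.array([base_year]))[0])
    base = base_fraction.values if isinstance(base_fraction, xr.DataArray) else np.asarray(base_fraction, dtype=float)
    if r0 == 0.0:
        if np.any(base > 0):
            raise ValueError("undefined scaling: base-year AEI ratio is zero")
        r0 = 1.0
    yrs = np.array(list(years))
    scale = ratio_at(yrs) / r0
    frac = np.clip(base[None, ...] * scale.reshape((-1,) + (1,) * base.ndim), 0.0, 1.0)
    coords = {"year": yrs}
    dims = ("year",)
    if isinstance(base_fraction, xr.DataArray):
        coords.update({d: base_fraction[d] for d in base_fraction.dims})
        dims = ("year", *base_fraction.dims)
    return xr.DataArray(frac, coords=coords, dims=dims, attrs={"units": "1"})


def build_area_panel(
    total_area: GriddedField,
    irrigated_fraction: GriddedField | xr.DataArray,
    crop: str = "crop",
) -> AreaPanel:
    """Combine total areas and irrigated fractions into an :class:`AreaPanel`."""
    tot = total_area.data
    frac = irrigated_fraction.data if isinstance(irrigated_fraction, GriddedField) else irrigated_fraction
    if "year" not in frac.dims:
        frac = frac.expand_dims(year=tot["year"].values)
    frac = frac.broadcast_like(tot)
    fv = frac.values
    finite = fv[np.isfinite(fv)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
        raise ValueError("irrigated fraction outside [0, 1]")
    rainfed = (tot * (1.0 - frac)).assign_attrs({"units": "ha"})
    return AreaPanel(crop=crop, total_area=tot, irrigated_fraction=frac, rainfed_area=rainfed)


def make_weights(
    panel: AreaPanel,
    mode: str,
    window: tuple[int, int] = DEFAULT_STATIC_WINDOW,
) -> WeightSet:
    """Dynamic (per-year) or static (reference-window mean) rainfed weights."""
    if mode == "dynamic":
        return WeightSet(mode="dynamic", weights=panel.rainfed_area)
    if mode == "static":
        years = panel.years
        if window[0] < years.min() or window[1] > years.max():
            raise ValueError(
                f"static window {window} outside panel years {years.min()}-{years.max()}"
            )
        win = panel.rainfed_area.sel(year=slice(window[0], window[1]))
        return WeightSet(
            mode="static", weights=win.mean("year", skipna=True), reference_window=window
        )
    raise ValueError(f"unknown weight mode {mode!r}")
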