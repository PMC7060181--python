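"""Per-cell trend maps, harvested-area centroid tracking, and yield extremes.

These diagnostics support the migration analysis: ordinary least-squares
trends of growing-season temperature (and of harvested area) per grid cell
with significance summaries expressed as area fractions; the harvested-area
weighted centroid of a region at the start and end of the record, with
great-circle displacement and bearing; and a comparison of yields between
the cold tail, middle, and hot tail of the area-weighted growing-season
temperature distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import stats

from .grids import GriddedField

__all__ = [
    "CellTrend",
    "CentroidTrack",
    "YieldExtremeComparison",
    "cell_trend",
    "cell_trend_map",
    "quadratic_term_test",
    "significant_area_fraction",
    "weighted_centroid",
    "centroid_shift",
    "weighted_quantile",
    "yield_extreme_comparison",
]

EARTH_RADIUS_KM = 6371.0
DEFAULT_START_WINDOW = (1973, 1977)
DEFAULT_END_WINDOW = (2008, 2012)


@dataclass
class CellTrend:
    slope: float
    p_value: float
    r_squared: float


@dataclass
class CentroidTrack:
    centroid_start: tuple[float, float]  # (lat, lon) degrees
    centroid_end: tuple[float, float]
    displacement_km: float
    bearing_deg: float  # clockwise from north, [0, 360)


@dataclass
class YieldExtremeComparison:
    mean_yield_cold: float
    mean_yield_mid: float
    mean_yield_hot: float
    pct_diff_hot: float
    pct_diff_cold: float
    p_hot: float
    p_cold: float
    threshold_cold: float
    threshold_hot: float


def cell_trend(values: np.ndarray, years: np.ndarray) -> CellTrend:
    """OLS trend of one series on year with a two-sided slope t-test."""
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 3:
        return CellTrend(float("nan"), float("nan"), float("nan"))
    res = stats.linregress(years[ok], values[ok])
    return CellTrend(float(res.slope), float(res.pvalue), float(res.rvalue**2))


def cell_trend_map(panel: xr.DataArray) -> xr.Dataset:
    """Vectorized per-cell OLS trends of a (year, lat, lon) panel.

    Returns a Dataset with ``slope``, ``p_value`` and ``r_squared`` maps;
    cells with fewer than 3 valid years are masked.
    """
    years = panel["year"].values.astype(float)
    v = panel.values.reshape(len(years), -1)
    ok = np.isfinite(v)
    n = ok.sum(axis=0).astype(float)
    t = np.where(ok, years[:, None], 0.0)
    y = np.where(ok, v, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = t.sum(axis=0) / n
        ybar = y.sum(axis=0) / n
        tc = np.where(ok, years[:, None] - tbar, 0.0)
        yc = np.where(ok, v - ybar, 0.0)
        stt = (tc**2).sum(axis=0)
        sty = (tc * yc).sum(axis=0)
        syy = (yc**2).sum(axis=0)
        slope = sty / stt
        sse = syy - slope * sty
        dof = n - 2
        sigma2 = sse / dof
        se = np.sqrt(sigma2 / stt)
        with np.errstate(invalid="ignore"):
            tstat = slope / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        r2 = np.where(syy > 0, sty**2 / (stt * syy), np.nan)
    bad = (n < 3) | (stt <= 0)
    slope[bad] = np.nan
    p[bad] = np.nan
    r2[bad] = np.nan
    # constant series: slope 0, no evidence
    const = (~bad) & (syy <= 1e-300)
    p[const] = 1.0
    r2[const] = 0.0
    shape = panel.shape[1:]
    coords = {"lat": panel["lat"], "lon": panel["lon"]}
    return xr.Dataset(
        {
            "slope": (("lat", "lon"), slope.reshape(shape)),
            "p_value": (("lat", "lon"), p.reshape(shape)),
            "r_squared": (("lat", "lon"), r2.reshape(shape)),
        },
        coords=coords,
    )


def quadratic_term_test(values: np.ndarray, years: np.ndarray) -> float:
    """Two-sided p-value of the quadratic coefficient in value ~ year + year^2.

    Years are centered before squaring to limit collinearity. Returns NaN for
    rank-deficient designs or fewer than 4 valid years.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 4:
        return float("nan")
    t = years[ok] - years[ok].mean()
    X = np.column_stack([np.ones(t.size), t, t**2])
    y = values[ok]
    if np.linalg.matrix_rank(X) < 3:
        return float("nan")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = t.size - 3
    if dof < 1:
        return float("nan")
    sse = float(resid @ resid)
    # exact polynomial fit (residuals at rounding level): the quadratic term is
    # either truly present or a pure float artifact of a perfectly linear series
    y_scale = max(1.0, float(np.abs(y).max()))
    if sse <= (1e-11 * y_scale) ** 2 * t.size:
        coef_scale = max(1.0, float(np.abs(coef[:2]).max()))
        return 0.0 if abs(coef[2]) > 1e-10 * coef_scale else 1.0
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[2, 2])
    tstat = coef[2] / se
    return float(2.0 * stats.t.sf(abs(tstat), dof))


def significant_area_fraction(
    trends: xr.Dataset,
    areas: xr.DataArray | GriddedField,
    p_threshold: float = 0.1,
    direction: str = "warming",
) -> float:
    """Percent of total area in cells with a significant trend of given sign."""
    if direction not in ("warming", "cooling"):
        raise ValueError("direction must be 'warming' or 'cooling'")
    a = areas.data if isinstance(areas, GriddedField) else areas
    area = np.nan_to_num(a.values, nan=0.0)
    slope = trends["slope"].values
    p = trends["p_value"].values
    valid = np.isfinite(slope) & np.isfinite(p)
    total = area[valid].sum()
    if total <= 0:
        raise ValueError("zero total area over valid cells")
    sign = slope > 0 if direction == "warming" else slope < 0
    hit = valid & (p < p_threshold) & sign
    return float(100.0 * area[hit].sum() / total)


def weighted_centroid(areas: xr.DataArray | GriddedField) -> tuple[float, float]:
    """Area-weighted mean of cell-center coordinates (lat, lon).

    Plain arithmetic means are used, matching a visual centroid on a regional
    map; regions spanning the antimeridian are not supported.
    """
    a = areas.data if isinstance(areas, GriddedField) else areas
    w = np.nan_to_num(a.values, nan=0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total area")
    lon = a["lon"].values
    if lon.size > 1 and (lon.max() - lon.min()) > 180.0:
        raise ValueError("region spans the antimeridian")
    latg, long_ = np.meshgrid(a["lat"].values, lon, indexing="ij")
    return (float((w * latg).sum() / total), float((w * long_).sum() / total))


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    p1, p2, dl = np.radians(lat1), np.radians(lat2), np.radians(lon2 - lon1)
    dphi = p2 - p1
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def _initial_bearing_deg(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    p1, p2, dl = np.radians(lat1), np.radians(lat2), np.radians(lon2 - lon1)
    x = np.sin(dl) * np.cos(p2)
    y = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    bearing = float(np.degrees(np.arctan2(x, y)) % 360.0)
    return 0.0 if bearing >= 360.0 else bearing  # float mod can return 360.0


def centroid_shift(
    panel,
    window_start: tuple[int, int] = DEFAULT_START_WINDOW,
    window_end: tuple[int, int] = DEFAULT_END_WINDOW,
) -> CentroidTrack:
    """Centroid movement of window-mean rainfed areas between two eras."""
    rain = panel.rainfed_area
    start = rain.sel(year=slice(*window_start)).mean("year", skipna=True)
    end = rain.sel(year=slice(*window_end)).mean("year", skipna=True)
    c0 = weighted_centroid(start)
    c1 = weighted_centroid(end)
    return CentroidTrack(
        centroid_start=c0,
        centroid_end=c1,
        displacement_km=_haversine_km(*c0, *c1),
        bearing_deg=_initial_bearing_deg(*c0, *c1),
    )


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Smallest value at which the cumulative sorted weight fraction reaches q."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = np.isfinite(values) & (weights > 0)
    if not ok.any():
        raise ValueError("no valid weighted values")
    v, w = values[ok], weights[ok]
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cw, q - 1e-12)])


def _weighted_mean(y: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(y * w) / np.sum(w))


def _bootstrap_se(y: np.ndarray, w: np.ndarray, n_boot: int, rng) -> float:
    n = y.size
    means = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        means[b] = _weighted_mean(y[idx], w[idx])
    return float(means.std(ddof=1))


def yield_extreme_comparison(
    yields: GriddedField | xr.DataArray,
    temps: GriddedField | xr.DataArray,
    areas: GriddedField | xr.DataArray,
    p_lo: float = 0.05,
    p_hi: float = 0.95,
    n_boot: int = 500,
    seed: int | None = None,
) -> YieldExtremeComparison:
    """Compare area-weighted mean yields across temperature-extreme bins.

    Bin thresholds are area-weighted quantiles of mean growing-season
    temperature at ``p_lo`` and ``p_hi``; the three bins (cold tail, middle,
    hot tail) partition all positive-area cells. P-values come from a
    two-sample weighted-means t-statistic with bootstrap standard errors
    (cells resampled within bins; normal reference distribution).
    """
    yv = (yields.data if isinstance(yields, GriddedField) else yields).values.ravel()
    tv = (temps.data if isinstance(temps, GriddedField) else temps).values.ravel()
    av = (areas.data if isinstance(areas, GriddedField) else areas).values.ravel()
    av = np.nan_to_num(av, nan=0.0)
    ok = (av > 0) & np.isfinite(yv) & np.isfinite(tv)
    if not ok.any():
        raise ValueError("no valid cells with positive area")
    y, t, a = yv[ok], tv[ok], av[ok]
    lo = weighted_quantile(t, a, p_lo)
    hi = weighted_quantile(t, a, p_hi)
    cold = t <= lo
    hot = t > hi
    mid = ~cold & ~hot
    rng = np.random.default_rng(seed)

    def bin_stats(m: np.ndarray) -> tuple[float, float]:
        if not m.any():
            return float("nan"), float("nan")
        return _weighted_mean(y[m], a[m]), _bootstrap_se(y[m], a[m], n_boot, rng)

    mean_cold, se_cold = bin_stats(cold)
    mean_mid, se_mid = bin_stats(mid)
    mean_hot, se_hot = bin_stats(hot)

    def pval(m1: float, s1: float, m2: float, s2: float) -> float:
        if not np.isfinite(m1) or not np.isfinite(m2):
            return float("nan")
        se = np.hypot(s1, s2)
        if se == 0:
            return 1.0 if m1 == m2 else 0.0
        return float(2.0 * stats.norm.sf(abs(m1 - m2) / se))

    return YieldExtremeComparison(
        mean_yield_cold=mean_cold,
        mean_yield_mid=mean_mid,
        mean_yield_hot=mean_hot,
        pct_diff_hot=float(100.0 * (mean_hot - mean_mid) / mean_mid),
        pct_diff_cold=float(100.0 * (mean_cold - mean_mid) / mean_mid),
        p_hot=pval(mean_hot, se_hot, mean_mid, se_mid),
        p_cold=pval(mean_cold, se_cold, mean_mid, se_mid),
        threshold_cold=lo,
        threshold_hot=hi,
    )
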