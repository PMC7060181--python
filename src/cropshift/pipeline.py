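"""Orchestration: config validation, full analysis runs, and result bundles.

A run is described by an :class:`AnalysisConfig` (usually loaded from YAML).
In synthetic mode each "crop" is one of the built-in scenarios and all inputs
are generated with seeds derived from the master seed; in file mode the
gridded inputs are read from NetCDF paths. Every stage is logged, and one
result bundle is written per run: ``results.csv`` (per crop x tau fits,
slope-difference test, classification), per-crop trend maps (NetCDF),
``centroids.csv``, optional ``yield_comparison.csv``, and ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import adaptation, diagnostics, synthetic
from .area_weights import build_area_panel, make_weights
from .grids import GriddedField, mask_top_area_fraction, read_gridded_series
from .quantile_trend import fit_pair, period_change
from .season_temp import CropCalendar, crop_season_panel

__all__ = ["AnalysisConfig", "CropInputs", "validate_config", "run_analysis"]

logger = logging.getLogger("cropshift")

DEFAULT_TAUS = (0.05, 0.9, 0.93, 0.95, 0.97)


class CropInputs(BaseModel):
    """NetCDF paths for one crop in file mode."""

    model_config = ConfigDict(extra="forbid")

    temperature: str
    temperature_var: str = "tmp"
    calendar: str
    total_area: str
    total_area_var: str = "harvested_area"
    irrigated_fraction: Optional[str] = None
    irrigated_fraction_var: str = "irrigated_fraction"


class AnalysisConfig(BaseModel):
    """Validated configuration of a full analysis run."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["synthetic", "files"] = "synthetic"
    crops: list[str] = Field(default_factory=lambda: list(synthetic.SCENARIOS))
    inputs: dict[str, CropInputs] = Field(default_factory=dict)
    scenario_overrides: dict = Field(default_factory=dict)
    taus: list[float] = Field(default_factory=lambda: list(DEFAULT_TAUS))
    primary_tau: float = 0.95
    years: tuple[int, int] = (1973, 2012)
    static_window: tuple[int, int] = (1973, 1977)
    n_boot: int = 500
    alpha: float = 0.05
    seed: int = 0
    mask_fraction: float = 0.98
    mask_quantile_sample: bool = False
    wrap_calendar: bool = False
    yield_comparison: bool = False
    output_dir: str = "results"

    @field_validator("taus")
    @classmethod
    def _taus_in_unit_interval(cls, v: list[float]) -> list[float]:
        for tau in v:
            if not 0.0 < tau < 1.0:
                raise ValueError(f"taus: {tau} outside (0, 1)")
        return v

    @field_validator("crops")
    @classmethod
    def _crops_unique(cls, v: list[str]) -> list[str]:
        if len(set(v)) != len(v):
            raise ValueError("crops: duplicate names")
        if not v:
            raise ValueError("crops: empty list")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "AnalysisConfig":
        y0, y1 = self.years
        w0, w1 = self.static_window
        if y1 <= y0:
            raise ValueError("years: end must exceed start")
        if not (y0 <= w0 <= w1 <= y1):
            raise ValueError("static_window: must lie inside years")
        if self.n_boot < 1:
            raise ValueError("n_boot: must be >= 1")
        if not 0 < self.mask_fraction <= 1:
            raise ValueError("mask_fraction: outside (0, 1]")
        if self.mode == "files":
            missing = [c for c in self.crops if c not in self.inputs]
            if missing:
                raise ValueError(f"inputs: missing paths for crops {missing}")
        else:
            for c in self.crops:
                if c not in synthetic.SCENARIOS:
                    raise ValueError(
                        f"crops: {c!r} is not a synthetic scenario {synthetic.SCENARIOS}"
                    )
        return self


def bundled_suite_config(
    seed: int,
    output_dir: str = "results",
    n_boot: int = 200,
    taus: tuple[float, ...] = (0.05, 0.95),
) -> AnalysisConfig:
    """The packaged four-scenario verification suite at desk scale."""
    return AnalysisConfig(
        crops=list(synthetic.SCENARIOS),
        taus=list(taus),
        n_boot=n_boot,
        seed=seed,
        output_dir=output_dir,
        yield_comparison=True,
    )


def validate_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML config, filling defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**raw)


def _load_crop_files(inp: CropInputs, crop: str):
    temps = read_gridded_series(inp.temperature, inp.temperature_var)
    total = read_gridded_series(inp.total_area, inp.total_area_var)
    if inp.irrigated_fraction is not None:
        irr = read_gridded_series(inp.irrigated_fraction, inp.irrigated_fraction_var)
        frac = irr.data
    else:
        frac = xr.zeros_like(total.data).assign_attrs({"units": "1"})
    panel = build_area_panel(total, frac, crop=crop)
    with xr.open_dataset(inp.calendar, engine="scipy") as ds:
        plant = [v for v in ds.data_vars if v.startswith("plant_doy")]
        harvest = [v for v in ds.data_vars if v.startswith("harvest_doy")]
        cal = CropCalendar(
            crop=crop,
            plant_doy=xr.concat([ds[v].load() for v in sorted(plant)], dim="season"),
            harvest_doy=xr.concat([ds[v].load() for v in sorted(harvest)], dim="season"),
        )
    return temps, panel, cal, None


def _prepare_crop(cfg: AnalysisConfig, crop: str):
    """Climate, area panel, calendar (and truth in synthetic mode) for one crop."""
    if cfg.mode == "files":
        return _load_crop_files(cfg.inputs[crop], crop)
    spec = synthetic.ScenarioSpec(
        scenario=crop,
        year_start=cfg.years[0],
        year_end=cfg.years[1],
        seed=adaptation.derive_seed(cfg.seed, crop, 0.0),
        **cfg.scenario_overrides,
    )
    temps = synthetic.make_climate(spec)
    panel, truth = synthetic.make_area_scenario(spec)
    cal = synthetic.make_calendar(spec, wrap=cfg.wrap_calendar)
    return temps, panel, cal, truth


def run_analysis(config: AnalysisConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full analysis and write the result bundle.

    Returns a dict with the results DataFrame, centroid table, manifest, and
    per-crop diagnostics. Identical config and seed give identical outputs.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    years = range(config.years[0], config.years[1] + 1)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "stages": [],
    }

    def stage(name: str, **info) -> None:
        logger.info("%s %s", name, info)
        manifest["stages"].append({"stage": name, **info})

    rows = []
    centroid_rows = []
    yield_rows = []
    diag_rows = []
    for crop in config.crops:
        temps, panel, cal, truth = _prepare_crop(config, crop)
        stage("inputs", crop=crop, n_years=len(list(years)), cells=int(np.prod(panel.total_area.shape[1:])))

        season = crop_season_panel(temps, cal, years)
        dynamic = make_weights(panel, "dynamic")
        static = make_weights(panel, "static", window=config.static_window)
        stage(
            "season_panel",
            crop=crop,
            valid_cells=int(np.isfinite(season.data.values).any(axis=0).sum()),
        )

        mean_rain = panel.rainfed_area.mean("year", skipna=True)
        topmask = mask_top_area_fraction(mean_rain, config.mask_fraction)
        if config.mask_quantile_sample:
            season_fit = season.__class__(
                crop=season.crop, data=season.data.where(topmask)
            )
        else:
            season_fit = season

        for tau in config.taus:
            observed, counterfactual = fit_pair(season_fit, dynamic, static, tau)
            boot_seed = adaptation.derive_seed(config.seed, f"{crop}|boot", tau)
            samples = adaptation.bootstrap_theta(
                season_fit, dynamic, static, tau, n_boot=config.n_boot, seed=boot_seed
            )
            result = adaptation.classify(
                samples,
                alpha=config.alpha,
                theta_hat=adaptation.theta(observed.slope, counterfactual.slope),
                seed=boot_seed,
            )
            rows.append(
                {
                    "crop": crop,
                    "tau": tau,
                    "beta_observed": observed.slope,
                    "beta_counterfactual": counterfactual.slope,
                    "intercept_observed": observed.intercept,
                    "intercept_counterfactual": counterfactual.intercept,
                    "change_observed": period_change(observed, *config.years),
                    "change_counterfactual": period_change(counterfactual, *config.years),
                    "theta": result.theta,
                    "p_adapt": result.p_adapt,
                    "p_expand": result.p_expand,
                    "label": result.label,
                    "expected_label": truth.expected_label if truth else "",
                    "n_obs": observed.n_obs,
                    "n_boot": config.n_boot,
                    "seed": boot_seed,
                }
            )
            stage("adaptation_test", crop=crop, tau=tau, seed=boot_seed, label=result.label)

        # per-cell trend maps across the top-area mask
        temp_trends = diagnostics.cell_trend_map(season.data.where(topmask))
        area_trends = diagnostics.cell_trend_map(panel.rainfed_area.where(topmask))
        ds = xr.Dataset(
            {
                "temp_slope": temp_trends["slope"],
                "temp_p_value": temp_trends["p_value"],
                "area_slope": area_trends["slope"],
                "area_p_value": area_trends["p_value"],
            }
        )
        ds.to_netcdf(outdir / f"trends_{crop}.nc", engine="scipy", format="NETCDF3_CLASSIC")
        diag_rows.append(
            {
                "crop": crop,
                "warming_area_pct": diagnostics.significant_area_fraction(
                    temp_trends, mean_rain.where(topmask), direction="warming"
                ),
                "cooling_area_pct": diagnostics.significant_area_fraction(
                    temp_trends, mean_rain.where(topmask), direction="cooling"
                ),
            }
        )
        track = diagnostics.centroid_shift(
            panel,
            window_start=config.static_window,
            window_end=(config.years[1] - 4, config.years[1]),
        )
        centroid_rows.append(
            {
                "crop": crop,
                "lat_start": track.centroid_start[0],
                "lon_start": track.centroid_start[1],
                "lat_end": track.centroid_end[0],
                "lon_end": track.centroid_end[1],
                "displacement_km": track.displacement_km,
                "bearing_deg": track.bearing_deg,
                "expected_displacement_deg": truth.centroid_displacement_deg if truth else np.nan,
            }
        )
        stage("diagnostics", crop=crop, displacement_km=track.displacement_km)

        if config.yield_comparison:
            era_temp = season.data.sel(year=slice(*config.static_window)).mean(
                "year", skipna=True
            )
            yields = synthetic.make_yields(
                era_temp, seed=adaptation.derive_seed(config.seed, f"{crop}|yield", 0.0)
            )
            comp = diagnostics.yield_extreme_comparison(
                yields.data,
                era_temp,
                mean_rain,
                seed=adaptation.derive_seed(config.seed, f"{crop}|yieldboot", 0.0),
            )
            yield_rows.append({"crop": crop, **comp.__dict__})
            stage("yield_comparison", crop=crop, pct_diff_hot=comp.pct_diff_hot)

    results = pd.DataFrame(rows)
    results.to_csv(outdir / "results.csv", index=False)
    centroids = pd.DataFrame(centroid_rows)
    centroids.to_csv(outdir / "centroids.csv", index=False)
    diag = pd.DataFrame(diag_rows)
    diag.to_csv(outdir / "trend_summary.csv", index=False)
    if yield_rows:
        pd.DataFrame(yield_rows).to_csv(outdir / "yield_comparison.csv", index=False)

    manifest["config_hash"] = hashlib.sha256(
        config.model_dump_json().encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "results": results,
        "centroids": centroids,
        "trend_summary": diag,
        "yield_comparison": pd.DataFrame(yield_rows) if yield_rows else None,
        "manifest": manifest,
        "output_dir": str(outdir),
    }
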