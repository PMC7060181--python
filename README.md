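# cropshift

Detecting adaptive crop migration from gridded climate and harvested-area
data.

## The problem

Rainfed crops are sensitive to heat, and the geographic distribution of
cultivation is not fixed: growers abandon land that becomes too hot, plant
newly suitable land poleward, or irrigate. A warming trend computed over a
*fixed* map of cropland therefore overstates (or understates) what the crop
actually experienced. `cropshift` quantifies this by comparing trends in the
**warm bound** of a crop's growing-season temperature distribution under two
weighting schemes:

- **observed** — each grid cell-year enters a quantile regression of
  growing-season mean temperature on year, weighted by that year's rainfed
  harvested area (hectares);
- **counterfactual** — the same regression with every cell's weight frozen
  at its mean rainfed area over a reference window (1973–1977 by default),
  so only the climate varies.

With β₀ and β_c the two slopes at quantile level τ (τ = 0.95 for the warm
bound), the statistic is

    Θ = β₀ − β_c .

Θ significantly below zero means cultivation shifted toward cooler
conditions faster than the climate warmed — *adaptive migration*. Θ
significantly above zero means the crop spread into even hotter conditions —
*niche expansion*. Significance comes from a cluster bootstrap: grid cells
are resampled with replacement (each keeping its whole year series), both
models are refit on the same resample, and one-sided p-values are the
proportions of the bootstrap Θ distribution on either side of zero.

The package is aimed at researchers in agro-ecological climate analysis who
have gridded monthly temperatures (NetCDF), crop calendars (planting/harvest
day of year), annual harvested-area rasters, and irrigated-fraction data —
or who want to study the method itself on synthetic data with known truth.

## What is in the box

| module | role |
| --- | --- |
| `cropshift.grids` | regular lat/lon raster model, classic-NetCDF I/O, area-conserving upscaling, top-area masking |
| `cropshift.season_temp` | monthly→daily interpolation and crop-calendar growing-season mean temperatures (wrapping winter seasons supported) |
| `cropshift.area_weights` | rainfed area panels, AEI-scaled irrigated-fraction series, dynamic/static weight sets |
| `cropshift.quantile_trend` | exact weighted quantile regression of temperature on year (interior-point solve + vertex polish) |
| `cropshift.adaptation` | Θ, the paired cluster bootstrap, and classification |
| `cropshift.diagnostics` | per-cell OLS trend maps, significant-area fractions, harvested-area centroid tracks, yield-extreme comparison |
| `cropshift.synthetic` | seeded scenario generators (static / migration / expansion / irrigation-expansion) with ground truth |
| `cropshift.pipeline`, `cropshift.cli` | YAML-configured orchestration and the `cropshift` command |

## Worked example

Run the adaptation test on a synthetic poleward-migration scenario
(20×20 half-degree cells, 1973–2012, 0.03 °C/yr warming, crop belt moving
poleward at 0.05°/yr):

```python
import cropshift as cs

spec = cs.ScenarioSpec(scenario="migration", seed=11)
climate = cs.make_climate(spec)                      # monthly degC + noise
panel, truth = cs.make_area_scenario(spec)           # annual rainfed areas
season = cs.crop_season_panel(climate, cs.make_calendar(spec), spec.years)
dynamic = cs.make_weights(panel, "dynamic")
static = cs.make_weights(panel, "static")            # frozen 1973-77 mean

res = cs.run_adaptation_test(season, dynamic, static,
                             tau=0.95, n_boot=200, seed=5)
print(f"beta_obs={res.beta_observed:+.5f}  beta_cf={res.beta_counterfactual:+.5f}")
print(f"theta={res.theta:+.5f}  p_adapt={res.p_adapt:.3f}  label={res.label}")
```

Output:

```
beta_obs=+0.01184  beta_cf=+0.03050
theta=-0.01866  p_adapt=0.000  label=adaptive_migration
```

Reading: the frozen-area model sees the pure climate trend (+0.0305 °C/yr,
the generator's true warming rate of 0.03 within noise), while the areas the
crop actually occupied warmed at only +0.0118 °C/yr because the belt moved
poleward; the difference (−0.0187 °C/yr ≈ −0.73 °C over 39 years) is
negative in every bootstrap replicate, so the scenario is classified as
adaptive migration — matching the generator's truth.

The same analysis over all four bundled scenarios, from a shell:

```bash
cropshift analyze --seed 42 --out results --tau 0.95 --n-boot 200 \
    --crop static --crop migration --crop expansion --crop irrigation_expansion
```

which writes `results.csv` (slopes, Θ, p-values, labels per crop × τ),
`trends_<crop>.nc` (per-cell temperature and area trend maps),
`centroids.csv`, `trend_summary.csv`, and `manifest.json`.

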