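# Methods

## Growing-season temperature

Monthly mean temperatures are converted to daily values by linear
interpolation on a fixed 365-day calendar (leap days ignored). Each monthly
value is anchored at its month's midpoint — cumulative day count of the
preceding months plus half the month length, so January anchors at day 15.5
— and daily values vary linearly between consecutive anchors across year
boundaries. Before the first anchor of the series and after the last, the
nearest anchor value is held constant; consequently season means touching
the first ~15 or last ~16 days of the record use held rather than
interpolated values, which is why analyses should supply one spin-up year of
climate before the first labeled year (the synthetic generator does this
automatically).

The growing-season mean for a cell-year is the arithmetic mean of daily
temperatures from the planting day through the harvest day inclusive.
Calendars are constant in time. A season whose planting day exceeds its
harvest day wraps the calendar year (winter crops); it takes days
plant..365 of the prior year plus 1..harvest of the labeled year and is
labeled by the **harvest** year, so a season's outcome is paired with the
harvested-area weights of the year in which it was harvested, and no data
after the harvest day of the labeled year is used. Cells with two seasons
contribute the unweighted mean of the per-season means; the two-season
combination rule and the midpoint anchoring are conventions of this package
(month-start anchoring is the obvious alternative and shifts season means by
a fraction of the month-to-month gradient).

Calendars supplied at finer resolution than the climate are upscaled with an
area-weighted circular mean on the 365-day circle (day-of-year is an angle;
unit vectors are averaged with harvested-area weights and the result is
rounded to a whole day in [1, 365]). A modal-value rule would be the main
alternative; the circular mean degrades more gracefully when planting dates
straddle the new year.

## Rainfed areas and weights

Rainfed area = total harvested area × (1 − irrigated fraction). Irrigated
fractions through time scale a base-year (circa-2000) fraction by the ratio
of area equipped for irrigation (AEI) in year *y* to AEI in the base year:
linear interpolation between AEI observations, linear extrapolation from the
two nearest observations outside the observed span, then clamping to [0, 1].
The clamp is the package's reading of capping the scaled fraction at the
full cell; it makes the series total (any inputs give a valid fraction).

The **dynamic** weight of a cell-year is its rainfed area that year. The
**static** (counterfactual) weight is the cell's mean rainfed area over the
reference window, 1973–1977 by default, repeated for every analysis year.
Weighted quantile fits are invariant to a global rescaling of weights, so
hectares, square kilometres, or normalized shares give identical trends.

## Weighted quantile regression

The τ-quantile trend line minimizes the weighted check loss
Σᵢ wᵢ ρ_τ(yᵢ − a − b·tᵢ), ρ_τ(u) = u(τ − 1{u<0}), pooled over all cell-year
observations (one observation per cell-year; masked or zero-weight
observations dropped per model). Years are centered at their weighted mean
before solving and weights normalized to sum one; the reported intercept and
objective are transformed back.

Because the check loss is positively homogeneous, the weighted problem is an
unweighted one on row-scaled data, whose dual is a box-constrained linear
program with two equality constraints. The solver is a Mehrotra
predictor–corrector interior-point iteration on that dual (the
Frisch–Newton scheme used for quantile regression); with two regression
parameters the normal equations are 2×2 and each iteration costs O(n). The
interior solution is then polished to an exact **vertex**: an optimal basic
solution interpolates two observations, so lines through pairs of the
smallest-|residual| points are enumerated, the best is taken, and a
subgradient certificate (zero must lie in the subdifferential, a 2×2 solve
plus box check, or a tiny feasibility LP when more than two points lie on
the line) confirms global optimality. If the certificate fails the candidate
pool is widened (12 → 40 → 160) and, as a last resort, the full LP is solved
with HiGHS and re-polished. Problems with at most 60 observations skip the
interior point and enumerate all pairs. Ties among exactly optimal vertices
(objective difference below 10⁻¹² relative — genuine degeneracy, e.g. integer
data) are broken by smallest |slope|, then smallest intercept, making the
output deterministic. The tie window must stay far below the ~10⁻⁸
vertex-to-vertex objective gaps of large noisy samples, otherwise a
near-optimal vertex could be returned.

Numerical contract, verified by tests: the objective equals the brute-force
minimum over all point-pair lines to 1e-8; the fit is invariant to weight
splitting and weight scaling; and the weighted mass strictly below the line
lies in [τ − Z/W, τ] where Z is the combined weight of the interpolated
points (the exact subgradient bound — note Z can reach twice the largest
single weight, not one times it).

Period changes are reported as slope × (last year − first year), i.e. slope
× 39 for 1973–2012 (the inclusive-span convention; ×40 would be the
alternative reading).

## The adaptation test

Θ = β_o − β_c at τ = 0.95 (the warm bound; 0.9, 0.93, 0.97 and the cold
bound 0.05 are also fitted). Inference is a paired cluster bootstrap: grid
cells are resampled with replacement, a sampled cell contributes its entire
year series (multiplicity multiplies its weight), and both models are refit
on the identical resample so their slopes stay coupled. Resampling cells
rather than cell-years preserves within-cell temporal dependence; an
unpaired variant (independent resamples for the two models) is available
behind a flag and is more conservative. Degenerate resamples (fewer than two
usable years, or zero total weight) are redrawn, up to 100 attempts.

p_adapt is the proportion of bootstrap Θ samples ≥ 0 and p_expand the
proportion ≤ 0; samples exactly at zero count toward both (conservative).
Labels at level α = 0.05: `adaptive_migration` if p_adapt < α,
`niche_expansion` if p_expand < α, else `no_evidence`. Bootstrap streams are
seeded per crop × τ by stable hashing of the labels combined with the master
seed, so partial reruns reproduce exactly.

## Synthetic study conditions

The generator produces the full input stack with known truth. Defaults — a
20×20 half-degree grid spanning 35–45° N, years 1973–2012 plus one spin-up
year, base temperature 30 °C minus 0.5 °C per degree latitude, seasonal
amplitude 8 °C (sign-flipped in the southern hemisphere), warming 0.03 °C/yr,
and independent N(0, 0.5 °C) noise per cell-month — give one pooled
regression of 16,000 cell-year observations, large enough to exercise the
estimator and small enough for seeded replication studies on one CPU.
Spatially correlated noise can be switched on via a Gaussian smoothing
kernel but is off by default.

Area scenarios, all Gaussian-in-latitude belts (σ = 2°, peak 1000 ha):

- **static** — belt constant in time (truth: no evidence). Because the
  areas never change, dynamic and static weights coincide and Θ is exactly
  zero in every replicate; the scenario checks that the machinery produces
  no spurious signal.
- **migration** — belt center moves poleward at 0.05°/yr (truth: adaptive
  migration; constructed centroid displacement 0.05 × 39 = 1.95°). The belt
  starts at 38.5° N so it has room to move.
- **expansion** — the belt gains 2.5% of current total area per year,
  spread over cells at or above the current area-weighted 95th-percentile
  temperature (truth: niche expansion). The ~2.5%/yr compounding growth
  matches the observed magnitude of real-world expansion of warm-region
  crops (on the order of +160% over four decades). The belt starts at 41° N
  so warmer land exists inside the domain; growth continues into the
  warmest available land once the bound saturates.
- **irrigation_expansion** — total areas static, but the irrigated fraction
  in the hottest decile of cultivated cells ramps linearly from 0 to 0.9
  over the period, so the *rainfed* distribution cools (truth: adaptive
  migration). This isolates the irrigation pathway: exposure falls with no
  land movement at all.

Yield surfaces are Gaussian in temperature (y_max 8 t/ha, optimum 15 °C,
breadth 4 °C), so both temperature tails under-yield by construction.

What the generator does **not** emulate: spatial autocorrelation of weather
(noise is iid by default), ENSO-like interannual structure, trends in
planting dates, multiple interacting crops, and economic drivers of area
change. Passing tests therefore demonstrate that the method recovers known
migration/expansion signals under idealized noise, not that it is robust to
every feature of observational data; with real inputs the cluster bootstrap
carries the burden of spatial dependence, and iid noise makes the synthetic
type-I study an easier condition than reality.

## Verification at desk scale

The test suite replays the full pipeline across seeds (bootstrap size 200,
the package's desk-scale choice): the counterfactual 95th-percentile change
over 39 years (true value 1.17 °C) must fall inside the 95% bootstrap
interval in ≥ 90% of 50 static-scenario runs; the test must reject in ≤ 12%
of 100 static runs at α = 0.05; the migration and expansion scenarios must
be correctly labeled in ≥ 90% of 50 runs each and irrigation-expansion
detected as adaptive migration in ≥ 80%; and the bundled four-scenario suite
must be bit-identical across reruns with the same master seed.
`scripts/acceptance.py` re-derives the headline quantities from scratch with
500 bootstrap replicates.

## Degenerate inputs and edge rules

Fractions outside [0, 1], negative areas, day-of-year outside [1, 365], and
irregular grids are rejected at construction. Cells with no calendar, masked
temperatures, or zero weight are dropped per model. Top-area masks keep the
smallest prefix of cells (sorted by mean area descending, ties by grid
index) whose cumulative area reaches the requested fraction. Fits require at
least two distinct years with positive weight. The area-weighted quantile
used for temperature thresholds is the smallest value at which the
cumulative sorted area share reaches the level, matching an "x% of area"
reading rather than a cell-count quantile. Centroids use plain weighted
means of cell-center coordinates (the visual centroid on a regional map);
regions spanning the antimeridian are rejected, and great-circle geometry
(sphere radius 6371 km) is used only for displacement and bearing.
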