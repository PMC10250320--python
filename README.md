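# borealtrend

Transect-based analysis of tree-cover trends across a biome with two
latitudinal boundaries, built for the kind of question asked of the North
American boreal forest: is cover being lost near the southern (warm) boundary
while densifying in the northern interior — an asymmetry that would signal a
transient contraction of the biome's latitudinal range?

The package implements the full analysis chain as reusable, tested
components, and ships a seeded synthetic-landscape generator that emulates
the statistical structure of the real inputs (annual percent tree-cover
stacks, fire/harvest disturbance grids with event years, a land-cover class
map, coarse climate grids with a warming trend, elevation), so the whole
pipeline can be exercised end-to-end against known ground truth.

## Methods at a glance

- **Trend per plot** — Theil–Sen slope β̂ = median{(y_j − y_i)/(t_j − t_i)}
  over all year pairs, with Yue–Pilon trend-free pre-whitening: detrend with
  β̂, estimate the lag-1 autocorrelation r₁ of the residuals, whiten
  y″_t = y′_t − r₁ y′_{t−1} when |r₁| > 0.05, re-add the trend, then
  re-estimate the slope and the tie-corrected Mann–Kendall statistic (S, Z,
  two-sided p). Relative change divides the slope by the period-mean cover
  (flagged undefined below 1 % cover).
- **Spatial structure** — empirical semivariogram γ(h) = Σ(z_i − z_j)²/2N_h
  on great-circle distances from 10,000 random points of the trend field
  (after removing a quadratic drift surface); weighted least-squares fits of
  exponential/Gaussian/spherical models; the 95 %-of-sill *practical range*
  (3a for the exponential) sets the minimum transect spacing; the residual
  correlation family is chosen by AICc over intercept-only spatial GLS fits.
- **Sampling design** — random south–north transects accepted greedily under
  the minimum spacing; contiguous 0.05° plots between the two boundary
  crossings plus 20 extension plots beyond each; *standardised boundary
  distance* (SBD): −1 at the southern crossing, +1 at the northern, linear in
  plot index between, ±0.025 per extension plot up to ±1.5. Plots whose
  dominant land-cover class is urban/cropland/wetland/bare/water/snow are
  excluded; the rest carry one of six vegetation classes and one of five
  disturbance categories (fire/harvest × 2000–2019/1985–1999, or
  undisturbed), assigned by largest disturbed area with any-sign sensitivity.
- **Summaries** — running means of trend along SBD in 0.025 bins; zonal and
  stratum means ± sample SD; missing-aware block-mean trend maps; a
  range-shrinkage metric (change between epochs of the 5th–95th SBD quantile
  span of plots above a 10 % cover threshold).
- **Smooth models** — penalized cubic B-spline smooths of trend against a
  predictor, one coefficient block per disturbance (or disturbance ×
  vegetation) stratum with a shared GCV-selected penalty, a transect random
  intercept and exponentially decaying residual spatial correlation,
  estimated by two-stage feasible GLS; curves ± pointwise SE on a grid.

## Worked example

```sh
python analysis/01_simulate_landscape.py
python analysis/02_spatial_structure.py
python analysis/03_sample_transects.py
python analysis/04_trends_profiles.py
python analysis/05_smooth_fits.py
```

The drivers write their tables under `results/` and print, for the default
seeded landscape (15° × 10° at 0.01°, 2000–2019):

```
exponential  nugget 0.0000  partial sill 0.0777  practical range    73.7 km
=> minimum transect spacing: 74 km
10 transects at >= 74 km spacing
1410 plots (53 excluded by the land-cover rule)
biome-wide trend: +0.107 +/- 0.338 %/yr (n = 1357)
  northern_interior  +0.227 +/- 0.347 %/yr (n = 195)
  southern_boundary  -0.059 +/- 0.247 %/yr (n = 85)
treed-belt SBD span: 1.938 -> 1.908 (shrinkage +0.031 sbd units)
```

Read: the fitted autocorrelation range of the trend field (~74 km) fixes the
transect spacing; the sampled plots recover the generator's asymmetry —
mean loss at the southern boundary, strongest gains in the northern interior,
and a northward retreat of the treed belt's southern edge (positive
shrinkage). The same numbers for the real rasters would be obtained by
pointing `RunConfig(simulate=False, input_dir=...)` at a directory in the
bundle layout (`cover/YYYY.tif`, `landcover.tif`, `disturbance_*.tif`,
climate and elevation grids, `boundaries.geojson`).

The one-shot equivalent is `borealtrend run-all --seed 1 --out results/run`,
and each stage is also a CLI subcommand (`simulate`, `variogram`, `sample`,
`trend`, `summarize`, `fit`).

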