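# Methods

This note documents the models and procedures implemented in `borealtrend`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic test bed does and does not establish about real data.

## Trend estimation

Each plot (or pixel) carries an annual series y_t, t = 2000…2019. The trend
is the Theil–Sen slope, the median of all pairwise slopes
(y_j − y_i)/(t_j − t_i), i < j — robust to outliers and to the non-Gaussian
interannual noise of percent-cover products. Serial correlation is handled by
trend-free pre-whitening: estimate the slope b, detrend, estimate the lag-1
autocorrelation r₁ of the residuals, whiten (y′_t − r₁ y′_{t−1}, losing one
year), re-add b·t, and re-estimate slope and Mann–Kendall statistics on the
whitened series. Pre-whitening is applied only when |r₁| > 0.05: below that
the correction is smaller than its own estimation noise and the one-year
length loss is not worth paying. Pre-whitening corrects the *size* of the
trend test under AR(1) noise; the Sen slope itself is essentially unbiased
with or without it (the Monte-Carlo suite verifies both statements rather
than assuming them).

The Mann–Kendall statistic uses the standard tie-corrected variance and the
±1 continuity correction; an all-tied series reports S = 0, p = 1. Series
with fewer than 15 of the nominal 20 years are flagged missing; gappy series
are re-indexed to consecutive steps for the whitening pass only (slopes
always use the true year axis). Relative change divides the slope by the
period-mean cover and is flagged undefined below 1 % mean cover, where the
ratio is numerically meaningless. All trends are retained regardless of
significance — the analysis describes a field, not a set of discoveries.

## Spatial structure and the transect spacing

The spacing rule asks: how far apart must transects be for their trend values
to be effectively independent? We sample 10,000 random retained-class pixels
of the trend field, remove a quadratic polynomial surface in (lon, lat), and
compute the Matheron semivariogram on great-circle (haversine) distances.
The drift removal matters: a biome-wide trend gradient is a deterministic
drift, and a variogram of raw values under drift never levels off — at the
compressed scale of the synthetic domain it inflates fitted ranges by orders
of magnitude. Residual variography is the standard remedy. Default lags are
10 km bins to 150 km in the pipeline (the module default is 25 km to 500 km
for general use); the fit is weighted least squares with pair-count weights,
and the range parameter is capped at 3× the largest lag because nothing
beyond the observed lags is identifiable.

"Range" is operationalized as the 95 %-of-sill practical range: 3a for the
exponential model, √3·a for the Gaussian, a for the spherical. A fit whose
partial sill is under 5 % of the total sill is flagged not-identifiable
(pure nugget — no finite range, and no data-driven spacing).

The residual correlation *family* is chosen by AICc among none / exponential
/ Gaussian / spherical, each fitted as an intercept-only Gaussian model by
maximum likelihood with the mean and variance profiled out and the practical
range and nugget fraction optimized (Nelder–Mead, two starts). Family
discrimination is weak below a few hundred points: with 150 points the
exponential and spherical likelihoods are statistically indistinguishable on
exponential truth, with 300 they separate. The pipeline therefore selects on
300-point subsamples.

## Sampling design and standardised boundary distance

Transect longitudes are drawn uniformly and accepted greedily while at least
the minimum spacing (great-circle, evaluated at the mid-domain latitude) from
every accepted transect. Plots are axis-aligned half-open 0.05° cells on a
global lattice; a transect contributes every cell between the rows containing
its two boundary crossings, plus 20 extension cells beyond each (≈ 111 km).

SBD maps the crossing rows to −1 and +1, interior rows linearly by index
(−1 + 2(i−1)/(N−1)), and the k-th extension row to ±(1 + 0.025k), so the
20th extension plot lands exactly at ±1.5. The 0.025 step is fixed by the
requirement that 20 plots span the 0.5 overshoot. Within a transect SBD is
strictly increasing with latitude (capped at ±1.5).

Aggregation and exclusion: the plot's dominant land-cover class is the mode
of its pixels; if that mode is urban, cropland, wetland, bare, water or
snow/ice the plot is excluded and carries no trend. Otherwise cover is
averaged over non-excluded pixels only, and the vegetation class is the
dominant class (ties resolve to the lowest class code, which errs toward
exclusion). Disturbance: a plot is disturbed if *any* pixel is disturbed;
fire vs harvest is decided by the larger disturbed-area fraction (ties to
fire, deterministically); the recorded year is the winning type's
largest-area event year (ties to the earliest); the category crosses the
type with the period (2000–2019 vs 1985–1999; earlier events count as
undisturbed). Climate covariates come from the nearest coarse climate cell;
means and pre-whitened trends are computed for 1980–2019 and 2000–2019.

## Profile summaries

Binned running means use half-open 0.025-SBD bins partitioning [−1.5, 1.5]
(120 bins); every plot with a defined value contributes to exactly one bin,
so weighted bin means recompose the global mean. Stratum summaries report
mean ± sample SD (n−1) and n; zones are configurable SBD intervals with
defaults southern boundary (−1.1, −0.9], interior (−0.5, 0.5], northern
interior (0.5, 0.9]. Coarse maps are missing-aware block means (all-missing
blocks stay missing; edges that do not fill a block are trimmed).

Range shrinkage is a stand-in metric with an explicit definition: per epoch
(default: first and last five years' mean cover), plots with cover ≥ 10 %
count as treed; the treed belt's span is the distance between the 5th and
95th SBD quantiles of treed plots; shrinkage is the first-epoch span minus
the second-epoch span (positive = contraction). The threshold and quantiles
are parameters, and the per-bin treed fraction table is emitted for
sensitivity checks.

## Smooth profile models

The semiparametric model for trend vs a predictor x is a penalized cubic
B-spline smooth (default basis dimension 10, basis and difference penalty
from statsmodels) fitted per stratum with one shared penalty weight, plus a
transect random intercept and exponentially decaying residual spatial
correlation. Estimation is two-stage feasible GLS:

1. penalized OLS with the penalty weight chosen by GCV over a 29-point
   logarithmic grid (10⁻⁸…10⁶ — wide enough that noiseless data select an
   effectively unpenalized fit);
2. variance components from the stage-1 residuals — nugget, partial sill and
   practical range from a residual variogram, transect variance from the
   excess variance of transect residual means — assembled into a dense
   covariance, followed by a whitened penalized refit. Coefficient
   covariance is σ̂²(XᵀV⁻¹X + λS)⁻¹, giving pointwise curve SEs.

Curves are predicted on an even grid restricted to each stratum's observed
predictor range. Strata under 10 plots are dropped with a warning; a
constant predictor yields a flagged degenerate fit, not an exception.
One model is fitted per predictor (the predictors are strongly collinear;
`collinearity_screen` reports the pairwise correlations), with identical
random-effect and correlation settings across predictors. Against mgcv's
`gam(y ~ s(x))` on shared data the fitted curves agree to well within the
noise level (cross-checked in the test suite). Simulation calibration: on
humpback signals with exponential-correlated noise the median curve RMSE is
~6 % of the signal amplitude and nominal 95 % bands cover the truth at
~94–95 % of grid points.

Limitations: the two variance stages are not jointly maximized (a full GAMM
would profile them together); SEs ignore the uncertainty of the variance
components themselves; strata share one penalty by design (togglable only by
fitting strata separately).

## Synthetic landscape

The generator emulates the statistical structure of the real inputs on a
15° × 10° (lon × lat) domain at 0.01° — a desk-scale stand-in for 250 m
continental rasters. Cover is assembled per pixel and year as

    cover = clip( baseline(sbd) + g(sbd)·(t − 2000) + spatial_field
                  + AR1_t + disturbance_t , 0, 100 )

with:

- two sinusoidal boundary polylines 5° apart (wiggle amplitude 0.6°);
- an asymmetric trend profile g(sbd) through (−1.25, 0), (−1, −0.13),
  (0.5, +0.22), (1, +0.05), (1.25, 0) %/yr (monotone PCHIP) — southern
  losses, strongest northern-interior gains;
- a baseline cover profile peaking at 45 % in the interior and thinning to
  below the 10 % treed threshold near both boundaries, so trend-driven
  threshold crossings (and hence range shrinkage) can occur;
- AR(1) interannual noise (ρ = 0.3, marginal sd 2 %), a static spatially
  correlated field (exponential covariance, 90 km practical range, sd 3 %)
  and a spatially correlated trend-noise field (110 km, 0.06 %/yr) — the
  last is what gives the trend field a finite autocorrelation range for the
  variogram stage to find, the analogue of the ~10²-km ranges seen in real
  trend fields. All three noise amplitudes scale with baseline cover
  (clip(baseline/25, 0.15, 1)): a bounded percent product has little
  variance near its floor, and this keeps clipping below 1 % (the generator
  reports the clipped fraction; ~0.2 % under defaults);
- circular disturbance patches (0.5 per deg², radius 0.05–0.3°, 70 % fire,
  years 1985–2019): a step drop (30 % fire / 40 % harvest, capped at the
  local baseline — a stand cannot lose more cover than it has) followed by
  linear recovery whose rate rises from 1.0 %/yr at sbd −1.5 to 2.5 %/yr at
  +1.5 (slower southern recovery);
- land-cover classes assigned from baseline cover with jitter, plus random
  water/wetland disks (2 %/1 % of area); climate stacks at 0.25° with MAT
  falling 0.6 °C per degree latitude and warming at 0.04 °C/yr since 1980;
  elevation as a gentle gradient with relief.

Spatial fields are generated by circulant embedding on the doubled torus
(FFT, float32, negative eigenvalues clipped — negligible mass for these
parameters). All stage RNGs are spawned from a single SeedSequence, so a
given (config, seed) reproduces bit-identical rasters and ledgers. The
ground-truth bundle (per-pixel sbd, per-pixel trend g + trend noise, the
disturbance patch ledger, the climate trend) is sufficient to score any
pipeline estimate.

What the test bed does not emulate: sensor artifacts and view-angle effects,
disturbance shapes other than disks, fire-probability gradients, land-cover
change over time, anisotropic correlation, and real boundary geometry.
Passing the suite shows the *estimators and pipeline logic* recover known
structure under realistic noise; it does not validate the ecological
conclusions on real rasters.

## Problem sizes and runtime choices

Monte-Carlo sizes were chosen to give stable statistics at interactive cost:
10,000 series for the Sen oracle sweep, 2,000 AR(1) replicates, 5,000 null
replicates, 20 field replicates for range recovery, 50 replicates for smooth
recovery, and 20 seeded full-pipeline runs (the pipeline's per-run cost is
dominated by landscape generation and the 10,000-point variogram). The
end-to-end replicate runs disable the coarse-map and smooth-fit stages,
which have their own dedicated checks, and score the binned profile of
undisturbed plots against g(sbd) — disturbance effects are ground truth in
their own right (the patch ledger), not part of g. Zonal means are computed
over all plots, as in a real zonal summary.

## Numerical details and edge cases

- Zero-variance inputs: lag-1 autocorrelation returns 0 by convention;
  all-tied Mann–Kendall returns (0, 0, 1).
- Sen slope requires ≥ 2 distinct years; pre-whitening requires ≥ 4 equally
  spaced points and rejects unequal spacing (resample upstream).
- Variogram bins with no pairs report count 0 and missing semivariance and
  are excluded from fitting; fits need ≥ 4 populated lags.
- The variogram fit bounds (nugget, partial sill ≤ 10× the observed maximum
  semivariance; range ≤ 3× max lag) prevent runaway extrapolation under
  residual drift; hitting the range bound is visible in the stored fit.
- GeoTIFFs are written with explicit ModelPixelScale/ModelTiepoint/GeoKey
  tags (WGS84) and GDAL-style nodata; arrays are stored north-up and held
  in memory with ascending latitude.
- Fire/harvest fraction ties break to fire; event-year ties to the earliest
  year; vegetation-mode ties to the lowest class code. All three are
  deterministic and documented rather than random.
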