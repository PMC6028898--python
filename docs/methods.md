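# Methods

This document describes the modelling choices in `phenoml`: what each stage
computes, which parameters it exposes, and where the synthetic study is — and
is not — a faithful stand-in for a real phenological network.

## Problem setting

The quantity modelled is the onset day-of-year (DOY) of a plant phenophase
(e.g. lilac flowering, birch leaf colouring) observed at ground stations over
a multi-year study period. Predictors come from three sources aggregated to a
10×10 km grid:

* **meteorological** (42 features): monthly and seasonal aggregates of daily
  mean temperature and precipitation, cumulative growing degree days and
  precipitation days;
* **satellite** (69 features): 64 vegetation-index features from four indices
  (NDVI, EVI, LAI, FPAR) plus five snow-cover metrics;
* **spatial** (4 features): projected x/y coordinates, altitude and distance
  to the coast.

Models are evaluated under leave-one-year-out (LOYO) cross-validation, so
scores measure transfer to an unseen year, the regime that matters for
forecasting.

## Synthetic study generator

Real phenological archives are not redistributable, so the package bundles a
generator that emulates the full data stack — station registry, daily gridded
weather, snow cover, pixel-level vegetation-index composites and observed
onsets — from one root seed. Every stage draws from a named substream
(`stations`, `meteo`, `senescence`, `onset`, `vi`, `outliers`) of
`numpy.random.SeedSequence(seed)`, so regenerating any one artefact is
reproducible and independent of the others.

### Weather

Daily mean temperature at a grid cell is a sinusoidal climatology plus
structured anomalies:

* annual mean 9.0 °C at the southern sea-level edge, seasonal amplitude
  10.5 °C, coldest day DOY 15;
* meridional gradient −0.35 °C per 100 km northward;
* altitudinal lapse 6.5 °C per km;
* coastal moderation of the seasonal amplitude (1.5 °C, e-folding distance
  100 km from the northern coast);
* a common interannual year effect, N(0, 1 °C), shared by all cells — this is
  what makes LOYO much harder than random-split CV;
* AR(1) daily weather noise (sd 3 °C, lag-1 correlation 0.7) shared
  regionally.

Precipitation is Bernoulli(0.45) wet days with Gamma(shape 0.8, scale 6 mm)
amounts. Snow-water equivalent accumulates precipitation on days with mean
temperature below 0 °C and melts at 2.5 mm per degree-day above zero — a
deliberately minimal degree-day snowpack.

The weather record starts one spin-up year before the first study year so
previous-year predictors exist for every study year.

### Canopy and onsets

A noise-free canopy greenness curve per cell and year is the product of two
logistics: green-up centred on the day cumulative GDD (base 5 °C) reaches
170 (rate 0.09 d⁻¹), and senescence centred on DOY 275 + N(0, 8 d) (rate
0.06 d⁻¹). The senescence midpoint is drawn from a weather-independent
substream — by construction, autumn truth is *not* recoverable from
temperature, which is what the autumn-attribution acceptance test exploits.

Spring onsets are threshold crossings of cumulative GDD (per phenophase base
and threshold); autumn onsets are the first day after Aug 1 where the canopy
curve falls below a phenophase-specific fraction of its summer maximum.
Observed onsets add N(0, 3 d) observer noise and are rounded to whole days;
unreachable thresholds yield missing records. Six default phenophases span
DOY ~70 (hazel flowering) to ~300 (birch leaf fall).

### Satellite sampling

Each cell holds 9 synthetic pixels sampled every 8 days (mimicking composite
products). Pixel values scale the canopy curve into each index's range, with
a fixed per-pixel bias (sd 0.02 of the index amplitude), reliability flags
0–3 drawn with probabilities (0.50, 0.25, 0.15, 0.10), additive noise whose
sd grows with the flag (0.01–0.10 of amplitude), winter-baseline values under
snow, and whole observations dropped with probability 0.15 (clouds).

### Realism and limits

The generator reproduces the *structure* that matters for exercising the
pipeline — spatially coherent climate, interannual variability, thermal-time
spring truth, canopy-driven autumn truth, reliability-dependent satellite
noise, snow contamination, irregular sampling — but it is not a calibrated
climate model: no weather fronts, no spatially varying precipitation, no
drought stress on the canopy, a single shared year effect rather than
synoptic fields, and snow from a two-parameter degree-day model. Absolute
RMSEs on synthetic data should therefore be read as self-consistency checks,
not as forecasts of real-data skill.

## Quality control of onset observations

Ground observations are subjective; gross errors (misread stage,
transcription slip) must be screened before modelling. The screen mimics
kriging with external drift in simplified form, per phenophase and year:

1. least-squares drift of onset DOY on 1 + x + y + altitude;
2. leave-one-station-out interpolation of drift residuals with an exponential
   distance kernel (range 100 km);
3. a record is an outlier when its deviation from the cross-validated
   prediction exceeds `k` robust standard deviations (1.4826 × MAD), k = 3 by
   default.

With fewer than 8 stations the screen warns and keeps everything — a robust
scale estimate from a handful of points would be noise. Operating
characteristics at the study scale (50 stations, observer noise sd 3 d, 10 %
outliers of ±25 d): sensitivity ≈ 0.96, false-positive rate ≈ 0.004.

## Predictor engineering

### Cutoff rule (no future leakage)

All predictors for a phenophase are computed through a cutoff: the last day
of the calendar month containing the *training* mean onset DOY, recomputed
per CV fold from training years only. Rows never see data after their own
cutoff; the acceptance suite enforces this by perturbation. Previous-year
predictors (previous December, previous-year seasons) deliberately reach into
the preceding calendar year — that is part of the design, not leakage of the
response.

### Meteorological features (42)

Monthly mean temperatures (12) and precipitation sums (12) of the target
year, previous-December values (2), previous-year seasonal temperature means
(4), winter and spring means (2), cumulative growing degree days from Jan 1
at nine bases 0–8 °C (9), and the count of precipitation days ≥ 1 mm (1).
Months ending after the cutoff are NaN and handled by training-median
imputation in the model layer.

### Satellite features (69)

The vegetation-index chain per cell, index and reliability stratum:

1. **snow masking** — values observed under snow cover are set to the winter
   baseline (zero greenness) rather than treated as vegetation signal;
2. **reliability-stratified aggregation** over the cell's pixels for four
   flag sets: all, {0}, {0,1}, {0,1,2};
3. **gap filling** by linear interpolation in time (edge values extended);
4. **smoothing-spline densification** to daily resolution on a trailing
   150-day support window ending at the cutoff, evaluated through the cutoff
   date;
5. derived series: trailing 7-day rolling mean, two rate-of-change contrasts
   (10-day mean minus 30-day mean; 7-day mean minus 10-day mean), and
   per-location normalization against the training years' history in a
   trailing 7-calendar-day window.

That yields 4 indices × 16 variants = 64 features, plus five snow metrics
(presence at cutoff, consecutive snow and snow-free runs ending at the
cutoff, snow days in the cutoff month, last snow DOY).

### Numerical choices

* **Fixed spline penalty.** Daily densification uses
  `scipy.interpolate.make_smoothing_spline` with a fixed penalty λ = 10
  rather than per-series generalized cross-validation. Benchmarked on 200
  synthetic composite series, the median maximum deviation from the
  GCV-selected fit is ~0.005 index units — below the flag-0 observation noise
  — for a ~12× speedup of the dominant pipeline cost. λ is invariant to the
  index's value scale (both the residual and penalty terms are quadratic in
  y), so one constant serves NDVI through LAI.
* **Causal windows everywhere.** Rolling means and rates are trailing;
  normalization pools only training-year history in a trailing calendar
  window; spline support ends at the cutoff. Nothing anywhere reads past a
  row's cutoff.
* **Non-leap DOY convention.** Cutoff months are derived from onset DOY via
  the non-leap calendar; in leap years the cutoff is still the end of that
  calendar month, so the mapping is stable across years.

## Model suite

Six techniques behind one `fit(spec, X, y)` / `predict(fit_result, X)`
interface:

| technique | estimator | tuning |
|---|---|---|
| `lm` | ordinary least squares | — |
| `lmAIC` | forward–backward stepwise OLS minimizing AIC | — |
| `lasso` | L1-penalized regression | inner-CV over the alpha path |
| `pcr` | principal-component regression | inner-CV over component count |
| `gbm` | gradient-boosted trees | inner-CV over a small grid |
| `rf` | random forest | inner-CV over a small grid |

Shared preprocessing, fitted on training data only: median imputation (zero
for all-NaN columns), zero-variance column removal, and — for the two OLS
variants — removal of linearly aliased columns via QR with column pivoting
(115 engineered features contain exact near-duplicates by construction, e.g.
reliability strata that coincide when all pixels are clean). Minimum 20
training rows. `relative_influence` (gbm only) returns per-feature relative
influence scaled to sum to 100.

## Shadow-feature screening (Boruta-style)

All-relevant feature selection: each iteration appends one freshly permuted
"shadow" copy of every undecided feature, fits a random forest, and scores a
real feature a *hit* when its importance exceeds the maximum shadow
importance. Accumulated hits are tested against Binomial(iterations, ½) with
two one-sided binomial tests at level α (default 0.01), Bonferroni-corrected
over the undecided features; significantly many hits confirm, significantly
few reject; survivors at `max_iter` (default 100) are tentative. The
"boruta" predictor group passes confirmed ∪ tentative features to the models.

The importance statistic is the **Z-score of out-of-bag permutation
importance** (per-tree OOB MSE increase when a column is permuted, averaged
over trees and divided by its standard error). This choice is load-bearing:
greedy impurity importance is strongly convex in a feature's sample
correlation with the response, so the single most chance-correlated noise
feature beats every freshly permuted shadow almost deterministically and gets
falsely confirmed. Accuracy-loss Z-scores are approximately linear in
incremental R² and carry per-feature uncertainty, restoring the intended
false-confirmation control (verified: empty confirmed set in ≥ 95 % of
pure-noise runs at α = 0.01, while a genuinely informative feature is
confirmed in 10/10 runs).

## Evaluation

* **LOYO folds**: one fold per study year; every training-fold artefact —
  cutoff rule, feature table, imputation medians, screening decision,
  hyperparameters, normalization history — is recomputed from training years
  alone.
* **RMSE (days)**: fold-level RMSEs averaged over folds.
* **R²**: squared Pearson correlation between pooled out-of-fold predictions
  and observations.
* **Best model**: per phenophase, minimum mean RMSE over the technique ×
  predictor-group grid; ties break toward the simpler technique
  (lm < lmAIC < lasso < pcr < rf < gbm).
* **Climatological baseline**: LOYO RMSE of predicting the training-years
  mean onset. Any model worth reporting must beat it.
* **Category attribution**: a gbm is fitted on all years and all 115
  predictors; the top-10 features by relative influence are partitioned into
  meteorological / satellite / spatial categories, influence is averaged
  within categories and the three means rescaled to 100 %.

## Design decisions

* **One root seed, named substreams.** All randomness in a run flows from
  `RunConfig.seed` through `SeedSequence` spawn keys; per-fold seeds are
  derived by hashing the (phenophase, technique, group, fold) label, so
  adding a technique never shifts another technique's stream.
* **Fold-aware caching.** Expensive intermediates (daily smoothed VI series,
  meteo monthly tables) are cached keyed by (cell, cutoff, training-years)
  so the 8-fold grid does not recompute them per model; cache keys include
  everything that could leak across folds.
* **Fail-loud contracts.** Gaps in daily series, unknown stations, missing
  previous-year data, empty grids and constant responses raise immediately
  rather than degrade silently; per-fold model failures are logged, recorded
  on the result object and skipped.
* **Text-first artefacts.** The CLI writes CSV/JSON/YAML plus PNG figures;
  every table is reproducible from the config and seed alone.

## Limitations

* Synthetic weather lacks synoptic spatial structure; spatial predictors
  therefore carry less information than in a real network, and the QC screen
  is exercised under a smooth drift rather than realistic mesoscale fields.
* The six techniques use small tuning grids chosen for CI runtimes; serious
  application should widen them.
* The screening step is O(iterations × RF fits) with permutation importance
  on top; for many phenophases × folds it dominates runtime, which is why it
  is opt-in via the `boruta` predictor group.
* R² is reported as squared correlation of pooled out-of-fold predictions;
  it is insensitive to calibration (a uniformly biased predictor can score
  well) and should be read alongside RMSE.
* Autumn truth is canopy-driven by construction; the satellite-dominance
  result on synthetic data demonstrates correct attribution, not a claim
  about real forests.
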