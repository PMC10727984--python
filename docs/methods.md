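# Methods

`agrishock` implements a counterfactual analysis of agricultural input
shocks on gridded cropland: stratify cropland into climate bins, learn the
yield–input relationship within each bin with random-forest regression,
re-predict yields after proportionally reducing off-farm inputs, and
aggregate the differences to production changes.  Because the global
datasets such an analysis runs on (gridded yields and harvested areas,
fertilizer and pesticide application rates, country-level machinery and
labour, daily climate reanalysis, soil grids) are large external downloads,
the package ships a synthetic-world generator with the same statistical
structure and a *known* yield response, so every stage can be exercised
end-to-end against ground truth.

## Climate binning

For each crop, growing degree days (GDD) accumulate on days whose mean
temperature exceeds a crop-specific base temperature; the daily
contribution is `min(T, cutoff) − base`, where the cutoff temperature caps
the heat a crop can use.  Annual sums are averaged over the years of the
climate record (21 by default).  The phrase "sum of temperatures above the
base" is sometimes used loosely in the agronomic literature for this same
quantity; the literal sum of capped temperatures is available behind the
`accumulation="sum_capped_temp"` switch, with the standard degree-day
definition as the default.

The GDD and mean-annual-precipitation climatologies are each split into
five quantiles **over the crop's cropland cells only**, and the joint
classification yields 25 bins (`bin_id = 5·(gdd_quintile−1) +
precip_quintile`).  Assignment is rank-based with ties broken by row-major
cell index, so each marginal quintile holds between ⌊N/5⌋ and ⌈N/5⌉ cells
and the assignment is invariant to monotone transforms of the
climatologies.  Joint bin occupancies are only approximately equal unless
the two climatologies are independent; nothing downstream requires joint
equality.

## Input processing

* Pesticide layers arrive as high/low estimates; the cellwise mean is
  used.  Each pesticide is rescaled by its 97.5th percentile over cropland
  (linear interpolation between order statistics; values above the
  percentile saturate at 1; an all-zero layer maps to 0), then the rescaled
  layers are summed within four groups — Herbicides, Insecticides,
  Fungicides, Others — so that low-dose active ingredients are not drowned
  out by heavy ones.
* Country-level machinery (metric horsepower per 1,000 ha) gaps are filled
  with the unweighted mean of the country's continent.
* Irrigation enters as the share (%) of harvested area under irrigation,
  0 where nothing is harvested.
* Topsoil organic-carbon and nitrogen densities (hg/m³ over 0–30 cm)
  convert to stocks as `density × depth` t/ha (the areal and mass unit
  factors cancel), with fine cells mean-aggregated into model cells first.
  Soil P is used in its native units.

The model feature set is 14 covariates: mineral N, P, K rates, non-mineral
fertilizer, machinery, labour, the four pesticide group indices, irrigation
share, soil N, soil P and soil organic carbon.  The feature table has one
row per cropland cell and is partitioned by bin.

## Yield models

Within each crop × bin, yield is regressed on the covariates with a random
forest (defaults: 1,000 trees, minimum leaf size 5, 2 candidate split
variables — deliberately below the p/3 regression convention, matching the
reference configuration for this analysis; the acceptance runs use 200
trees, which at these data volumes is statistically indistinguishable).
To limit leakage through spatial autocorrelation, a coarse lattice of
12 × 12 model cells (one degree on a 5-arcmin grid) is imposed over the
map; whole blocks are randomly assigned to training
(⌊0.75 · n_blocks⌋ blocks) or testing, so adjacent cells never straddle
the split.  Splitting and fitting are repeated over 25 independent
iterations (seeds spawned from one master seed via `SeedSequence`), which
yields a per-cell ensemble of baseline predictions for uncertainty
quantification.  Bins with fewer than 50 training rows in an iteration are
skipped there with a warning; the threshold is configurable.

## Scenarios

Seven scenario families — N, P, K, machinery, pesticide (all four groups
together), all fertilizers, all inputs — each at 25/50/75 % severity, plus
a control with every shockable input set to zero.  A shock multiplies the
shocked covariate columns by (1 − severity); non-mineral fertilizer,
labour, irrigation and the soil properties are frozen in every scenario.
Scenario predictions reuse the fitted forests of each iteration — no
refitting under shock — so a scenario yield is the model's reading of
baseline cells in the same climate bin whose input use resembles the
shocked cell's.  A severity-0 scenario is bit-identical to the baseline.

## Aggregation and evaluation

Production is yield × harvested area per cell; changes are reported per
cell, per climate bin (share of bin area, harvested-area-weighted by
default, where yield drops by at least 10 %), per country and globally,
with increases and decreases both counted.  Model skill is Nash–Sutcliffe
efficiency on held-out cells (classes: very good > 0.75, good 0.65–0.75).
The headline per-bin NSE pools the held-out predictions of all iterations:
at desk-scale grids a single iteration's per-bin test set is ~20 spatially
clustered cells, whose tiny, unstable variance makes the per-iteration NSE
denominator close to meaningless; the iteration-mean NSE is exported
alongside (`nse_iter_mean`) for comparability.  Baseline country-mean
yields are validated against the generator's noise-free yields with a
production-weighted R² (the R² of a weighted least-squares fit with
intercept).  Prediction uncertainty is the per-cell coefficient of
variation (sample sd / mean) of baseline predictions across iterations.

## The synthetic world

The generator emulates, on a configurable lat/lon grid (default 50 × 50 at
0.5°), the features of the real data the method relies on, with defaults
chosen so that the world is a fair but passable test bed for the method:

* **Climate.** Daily temperature = latitudinal mean + a fixed fine-scale
  relief term (elevation-like, ±3 °C at ~1-cell scale) + seasonal cosine +
  daily weather noise.  Precipitation combines a west–east gradient,
  regional structure and fine-scale orographic variation; daily values are
  exponential weights normalized to each year's total.  The fine-scale
  terms matter: they interleave climate strata at sub-degree scale, as
  topography does on real cropland, so each climate bin spans many
  one-degree blocks instead of forming one contiguous band — without this,
  block-held-out evaluation degenerates into pure spatial extrapolation at
  this grid size.
* **Inputs.** A single "intensification" latent field (regional + local
  smoothed noise, rank-transformed to uniform on [0, 1]) drives N/P/K and,
  partially, pesticide rates, making all purchased inputs positively
  correlated — as in real data, where intensive regions use more of
  everything.  The rank transform guarantees a wide spread of input levels
  inside every climate bin, so the yield signal is identifiable everywhere.
  Pesticide use additionally follows its own smooth "pest pressure" field.
  Machinery and labour are drawn per country (contiguous rectangular
  blocks; continents group countries) from a common development latent.
  Irrigation concentrates where it is dry and intensive; soils are smooth
  positive fields.
* **Yield response.** Mitscherlich-type saturating factors per shockable
  input, `f_i(x) = floor_i + (1 − floor_i)(1 − e^{−k_i x b_i})`, multiplied
  together with a climatic potential (Gaussian response surface in GDD ×
  precipitation), monotone soil and labour multipliers, and lognormal
  multiplicative noise with CV 0.10.  `b_i = 1 + γ · irrigation/100`
  (γ = 0.3) for the mineral fertilizers only — irrigation boosts fertilizer
  efficiency.  Non-mineral fertilizer contributes half-weight mineral-N
  equivalents.  Response floors (N 0.15, P 0.25, K 0.30, machinery 0.75,
  pesticide groups 0.90–0.96) encode that yields do not collapse to zero
  without purchased inputs and that fertilizers dominate the input
  response while pesticides and machinery are secondary.  The realized
  noise field is stored, so counterfactual truths are noise-matched:
  re-evaluating the response with shocked covariates and the same noise
  gives an exact per-cell ground truth, and severity 0 reproduces the
  baseline bit-for-bit.

What the generator does **not** emulate: real geography and actual crop
calendars, reporting artefacts of real input data (county-level constancy,
the ~30 unique fertilizer values per region), measurement error that is
spatially correlated, price and adaptation behaviour.  Passing the
recovery tests therefore shows that the pipeline's machinery is correct
and that the method recovers a known response under favourable but
structurally realistic conditions — not that real-world estimates carry
the same accuracy.

## Numerical choices and known limitations

* Quantile edges use linear interpolation between order statistics; bin
  ties break by cell index; block counts use the floor rule with both
  sides forced non-empty.
* Skipped bins predict NaN and are excluded from aggregation for the cells
  they cover; aggregation masks propagate through production and change
  tables.
* Degenerate inputs fail loudly: constant climatologies, all-nodata
  layers, concentrated validation weights, constant observations in NSE.
* **Attribution under collinearity.** Because purchased inputs co-vary,
  the forests spread the shared intensification signal across correlated
  covariates.  Single-family shock predictions (e.g. pesticide-only) can
  therefore substantially exceed the generator's true single-input effect,
  while combined-shock predictions track the truth closely (cellwise
  correlation ≳ 0.9 on default runs).  This is a property of the method on
  correlated inputs, not a bug; interpret single-input scenarios as "what
  the model associates with this input's gradient", not as causal
  single-input effects.
* Random forests cannot extrapolate below the training yield range, which
  is why the all-inputs-zero control retains an appreciable predicted
  yield — a robustness probe, reproduced here by design.
* Problem sizes in the shipped tests and the acceptance script (default
  50 × 50 world, 200 trees, 10 iterations) are the package's desk-scale
  defaults; all of them scale up by configuration.
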