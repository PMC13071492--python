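# Methods

`croplandn2o` estimates fertilization-induced nitrous-oxide nitrogen
(N₂O-N) losses from croplands and projects how manure substitution
policies change them. The pipeline has five scientific stages —
observation curation, flux modelling, gridded upscaling, factorial
driver attribution and scenario projection — plus a synthetic-data
generator that provides a known ground truth for testing all of them.

## Response variable and curation

The unit of observation is a paired chamber experiment: a zero-N
reference plot and an N-fertilized plot, each with a cumulative
N₂O-N flux (kg N₂O-N ha⁻¹). The modelled response is the **net
cumulative flux**

    net_flux = flux_treated − flux_control ,

which may be negative (net uptake); negative values are retained, not
clipped, so the model sees uptake cases. The fertilizer-induced
**emission factor** is `EF% = 100 · net_flux / (CheN + ManN)`.

Screening keeps records that (i) are fertilization experiments
(positive N input), (ii) were run under field conditions in the study
domain, and (iii) report both the reference and treated cumulative
fluxes. Each excluded record is counted under the first criterion it
fails, so exclusions plus retentions always equal the input size.

Twelve predictors are used: climate (MAT °C, AAP mm yr⁻¹), soil
(TN, TP g kg⁻¹, Olsen AP mg kg⁻¹, pH, SOM g kg⁻¹, BD g cm⁻³),
N management (CheN, ManN kg N ha⁻¹ and the manure ratio
ManN/(CheN+ManN), the model's handle on N-source interaction), and the
cropping system (paddy vs upland, encoded paddy = 1). The curated
table is split into a 90 % development set and a 10 % independent test
set; the development size is `floor(0.9 n)` so a 2186-record table
yields exactly 1967/219.

## Flux models

Three families are fitted behind one interface: an identity-link
Gaussian linear model (ridge-regularized, penalty grid
{10⁻⁸, 1, 10}), a random forest (500 trees, `max_features` grid
{0.33, 0.6, 1.0}), and stochastic gradient-boosted regression trees
(learning rate {0.01, 0.05, 0.1} × depth {2, 3, 5} × subsample
{0.5, 0.75}, up to 500 trees with early stopping on an internal
validation split). A log1p response transform for the linear family
was considered and rejected: net fluxes below −1 kg ha⁻¹ are
legitimate observations and would leave the transform undefined.

Hyperparameters are chosen by ten-fold cross-validation on the
development set, scored by mean fold RMSE with seed-deterministic fold
assignment; the winner is refit on the full development set. Models
are compared on the independent test set by R², RMSE and MAE, ranked
by highest R² with RMSE, then MAE, then a fixed family order as tie
breaks. R² is the coefficient of determination about the 1:1 line
(1 − SS_res/SS_tot); the squared Pearson correlation is reported
alongside because scatter-plot regressions of observed vs predicted
are sometimes summarized that way.

Diagnostics: relative influence (native impurity-based importance for
tree families, seed-controlled permutation importance otherwise,
normalized to sum to 100 %) and partial dependence. The raw PD value
at grid point *g* is the mean prediction over the development rows
with the variable set to *g* (development set subsampled above 5000
rows with a fixed seed); curves are LOESS-smoothed with default span
0.75 and degree 1. Grid points outside the training range are
evaluated but flagged as extrapolation.

## Upscaling

A fitted model is applied per cell to aligned covariate layers.
Cells are evaluated exactly where cropland area > 0 and total N
input > 0; all other cells are masked, contribute nothing to totals
and are excluded from the flux median/SD. Cell loss is
`flux (kg ha⁻¹) × cropland_area (ha)`, converted to Gg by dividing by
10⁶. The national total is defined as the exact sum of the six
regional totals, which are sums over cells in a fixed row-major order,
so additivity holds to machine precision. The flux summary is the
unweighted median ± SD over evaluated cells; an area-weighted median
is reported alongside because the weighting convention of such
summaries is ambiguous in the literature. Grids are plain aligned
row/col rasters with an explicit cropland-area layer (never derived
from latitude geometry) and a six-region id layer; I/O is NetCDF-3
via the scipy backend. Inputs must be pre-aligned; an alignment
checker rejects shape mismatches rather than resampling.

## Factorial attribution

To attribute the change in national loss between a start year T1 and
end year T2, six simulations are formed. S0 is the T2 grid. Each
subsequent simulation freezes one more driver at its T1 state, in the
fixed order MAT, AAP, total N input, manure ratio, cropland
distribution; S5 is the T1 grid itself. The freeze of total N (S3)
is per cell: `CheN′ = totalN_T1·(1−ratio_T2)`,
`ManN′ = totalN_T1·ratio_T2`, so the T2 source mix is preserved while
the amount reverts. Cells with T1 input but no T2 input have no T2
ratio; they fall back to the T1 ratio and are counted. Per-cell
(rather than national) fixing preserves spatial structure and makes
the subsequent ratio freeze (S4) exact.

The contribution of driver *k* is `Δ_k = total(S_{k−1}) − total(S_k)`;
by construction the five deltas telescope to
`total(S0) − total(S5)` exactly, which `verify_telescoping` checks at
10⁻⁹ Gg. Percentages normalize each delta by the absolute total
change with sign preserved; signed deltas in Gg are the primary
quantity because percentage sign conventions are ambiguous when the
period's net change is small. The deltas depend on the freezing
order; this is inherent to sequential counterfactuals and an optional
reversed-order run can quantify it.

## Scenario engine

A scenario is a national nitrogen budget built from four primitives:
manure-N in excreta (Tg), the manure recycling rate (fraction of
excreted N returned to cropland), the manure-N fertilizer equivalency
MFE (plant-available fraction after storage/processing/spreading
losses), and the national plant-available-N target (Tg):

    total_manure  = excreta × recycling
    avail_manure  = total_manure × MFE
    avail_chem    = target − avail_manure          (must be ≥ 0)
    substitution% = 100 · avail_manure / target

Historical years fix observed chemical-N instead of the target. All
arithmetic is unrounded internally; reporting rounds half-up to two
decimals. The gridded scaling factors divide the *rounded* scenario
and baseline totals because the published parameter table was
evidently computed that way (23.97/4.37 = 5.49, not
23.97/4.3716 = 5.48); with unrounded ratios one scale would differ in
the last printed digit. Two cells of the published table are
internally inconsistent at the last digit under any rounding
convention we could construct (available chemical-N of the
half-recycling scenario prints 25.00 where the primitives give
24.9945 → 24.99, and the 2014 substitution ratio prints 4.40 where
the primitives give 4.4059 → 4.41); the engine reports the computed
values.

Applying a scenario multiplies the baseline-year ManN and CheN layers
by the two national factors (spatially uniform, as the parameter
table specifies), optionally replaces climate and cropland layers by
their 2050 counterparts, leaves soil layers unchanged, and lets the
per-cell manure ratio follow from the scaled layers. Projections are
compared as signed percent changes vs the baseline year and vs the
business-as-usual scenario. Scaled inputs are not capped; a
configurable flag could be added but the published protocol specifies
none.

## Synthetic data generator

The generator defines the study conditions for all tests.

**Observations.** Records are drawn per region (six agro-regions).
Environmental covariates are median-preserving lognormals (normals
for MAT and pH, truncated where physically required), anchored to
regional medians — the most acidic and warmest region at pH 5.2 /
MAT 21.4 °C, the lowest-SOM region at 10.9 g kg⁻¹, the remaining
medians set to realistic regional levels. N inputs are a mixture of
chemical-only, manure-only and mixed fertilization with a
manure-positive fraction of 0.3152, matching the compiled data's
689/2186; rates are lognormal with medians 180 (chemical) and 120
(manure) kg N ha⁻¹.

**True surface.** Net flux is a saturating response to total N
(`fmax = 14 kg ha⁻¹`, half-saturation 450 kg N ha⁻¹) with
multiplicative modifiers: an acidity boost below pH 6, a temperature
sigmoid centred at 20 °C, a saturating SOM factor, a mild
precipitation factor, a linear manure-ratio reduction (−35 % at full
substitution) and a paddy suppression factor (×0.6). It is zero at
zero N input and finite everywhere. Under the default covariate
distribution the chemical-N input dominates the surface's variance,
followed by pH, MAT and SOM; TN, TP, AP and BD do not enter at all
and serve as null features for importance and PD diagnostics.

**Noise.** Treated flux = control + surface × lognormal(σ = 0.27,
mean-corrected) + N(0, 0.3 kg ha⁻¹); the control (background)
flux is lognormal with median 0.8 kg ha⁻¹. The multiplicative term
gives the heteroscedasticity typical of cumulative chamber data and
the additive term permits slightly negative net fluxes. σ was
calibrated once so that CV-tuned boosted trees reach a test R² near
0.77 on the default-size dataset — the signal-to-noise regime of the
real compilation — and then frozen.

**Grids.** Covariate fields are smoothed white noise (separable
Gaussian kernel, default correlation length 2 cells; length 0 gives
independent cells) around the regional medians of a contiguous
six-region partition. Cropland area is lognormal with a configurable
zero-cropland probability (default 20 % of cells). Multi-year series
apply linear-in-time trends to the five attribution drivers only;
drivers with identity trends are bitwise constant across years, and
the first-year grid is independent of the trend specification — the
property the attribution tests rely on.

The generator does **not** emulate: the real covariate joint
distribution (covariates are independent within region), literature
heterogeneity (chamber protocol, study design, measurement error
structure), geodesic cell geometry, or real spatial N-input patterns.
Passing tests therefore demonstrate the correctness of the machinery
and its recovery properties under a known truth, not the accuracy of
any real-world emission estimate.

## Problem sizes and determinism

Default test and acceptance runs use 2186-record tables (the size of
the real compilation), 2000-record noiseless recovery sets, and
8×8–12×12 grids; these sizes keep full recovery experiments
comfortably reproducible on a single CPU while leaving the Monte-Carlo
properties (binomial screening counts, median recovery, importance
ranking over 20 seeded refits) well resolved. Every stochastic stage
takes an explicit seed; identical configuration and seeds give
byte-identical artifacts, which the pipeline manifest checks by
SHA-256.

## Reproducing the real-data results

The headline real-data numbers — a national loss of 243.7 Gg and a
median flux of 1.1 kg ha⁻¹ in 2019, test metrics R² 0.77 / RMSE 3.2 /
MAE 1.3 kg ha⁻¹, the driver contributions of 29.6 % / −7.2 % /
−4.7 % over 2000–2014, and the regional hotspot ranking — cannot be
computed from this repository alone. They require the compiled field
dataset deposited on Zenodo (doi:10.5281/zenodo.19144029) and the
external gridded archives: HaNi chemical/manure N application rates,
HWSD soil properties, TPDC climate layers, and the national cropland
area/type maps. Given those inputs in the documented CSV/NetCDF
schemas, the same pipeline applies unchanged: screen and split the
table, fit and select the model, upscale over the HaNi years,
attribute 2000→2014 and 2014→2019, and run the scenario presets.

## Known limitations

- Importance is impurity-based for tree families and can inflate
  high-cardinality continuous features; permutation importance is
  available for any family as a cross-check.
- Partial dependence averages over the background distribution and is
  misleading under strong covariate dependence; the synthetic
  covariates are independent within region, so the recovery tests do
  not probe that failure mode.
- Sequential counterfactual attribution is order-dependent by
  construction.
- The scenario engine treats national scaling factors as spatially
  uniform and does not model reallocation of manure between regions,
  nutrient caps, or yield feedbacks.
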