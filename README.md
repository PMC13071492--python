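# croplandn2o

Modelling fertilization-induced N₂O-N losses from croplands: from
paired chamber flux observations to national emission totals, driver
attribution and manure-substitution scenarios.

Cropland fertilization is a dominant anthropogenic source of nitrous
oxide, and substituting chemical fertilizer with recycled manure-N
changes both the amount and the composition of nitrogen applied.
This package is for agroecosystem and nutrient-management researchers
who want a tested, reproducible implementation of that full analysis
chain:

1. **Curation** (`obsdata`) — screen field experiments that report
   cumulative N₂O-N fluxes for both a zero-N reference and an N-input
   treatment; compute the net flux `F_net = F_treated − F_control`
   (kg N₂O-N ha⁻¹) and emission factors
   `EF% = 100·F_net/(CheN+ManN)`; derive features and split 90/10
   into development and test sets.
2. **Modelling** (`mlcore`) — fit a generalized linear model, a random
   forest and boosted regression trees on 12 predictors (MAT, AAP,
   TN, TP, AP, pH, SOM, BD, CheN, ManN, manure ratio, crop type),
   tune by ten-fold CV (minimum mean fold RMSE), select by test-set
   R²/RMSE/MAE, and interrogate the winner with relative influence
   and LOESS-smoothed partial dependence plots.
3. **Upscaling** (`upscale`) — apply the model per cell to aligned
   covariate rasters and aggregate
   `loss = flux × cropland area` to six-region and national totals in
   Gg N₂O-N.
4. **Attribution** (`attribution`) — sequential factorial
   counterfactuals: freeze MAT, AAP, total N input, manure ratio and
   cropland distribution one at a time at their start-year state;
   successive differences of the simulation totals S0…S5 assign the
   change to each driver and telescope exactly to
   `total(S0) − total(S5)`.
5. **Scenarios** (`scenarios`) — national nitrogen budgets
   `available manure-N = excreta × recycling rate × MFE` under a
   fixed plant-available-N target, translated into uniform gridded
   scaling factors for manure-N and chemical-N maps and projected to
   2050 losses.

A synthetic-data generator (`synthgen`) with a known nonlinear
response surface, regional covariate distributions and per-driver
grid trends makes every stage testable end to end, and a pipeline
module (`pipeline` + a thin `croplandn2o` CLI) ties the stages into
one seeded, checksummed run.

## Worked example

`examples/02_fit_and_diagnose.py` generates a 2186-record synthetic
compilation, tunes the three families and inspects the winner:

```
generalized_linear R2=0.715 RMSE=1.93 MAE=1.38 kg/ha
random_forest      R2=0.771 RMSE=1.73 MAE=1.21 kg/ha
boosted_trees      R2=0.783 RMSE=1.68 MAE=1.18 kg/ha
selected model    : boosted_trees {'learning_rate': 0.05, 'max_depth': 3, 'subsample': 0.75}
top influences (%):
CheN    41.7
pH      21.6
crop    11.8
MAT      8.2
AAP      5.5
PDP(CheN) rises +11.81 kg/ha across the observed range
```

The boosted family wins on the nonlinear surface (test R² 0.78 on 219
held-out records, at the generator's calibrated signal-to-noise), and
chemical-N input dominates the relative influence, as the generating
surface dictates. `examples/05_scenarios.py` reconstructs the
scenario nitrogen budgets and projects losses on a synthetic baseline
grid:

```
FMR        loss   67.30 Gg | vs 2019   +8.5% | vs BAU +1.2% | scales manure x5.49 chem x0.93
FMR_MFE50  loss   62.31 Gg | vs 2019   +0.4% | vs BAU -6.3% | scales manure x5.49 chem x0.72
```

Full manure recycling at 30 % fertilizer equivalency *raises* losses
(more total N must be applied to hold plant-available N constant);
raising MFE to 50 % reverses that. The remaining examples cover
generation/curation, upscaling and driver attribution.

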