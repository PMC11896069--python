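# miombo-aba

Area-based UAS-lidar forest inventory for Miombo woodlands.

Forest managers in the Miombo ecoregion need plot-level estimates of
aboveground biomass (AGB), basal area (BA), mean stem diameter (DBH) and
volume (Vol) at a precision that satellite products do not reach, and at a
cost that crewed airborne lidar does not allow. The area-based approach
(ABA) fills that gap: canopy statistics computed from a drone-borne lidar
point cloud over each field plot are regressed against the attributes
measured on the ground, and the fitted models predict the attributes
wall-to-wall. This package implements the full ABA chain for that setting
— and, because such studies rarely publish their raw data, it also ships a
synthetic wet-Miombo stand and lidar simulator with exact ground truth, so
the entire chain is testable and reproducible from nothing.

## What it computes

For field plot *i* with attribute *y&#8329;* (e.g. AGB in Mg/ha, from tree-level
allometry AGB = a·(ρD²H)^b, BA = π(D/200)², Vol = BA·H·f) and lidar metric
vector **x**&#8329; (height percentiles H1…H99, height-range densities D1…D9,
canopy cover CC, gap fraction GF, LAI, moment statistics), the model is

    ln y_i = β₀ + βᵀ x_i + ε_i,   ε_i ~ N(0, σ²)

fitted by OLS after a collinearity screen (|r| > 0.85) and exhaustive
best-subsets search ranked by small-sample AICc. Predictions
back-transform with the lognormal bias correction ŷ = exp(β̂₀ + β̂ᵀx)·
exp(MSE/2). Accuracy is reported as RMSE, Bias, rRMSE = 100·RMSE/ȳ and
rBias = 100·Bias/ȳ from pooled 10-fold cross-validation, and model
transferability is assessed by applying one site's model to the other
site's plots without refitting.

The pipeline stages (each usable as a library module or CLI command):

| stage | module | what it does |
|---|---|---|
| simulate | `synthforest` | terrain, tree lists, triple-echo clouds + truth |
| preprocess | `pointcloud` | outlier removal, progressive-TIN ground filter, IDW DTM, height normalization |
| metrics | `metrics` | plot/grid clipping, canopy metric vocabulary (2 m threshold) |
| field | `fieldcalc` | wood density lookup, tree allometry, per-ha plot attributes |
| select/fit | `modelsel` | collinearity screen, best subsets, ln-scale OLS + bias correction |
| evaluate/transfer | `evalstats` | Eq-style error statistics, pooled k-fold CV, cross-site transfer |
| run | `pipeline`/`cli` | one-command two-site study with seeded reproducibility |

## Worked example

Run the full synthetic two-site study (16 plots per site, 25 pulses/m²)
and print the cross-validated accuracy of the site-specific, combined and
transferred models:

```python
from miombo_aba.pipeline import run_synthetic_study

res = run_synthetic_study(seed=1, n_plots=16, pulse_density=25)
print(res.cv_stats[res.cv_stats.response == "AGB"].round(2).to_string(index=False))
print(res.transfer_stats[res.transfer_stats.response == "AGB"].round(2).to_string(index=False))
```

```
    site response  n  RMSE  rRMSE_pct  Bias  rBias_pct   R2
 Mwekera      AGB 16 14.93       7.25  1.92       0.93 0.92
 Miengwe      AGB 16  7.52       6.84 -0.13      -0.12 0.95
combined      AGB 32 14.29       9.05 -0.12      -0.08 0.95
   site   model response  n  RMSE  rRMSE_pct  Bias  rBias_pct   R2
Mwekera Miengwe      AGB 16 28.09      13.64 17.02       8.26 0.86
Miengwe Mwekera      AGB 16 18.69      17.00 13.14      11.95 0.86
```

Reading: with local training data, cross-validated AGB errors sit around
7 % of the plot mean with sub-1 % bias; pooling the two sites costs a
little accuracy (9 %). Carrying a model across sites without local
calibration roughly doubles the relative error and introduces a large
systematic bias (8–12 %), because the two simulated sites (like the two
real forest types they are patterned on) differ in species mixture and
height–diameter allometry. The same study can be run from the shell:

```bash
miombo-aba run --seed 1 --out report/
miombo-aba simulate --site mwekera --n-plots 4 --pulse-density 50 --out sim/
miombo-aba preprocess sim/cloud_Mwekera-01.csv --out norm.csv --dtm-out dtm.asc
```

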