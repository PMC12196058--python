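# granupls

PLS chemometrics for fluidized-bed granulation (FBG) process analytics.

Inline control of a fluid-bed granulator hinges on two critical quality
attributes measured while the batch runs: the granule size distribution
(volumetric percentiles Dv10–Dv90, µm, from an in-line imaging probe)
and the bed moisture (loss on drying, LOD %, referenced by a gravimetric
analyzer).  A 256-channel NIR probe (1081–2122 nm) sees both — moisture
through the water absorption bands near 1450 and 1934 nm, particle size
through scatter-driven baseline changes — and the granulator's ~17
process parameters (airflow, atomizing pressure, temperatures, PHT
pressure/humidity/temperature air probes, runtime) carry complementary
information about how the batch got where it is.

`granupls` implements the full chemometric workflow for such campaigns:

* **PLS1 regression** (`granupls.pls`) — NIPALS with coefficient paths,
  Y = XB + E, predictors autoscaled on training statistics, the response
  never scaled; leave-one-out, interleaved (`sequential_k`) and
  contiguous-block cross-validation; latent-variable selection by RMSECV
  minimum with a parsimony tie-break; RMSEC/RMSECV/RMSEP/R² plus the
  standardized prediction ratios RPD = SD/RMSEP, RER = range/RMSEP,
  PRL = RMSEP/lab error and RPIQ = (Q3−Q1)/RMSEP.
* **Batch outlier screening** (`granupls.outliers`) — PCA of the SNV
  spectra with a modified Kaiser rule (Kaiser score = 256 × explained
  variance fraction, tempered by a scree condition), Mahalanobis
  distances in PC-score space (flagging threshold 3), SIMCA-style
  one-tailed t p-values on squared distances, and **BBE-PLS**: backward
  batch elimination on the NIR→LOD model, removing the batch whose
  exclusion most lowers RMSECV while a one-tailed equal-variance t-test
  on squared CV residuals stays significant (p < 0.1).
* **UVE-PLS variable selection** (`granupls.uve`) — jackknife coefficient
  stabilities against appended noise variables, with a 20-point cutoff
  grid searched by refit RMSECV.
* **Modeling approaches** (`granupls.evaluate`) — within-batch endpoint
  prediction (train on the first 90% of a batch, predict the last 10%;
  `ma1`, and `ma1add` for the last half of the terminal zero-spray run)
  and across-batch prediction with whole-batch folds (9→3 `ma2a`,
  leave-one-batch-out `ma2b`, 8→4 `ma2c`), each comparing NIR-only,
  parameters-only and merged (256 + 17 = 273 predictors) models, with
  paired one-tailed t-tests and |coefficient| importance tables.
* **Synthetic campaigns** (`granupls.simulate`) — a seeded generator
  producing 14-batch campaigns with spray→drying phase structure,
  saturating parameter-driven size growth, moisture dynamics,
  size/moisture-dependent spectra with drift and scatter, sparse LOD
  points, and injectable extreme-settings outlier batches, so the whole
  pipeline is testable without plant data.

## Worked example

```bash
python examples/size_prediction.py
```

```
within-batch endpoint (last 10%):
      nir: mean external RMSEP   17.1 um, mean RPD  6.74
     pars: mean external RMSEP   16.1 um, mean RPD  6.03
   merged: mean external RMSEP   11.0 um, mean RPD  7.03
  paired one-tailed t-test (merged < nir): p = 0.0931

leave-one-batch-out:
      nir: mean external RMSEP   16.3 um, mean RPD  4.15
     pars: mean external RMSEP   20.9 um, mean RPD  3.37
   merged: mean external RMSEP   14.4 um, mean RPD  4.76
  paired one-tailed t-test (merged < nir): p = 0.0152
```

Each line is the mean root-mean-squared error on rows the model never
saw — the batch endpoint for the first scheme, entire held-out batches
for the second — and the residual predictive deviation RPD
(reference-population SD divided by RMSEP; above 1.75 is usable, above
3 excellent).  The merged model beats both single-block models on both
schemes: the spectra read the attained size only through a drifting
scatter baseline, while airflow and atomizing pressure modulate the
growth itself.  Other entry points: `examples/outlier_screening.py`,
`examples/variable_selection.py`, `examples/moisture_calibration.py`,
`examples/simulate_campaign.py`, or the `granupls` CLI
(`simulate`/`screen`/`uve`/`evaluate`/`run`).

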