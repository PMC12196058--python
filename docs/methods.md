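# Methods

## The problem

In fluid-bed granulation a powder bed is fluidized by heated air while a
binder solution is sprayed onto it (spray phase); spraying then stops
and the wet granules dry in the same chamber (drying phase).  Product
quality is summarized by the granule-size percentiles Dv10–Dv90 (µm)
and the bed moisture (loss on drying, LOD %).  Both can be followed
inline: an imaging probe returns sizes every few seconds, a 256-channel
NIR probe (1081–2122 nm) returns absorbance spectra, and the unit logs
~17 process parameters (airflow rate, atomizing pressure, inlet/exhaust
temperatures, plenum and exhaust pressures, PHT
pressure–humidity–temperature air probes at inlet and outlet, product
temperature, filter differential pressure, runtime).  The package asks
the calibration-transfer questions that matter for control: how well can
the *endpoint* of a batch be predicted from its own earlier data (MA 1),
how well can a *whole unseen batch* be predicted from other batches
(MA 2), and does merging the process parameters with the spectra
(256 + 17 = 273 predictors) improve on spectra alone?

## Models and procedures

**PLS1.** Y = XB + E fit by NIPALS; for a single response the inner loop
is non-iterative, so fits are deterministic.  Predictors are autoscaled
with training-row means and sample SDs (ddof = 1 throughout); the
response is centered, never scaled, so errors are in µm or %LOD.  One
deflation pass yields the coefficient path over 1..max_lv components,
so cross-validation scores every component count from a single fit per
fold.  At full rank the PLS solution coincides with least squares; the
test suite checks this against the pseudoinverse and checks predictions
against scikit-learn's PLSRegression (the independent reference), while
the package's own engine is used everywhere else.

**Cross-validation.**  `loo` (one row per fold), `sequential_k` (row i →
fold i mod k; interleaved, hence optimistic on autocorrelated series)
and `block_k` (contiguous blocks, remainder on the leading blocks).  The
component count is the smallest one attaining the RMSECV minimum within
1e−12 (parsimony tie-break); the default cap is 15 in the evaluation
drivers, 10 for the LOD models (moisture needs few factors).

**Preprocessing.**  SNV is applied row-wise to spectra only (center,
divide by sample SD); autoscaling is column-wise on the assembled
predictor block, learned on training rows only.  SNV before merging with
the parameter block, because scatter correction is a per-spectrum
operation and must not see the parameters.  The spray-rate moving
average (seven points, centered, truncated at the edges) enters only
when the 18-predictor option is selected.

**Outlier screening.**  The LOD-bearing rows' SNV spectra are the
screening population.  PCA (all columns autoscaled) gives Kaiser scores
= 256 × explained-variance fraction; the PC count is the largest
component that passes the score threshold (default 1) *and* sits above a
scree elbow (its log-eigenvalue drop exceeds the median of the later
drops) — the plain threshold rule is known to overestimate.  Mahalanobis
distances are computed in the retained PC-score space with the scores'
covariance; rows above 3 are flagged.  SIMCA membership p-values use a
one-tailed t predictive interval on squared distances, with the
below-threshold rows as the non-outlier reference; a batch's p-value is
the median over its rows.  BBE-PLS repeatedly removes the batch whose
exclusion most lowers the LOO RMSECV of the NIR→LOD model, gated at
p < 0.1 by a one-tailed equal-variance two-sample t-test comparing the
full model's squared CV residuals with the reduced model's; the
component count is re-selected every evaluation.  The two residual
samples overlap heavily, which makes the test conservative on clean
campaigns — desirable for specificity.  The alternative pairing (only
the candidate batch's residuals against the rest) is a one-line change
in `_squared_cv_residuals`/`bbe_pls` but is more exposed to
selection bias.

**UVE-PLS.**  As many uniform noise columns as real predictors are
appended (amplitude 1e−10; the stability ratio mean/SD over CV submodels
is scale-free, so amplitude is irrelevant after autoscaling).  Cutoffs:
20 linearly spaced values from the smallest |stability| to the
(n_lv + 2)-th largest, with 0 prepended so the full model is always a
candidate; each cutoff's retained set is refit and scored by RMSECV; the
minimum wins, smaller cutoff on ties.  The alternative grid top (the
overall maximum |stability|) is selectable via `cutoff_strategy="top"`.

**Splits.**  MA 1: external test = last ⌊n/10⌋ rows (2644 rows → 264);
within the remaining head, every 10th row (1-based) is internal test.
MA 1-add: external = last half of the terminal zero-spray run.  MA 2
folds partition whole batches in campaign order (3, 1 or 4 test batches
per fold).  The LOD hold-out pools LOD rows in order and reserves every
5th (150 rows → 120/30).  No test row ever contributes to scaling,
component selection or coefficients of the model that predicts it.

**Metrics.**  RPD = SD/RMSEP, RER = range/RMSEP, PRL = RMSEP/lab error,
RPIQ = (Q3−Q1)/RMSEP, with reference statistics taken over the pooled
non-outlier population; the lab error is the SD of per-batch endpoint
sizes.  Comparisons against printed reference values use decimal
half-up rounding at the printed precision.

## The synthetic generator

`granupls.simulate` emulates the *structure* of a granulation campaign,
not its physics.  Per batch: setpoints are drawn per batch (airflow
18.7–36.0 m³/h — the one published operating window — atomizing 1–3 bar,
inlet air 50–75 °C, spray rate 18–22 g/min), trajectories are setpoint
plus stationary AR(1) noise (ρ = 0.97).  Batch duration is fixed at
5000 s, so the row budget only sets the sampling cadence and endpoint
sizes are independent of it.  Moisture rises toward a wetting-dominated
equilibrium (~8%, only weakly spray-dependent) and decays during drying,
faster at high airflow.  Dv50 grows toward a plateau
`140 + 8·spray·g(airflow, atomization)` µm, where `g` rises linearly
with airflow and falls with atomizing pressure (sensitivities 0.5 each,
clipped positive); drying causes mild attrition.  Dv10–Dv90 are fixed
span multiples (0.45/0.7/1/1.4/1.9) of Dv50.  Spectra = size-dependent
baseline (offset + slope) + three fixed solid-component Gaussian bands +
water bands at 1450/1934 nm scaled by moisture + multiplicative scatter
+ AR(1) offset/slope drift + white noise.  Two deliberate imperfections
make the spectral size channel realistically imperfect: a multiplicative
AR(1) size-reading error (the optical size response depends on bed
packing, not size alone) and a consolidation shift — below ~1.2%
moisture the dry bed's optical size response is biased by +8% — so the
very endpoint regime is read with a bias the wetter training data lack.
LOD values are the moisture latent plus 0.3% measurement error at ~12
sampled rows per batch.

Outlier injection shifts six process parameters by ±magnitude (default
8) campaign SDs and corrupts the spectra three ways: a signed baseline
tilt/curvature (PC-space separation), a mode-independent attenuation of
the water bands (a fouled window weakens the moisture signal whichever
way the parameters are extreme), and a wavelength-registration failure —
a systematic channel shift in the mode's direction plus per-row jitter,
seeded by the batch id so injection stays deterministic.  The
attenuation and mis-registration break the batch's NIR→moisture
relationship in a way no extra latent direction can repair (a purely
additive fixed-shape distortion would simply be absorbed by the model),
which is what makes the batch a genuine calibration outlier.  In
campaigns the corrupted batches alternate high/low extremes, emulating
a pair run at mutually opposite settings.

What the generator does **not** emulate: granulation physics (population
balances, droplet breakup), nonstationary instrument effects (window
fouling trends), API chemistry, or irregular acquisition. Passing
recovery tests on these campaigns therefore demonstrates that the
procedures detect the statistical signatures they target, not that any
particular plant dataset will behave identically.

## Problem sizes

The simulated studies run at 12–14 batches with 200–360 rows per batch
(a coarser sampling of the same 5000 s batch than the ~2000–3000 rows a
real campaign yields) and 8–20 seeded replicates per property; LOD-based
screening always uses ~12 LOD points per batch, matching the sparse
reference sampling of a real campaign.  These sizes were chosen so the
statistical properties under test (recovery rates, win rates, CV-scheme
ordering) are stable while a full run of the suite stays convenient.

## Known limitations and deliberate choices

* The null case of the merged-vs-NIR comparison (growth coupling
  switched off) is *not* a regime where the parameter block is useless:
  runtime and the moisture-linked temperatures/humidities still anchor
  the batch's position in its trajectory, so the merged model retains a
  small but systematic advantage over NIR-only even without any
  parameter-driven growth.  This mirrors the role of runtime and
  process covariates in real campaigns; the package reports the
  comparison rather than forcing equivalence.
* Block-CV error estimates sit above sequential-CV estimates on these
  autocorrelated batches and approximate the external endpoint error
  only roughly; block-CV component selection is erratic (too few or too
  many factors), so the evaluation drivers default to sequential CV for
  selection — the same trade-off a practitioner faces.
* BBE-PLS's t-test saturates when a single batch dominates the residual
  variance; the injected outliers are therefore strong by design, and
  marginally corrupted batches may survive screening.
* PCA sign convention: each loading's largest-magnitude entry is made
  positive, so score plots are reproducible across runs and platforms.
* The 17th canonical process parameter is the PHT inlet temperature;
  the optional 18th is the smoothed spray rate.
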