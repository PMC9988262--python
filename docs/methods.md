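# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and what the test suite does and does not establish.

## Brain-age model

Each unimodal model is a Gaussian-process regression of chronological age on
standardized features with a rational-quadratic covariance

k(x, x′) = s² · (1 + ‖x − x′‖² / (2αℓ²))^(−α),

a constant prior mean (the training-age mean; targets are internally scaled
to unit variance, predictions rescaled to years), and i.i.d. observation
noise with standard deviation σ. The rational-quadratic kernel is a scale
mixture of squared exponentials; as the mixture exponent α → ∞ it
degenerates to a single squared exponential, and the marginal-likelihood
optimizer frequently runs α to its upper bound on strongly age-dominated
feature sets. That is a flat direction of the likelihood, not a fitting
failure, and is left as-is.

**Noise tuning.** σ is selected over [10⁻⁴, 10·SD(age)] years. The default
strategy is a deterministic seeded log-spaced grid of 100 candidates scored
by 5-fold inner-CV RMSE; a seeded log-uniform random search is available as
a config switch. During the search the kernel hyperparameters are pinned to
median-distance heuristics and each training fold's kernel eigendecomposition
is reused across all candidates, so the whole budget costs a handful of
O(n³) factorizations. σ is chosen once per model and reused for every later
application of that model (cross-validation folds, held-out prediction);
the remaining hyperparameters (s², ℓ, α) are refit by marginal likelihood
within each training fold.

**Performance metrics.** r, R², MAE and RMSE are computed once on the
out-of-fold predictions merged across the 10 folds — not averaged over
folds; the two definitions genuinely differ and a test pins the merged one.
R² is 1 − SS_res/SS_tot rather than r²: with biased predictors the
proportion of variance explained can fall below the squared correlation.
Folds are stratified by age decile and seeded.

**Stacking.** The multimodal model trains a second-level GP on the two
first-level *out-of-fold* age predictions (leakage-safe stacking; whether
the original analysis used in-sample or out-of-fold first-level predictions
is not stated, and out-of-fold is standard practice). Second-level inputs
are left in years rather than re-standardized: both inputs share units, and
standardizing would inflate an uninformative modality's prediction noise to
unit scale and distort the kernel metric. At apply time the first-level
models are refit on the full training set.

**Shuffled-FC null.** The stacking gain is referenced against a permutation
null: each of (by default) 1000 resamples permutes every FC feature column
independently across participants, retrains the FC model, stacks it with the
unchanged structural model, and records the stacked CV R². Resample fits pin
the kernel hyperparameters and σ to the observed models' values and refit
only the dual coefficients — the permuted features cannot justify
re-tuning, and this keeps 199-resample nulls to seconds. The p-value uses
the add-one convention, p = (1 + #{R²_null ≥ R²_obs}) / (B + 1).

## ComBat harmonization

Parametric empirical-Bayes location-scale harmonization: per feature, a
covariate fit (age by default) and pooled variance standardize the data;
per-batch location γ and scale δ² estimates are shrunk toward batch-level
normal / inverse-gamma moment-matched priors by the usual fixed-point
iteration, run to relative tolerance 1e-6 (max 500 iterations; typical
tables converge in ~4). Single-batch input degenerates to a warned
pass-through so partial cohorts remain analyzable. The default protocol
fits harmonization on the union of training and analysis tables per
modality, matching the all-data-harmonized design this analysis mirrors; a
fit-on-train/apply-to-test flag exposes the leakage-safe alternative. Which
biological covariates the original analysis protected is unstated; age as a
linear term is the default here and group indicators can be added by the
caller. The implementation reproduces Bioconductor `sva::ComBat` to < 1e-6
on two-batch tables (sva stops its EB iteration at 1e-4, so the comparison
fixture uses enough features that both implementations sit well inside both
tolerances).

## BAG inference

BAG = predicted − chronological age, so positive values mean an
older-appearing brain. (The source analysis's Methods wording reverses the
order, but its Results — "BAG was 2.17 years older in CI" with positive
coefficients — require this sign; it is fixed here and documented.) Because
regression-to-the-mean makes raw BAG anticorrelated with age, age enters
every statistical test as a covariate; age-residualized BAG (OLS residuals
of BAG on age within a reference sample, the pooled analysis set by
default) is used for group contrasts and plots. Model performance is always
evaluated on *uncorrected* predictions.

Two regression layouts are exposed, because they answer different questions:

* the additive model (`fit_bag_model`): BAG on a CDR>0 indicator, an
  amyloid-positivity indicator, age, sex, education, and mean FD for
  FC-containing models — the published-table layout;
* the group-dummy model (`fit_group_shift_model`): BAG on group
  (CN/A−/CN/A+/CI) with the same covariates. When an effect is planted *per
  group*, this is the estimand-matched recovery model: the additive layout
  splits a group shift across two correlated indicators (90% of CI
  participants are amyloid-positive) and its coefficients are not the group
  shifts.

Effect sizes are partial η²; for 1-df terms η_p² = t²/(t² + df_resid),
which equals the SS-decomposition definition (tested). Pairwise group
contrasts use Welch t (robust default; Levene's statistic is reported
alongside) with Benjamini–Hochberg correction over the three contrasts
within one model. Williams's test compares dependent age-prediction
correlations sharing the age variable. Continuous biomarker models use
treatment coding with the lowest-severity group present as reference,
exclude CN/A− from continuous-amyloid models (their amyloid range is
restricted by definition), log-transform CSF pTau/Aβ40, and report
per-group simple slopes via linear contrasts.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the imaging physics. Per participant, two latent "effective brain ages"

eff_m = age + shift_m(group) + ε_m,  m ∈ {FC, S},

drive all features of modality m. Planted shifts default to the effects the
analysis is designed to detect: −1.64 y (FC, CN/A+), +2.17 y (FC, CI),
+5.10 y (S, CI). The latent dispersions ε are bivariate normal with SDs of
8 y (FC) and 5 y (S) and correlation 0.1 (the within-person coupling of the
two modalities' aging is not established; the observed BAG correlation in
comparable cohorts is r ≈ 0.10–0.13, and 0.1 is exposed as a parameter
rather than a mechanism).

*Choosing the dispersions.* Two desiderata conflict. Larger dispersion
reproduces the published prediction accuracies (R² ≈ 0.68 FC / 0.81 S), but
the conditional mean E[age | eff] has slope Var(age)/(Var(age)+σ_lat²), so
any model predicting age from these features attenuates planted shifts by
that factor and adds per-seed noise σ_lat·√(2/n_group) to shift estimates.
Requiring the planted ±1.6–5.1 y shifts to be recoverable with |bias| < 1 y
and stable signs at n = 150/group forces sensitivity ≥ ~0.8 and per-seed SE
≤ ~0.9 y, i.e. the dispersions used. The cost is optimistic accuracy
(R² ≈ 0.86 FC / 0.95 S at desk scale); the recovered shifts remain mildly
attenuated (e.g. +5.10 → ≈ +4.4 y averaged over seeds), which is the
expected conditional-mean shrinkage, not an estimation bug.

FC edges mix a lifespan-wide linear trend with smooth tanh ramps whose
centers and widths vary per edge, on a random 30% of edges with
heterogeneous signs — edges change at different life stages but none
saturates completely, so sensitivity to effective age never vanishes on the
adult range. Structural features (68 cortical thickness, 33 subcortical
volumes) decline monotonically with structural effective age at
feature-specific rates. Site effects are per-batch location shifts (scaled
to each feature's noise SD) and log-normal scale factors on the residual
noise, matching the ComBat generative model. A mean-FD confound feeds 20%
of FC edges. Amyloid and tau biomarkers, CSF ratios and the cognitive
composite couple to the structural effective-age gap within CI only
(0.79 centiloid/y, 0.02 SUVR/y, −0.03 z/y); tracer SUVRs derive from
centiloid through synthetic linear maps that place the published positivity
cutoffs at ~24 centiloid — published centiloid conversion coefficients are
out of scope, only the ordering/cutoff behaviour matters downstream.
Demographics (group age means/SDs, sex and education distributions, CDR
staging, biomarker availability) follow the published cohort's summary
table; ~90% of CI participants are amyloid-positive (the summary table's
amyloid row for CI reflects measure availability, not status).

*What passing tests do not show.* The generator has no spatial structure,
no non-AD pathology, no longitudinal dynamics, no scanner physics, and its
feature-age relationships are smooth by construction; recovery results
certify the pipeline's statistical machinery, not performance on real MRI.

## Problem sizes and determinism

All randomness flows through integer seeds (cohort seed; model seeds for
fold assignment and searches); identical seeds give byte-identical
artifacts. Desk scale — 390 training + 450 analysis participants, 50 ROIs
(1,225 edges), 101 structural features — was chosen so a full pipeline run
takes ~10 s: the recovery suite runs 20 seeds at this scale, the
permutation-null checks use 199 resamples (one full-scale run plus a
20-seed calibration at a reduced cohort of 150 training participants and 20
ROIs with the FC age signal switched off), and Monte-Carlo calibrations use
2000 (Williams) and 200 (regression-term) replicates.

## Known limitations

* The GP saturates outside the training age range; CI participants with
  structural effective ages beyond ~89 y are predicted at the boundary,
  contributing to the (documented) shift attenuation.
* Bayesian optimization for σ is not implemented; the seeded grid matches
  its search space and budget and is deterministic.
* The non-parametric ComBat variant and longitudinal harmonization are out
  of scope.
* `biomarker_association` assumes complete covariates within the outcome's
  available subsample; no imputation is attempted.
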