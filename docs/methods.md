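# Methods

## Overview

`habitomics` implements a subregion ("habitat") radiomics analysis for
predicting microsatellite instability (MSI) of rectal tumors from four
co-registered MRI sequences (T2WI, T1WI, DWI, CE-T1WI), together with a
synthetic phantom cohort generator that supplies a known ground truth
for every stage.  The pipeline is:

1. **Standardization** — N4 bias-field correction (SimpleITK), z-score
   intensity normalization, isotropic B-spline resampling to 1×1×1 mm,
   and fixed-bin-count discretization to 32 gray levels over the tumor
   mask.  The order is fixed and enforced.
2. **Habitat map** — fuzzy c-means (FCM) over the per-voxel 4-vector of
   z-scored intensities into 10 preliminary subregions; a 368-column
   secondary signature (18 first-order + 74 texture features × 4
   sequences) per preliminary cluster; column standardization and PCA
   keeping ≥ 85 % of the variance; merging of the preliminary clusters
   by a variational Bayesian Gaussian mixture whose effective component
   count V adapts per patient (1 ≤ V ≤ 10).  The final map is always a
   coarsening of the FCM partition.
3. **Signatures** — 424 features per region (18 first-order, 14 shape,
   74 texture, × 4 sequences) for every final subregion and for the
   whole tumor.
4. **Selection** — ICC(2,1) reliability filter (inter- and
   intra-observer, both > 0.75), univariate logistic screen, Pearson
   correlation pruning (|r| ≤ 0.75), L1-penalized logistic selection
   with a cross-validated penalty, and bidirectional stepwise AIC.
   Clinical covariates use the separate univariate P < 0.1 → stepwise
   AIC → multivariable P < 0.05 rule.
5. **Models** — five elastic-net logistic models (clinicoradiological,
   subregion, classical, subregion-clinicoradiological, combined) with
   balanced class weights, tuned by exhaustive grid search maximizing
   mean out-of-fold AUC on the training cohort only.  The subregion
   model is trained on subregion rows (each inherits its patient's MSI
   label; cross-validation folds are grouped by patient) and produces a
   patient score as the arithmetic mean of the patient's V subregion
   scores.
6. **Evaluation** — AUC with DeLong confidence intervals, paired DeLong
   tests, F1/accuracy/sensitivity/specificity with stratified bootstrap
   CIs (2000 replicates, percentile method), decision curves
   (thresholds 0.01–0.60), Hosmer–Lemeshow calibration, Youden-index
   cutoffs chosen on the training cohort, and Kaplan–Meier / log-rank
   stratification of 3-year disease-free survival by predicted MSI
   status.

## Feature definitions

First-order, shape and texture features follow the IBSI / pyradiomics
conventions: population moments (kurtosis is the raw fourth
standardized moment), histogram statistics on the 32-level
discretization, marching-cubes mesh surface quantities, principal-
moment axis lengths (4·√eigenvalue), GLCM and GLRLM aggregated as
per-direction features averaged over the 13 unique 3-D directions at
distance 1, and GLSZM/GLDM/NGTDM with 26-connectivity.  The standard
texture families total 75 features; GLCM `SumAverage` — identically
`2·JointAverage` for a symmetric matrix — is excluded to form the
74-feature panel, so a full extraction is exactly
4 × (18 + 14 + 74) = 424 columns and the secondary clustering
signature 4 × (18 + 74) = 368.  Shape is a property of the region
geometry; it is computed once and repeated under each sequence
namespace so every sequence block carries the complete 106-feature
panel.

Numerical choices worth knowing:

* the binary indicator is smoothed with a 0.6-voxel Gaussian before
  iso-surfacing; without it the marching-cubes surface of a digitized
  ball overestimates the analytic area by ≈ 8 % (staircase bias), with
  it the mesh volume is within 1 % and sphericity within 0.025 of the
  analytic values for a 10-mm ball;
* features that are undefined on degenerate inputs (correlation of a
  constant region, skewness of a constant region, NGTDM statistics of
  a single-level region) are 0 by convention, with warnings where the
  situation is unusual;
* GLCM MCC uses the similarity transform B = D^(-1/2) P D^(-1/2) so a
  symmetric eigensolver applies; absent gray levels contribute zero
  eigenvalues which cannot displace the second-largest.

## Habitat clustering choices

* FCM: fuzzifier m = 2.0, tolerance 1e-5 on the maximum membership
  change, at most 300 iterations, k-means++-style seeding from the
  stage seed.  Voxels coinciding with a centroid get full membership
  (the standard singularity rule); empty hard clusters are dropped and
  the labeling compacted.
* Preliminary clusters below 10 voxels are merged into the nearest
  surviving cluster by intensity-centroid distance before secondary
  extraction — texture matrices are unstable below that size.
* The Bayesian Gaussian mixture uses a Dirichlet-process weight prior
  with concentration 1/max_components, reg_covar 1e-4, 10 restarts
  keeping the best evidence lower bound, and an effective-component
  rule of posterior weight ≥ 0.01 with at least one assigned row.
  Component covariances are **spherical**: with at most ten rows
  (the preliminary clusters) a full covariance per component is
  rank-deficient, and the variational fit then places one
  near-singular component on every row and never merges anything
  (observed V ≈ 5–7 with adjusted Rand ≈ 0.6 on well-separated
  3-habitat phantoms); the spherical model recovers the planted
  partition essentially perfectly under the same conditions.
* PCA operates on column-standardized secondary features and keeps the
  smallest number of leading components whose cumulative explained
  variance reaches 0.85; zero-variance columns are dropped first.

## Selection choices

* The univariate radiomic screen uses α = 0.05 (the clinical screen
  uses the stated 0.1).  Single-covariate logistic models are fitted by
  a vectorized Newton–Raphson across all columns at once; agreement
  with statsmodels' per-column MLE is verified in the tests.
* The LASSO penalty is chosen by the glmnet-style **1-SE rule**: the
  strongest penalty whose mean out-of-fold AUC is within one standard
  error of the best.  Choosing the AUC maximizer directly turns out to
  keep large feature sets even on pure-noise designs (a random penalty
  wins the comparison), while the 1-SE rule returns empty sets under
  the null and still retains a planted strong predictor in 10/10
  seeded trials; `criterion="max_auc"` remains available.
* Stepwise AIC is bidirectional from the full post-LASSO model with a
  deterministic scan order (descending univariate |z|); it reproduces
  the exhaustive-subset AIC minimum on small candidate sets.
* ICC is the two-way random-effects, absolute-agreement, single-rater
  form (ICC(2,1)), computed vectorized across features and checked
  against pingouin.

## The phantom cohort

Each phantom patient is an ellipsoidal tumor (randomly jittered center
and semi-axes) on a small isotropic grid.  Habitats grow from random
interior seed points by nearest-seed assignment; every habitat has its
own per-sequence mean intensity (base 120, separation 25 in arbitrary
units along near-orthogonal contrast patterns from a six-archetype
library) and its own texture correlation length (1.2–4 mm), realized
as Gaussian random fields of amplitude 12 plus white noise of SD 4.
In cohort mode the habitat count is drawn per patient from {2,…,5}
and the non-risk archetypes are sampled from the library, so tumor
composition — and therefore every whole-tumor summary statistic —
varies across patients, mirroring the per-patient adaptive subregion
count the pipeline targets.  Each habitat's mean intensities also
receive a per-patient random offset (SD 8, phenotype independent),
emulating biological variability of the tissue archetypes.  One
designated *high-risk habitat* is always present, shrunk to a focal
region whose volume fraction is drawn per patient from U(0.08, 0.25).

The MSI phenotype displaces the image parameters: a weak diffuse mean
shift (+2) on every habitat, plus a focal effect on the high-risk
habitat — a mean shift (+14) and a texture-scale factor of 0.3
(markedly finer texture).  This is the package's model of the
biological claim under test: the MSI signal is concentrated in a focal
habitat of variable size, so whole-tumor statistics dilute it by a
patient-dependent factor (and bury it under composition variability)
while subregion features retain it at full, size-independent
strength.  The effect sizes were designed by pilot measurements of
per-feature discrimination ceilings so that the planted phenomenon
actually exists at desk scale; they are free parameters of the
generator, not estimates of any clinical effect.  A null cohort
(`MsiEffect.null()`) removes the image effect entirely while keeping
everything else.

Clinical covariates are drawn from rectal-cancer-like marginals; MSI
labels follow a logistic model with planted odds ratios 3.0 (high vs
low tumor location), 1.3 (middle vs low) and 0.4 (N1–N2 vs N0), with
the intercept calibrated by bisection so the expected prevalence
matches the requested value (default 11 %).  Disease-free survival is
exponential with monthly hazard 0.028 for MSS and an MSS:MSI hazard
ratio of 4, censored at min(60 months, U(6, 60)).  All randomness
derives from one master seed via `numpy.random.SeedSequence` spawning.

What the generator does **not** emulate: scanner physics, k-space
artifacts, anatomy, inter-sequence misregistration (volumes are
generated aligned; the pipeline asserts rather than performs
registration), non-exponential hazards, and the correlation structure
of real radiomic features.  Passing tests therefore demonstrate the
pipeline's correctness and its behavior under a known generative
model, not clinical performance.

## Calibration experiments and problem sizes

The experiment harnesses (`habitomics.experiments`) run at desk scale
so the full suite completes in minutes on one CPU:

* planted-habitat recovery: 10 phantoms, 24×24×18 grids, separation
  40, noise 2, amplitude 8 — modal V and adjusted Rand vs truth;
* subregion-vs-classical comparison: 50 replicates of 40-patient
  cohorts on 20×20×14 grids, case-enriched to 25 % MSI (the usual
  case-control strategy for a discrimination experiment — at the
  population prevalence of ~11 % a 40-patient cohort carries only ~4
  cases, too few to select features on); held-out AUC is the mean of
  per-fold AUCs over 3 stratified folds (averaging rather than pooling
  keeps the fold models' different probability calibrations from
  contaminating one combined ranking), with per-fold selection
  (univariate → correlation → LASSO) and the reduced elastic-net grid;
* null calibration: the same harness with the image effect off;
* clinical recovery: 200 cohorts of 400 patients; retention and
  selection-conditional CI coverage of the planted odds ratios (the
  retention power of the OR-0.4 N-stage effect at ~45 events per
  cohort is only ≈ 50 %, so unconditional coverage is bounded by
  power, not by interval validity);
* Hosmer–Lemeshow type-I error: 1000 well-specified logistic
  replicates of n = 500; log-rank power: 200 replicates at hazard
  ratio 4, n = 200.

## Known limitations

* The subregion pipeline's advantage over whole-tumor radiomics
  depends on the planted signal being focal and the habitat map
  isolating it; with diffuse signals the whole-tumor model is at least
  as good (it has better voxel statistics).
* The BGMM merge step operates on at most ten rows; its component
  count is a regularized estimate, not a consistent one.
* Small cohorts (tens of patients) make out-of-fold AUCs noisy;
  the Monte-Carlo replicate counts are chosen to average over that.
* N4 bias correction is exercised against synthetic multiplicative
  fields; scanner-specific bias behavior is out of scope.
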