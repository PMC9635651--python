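# Methods

`metml` is a pipeline for machine-learning genomic prediction on
multi-environment trial (MET) data. This note documents the models and
procedures it implements, the choices made where the design was genuinely
open, and what the synthetic data generator does and does not emulate.

## Data model

A MET dataset joins four user tables: a genotype dosage matrix (minor-allele
counts in {0, 1, 2}, imputed beforehand — the package validates and refuses
missing dosages rather than imputing), a genetic map, a phenotype table keyed
by (genotype, year, location), and per-environment metadata (coordinates,
elevation, planting and harvest dates). An *environment* is a `location_year`
combination; collisions of the composite id are rejected. Dates must be
ISO-8601 — locale-dependent dialects fail loudly instead of being guessed.
Dosage coding is fixed at 0/1/2 with heterozygote = 1; since markers are
centered and scaled before every downstream use, the choice between 0/1/2 and
−1/0/1 coding only shifts column means and does not affect any model.

## Environmental covariates

Daily weather per environment (in-field records, a pluggable provider, or a
mix — only environments without in-field data are fetched) passes a quality
control with physical-range rules: temperatures in [−50, 60] °C, precipitation
in [0, 500] mm, non-negative radiation and wind, relative humidity in
[0, 100] %, `tmax ≥ tmin` (violations swapped), `tmean` within [tmin, tmax].
Flagged or missing values are linearly interpolated in time within the
environment (precipitation imputed as 0, since rain is not continuous in
time); an environment with more than 30 % of days flagged is rejected as
unusable. QC is idempotent.

Derived daily variables:

* saturation vapour pressure by the Tetens form
  `es(T) = 0.6108·exp(17.27 T / (T + 237.3))` kPa; daily VPD =
  mean of es(tmax), es(tmin) minus actual vapour pressure (from mean RH or
  dewpoint), clipped at zero;
* FAO-56 Penman–Monteith reference evapotranspiration at the daily step with
  soil heat flux G = 0, net radiation from measured short-wave radiation with
  albedo 0.23 and the standard net long-wave terms, and elevation defaulting
  to sea level when absent. Wind is assumed measured at 2 m; the FAO-56
  log-profile conversion is applied when another height is given.
* growing degree-days `max(0, (min(tmax, t_cap) + max(tmin, t_base))/2 −
  t_base)` with defaults t_base = 10 °C, t_cap = 30 °C (maize convention,
  overridable per crop);
* astronomical daylength (rejected for |latitude| > 66°, where polar day/night
  breaks the formula), and photothermal time defined here as daily GDD ×
  daylength (°C·h). This definition is a documented package convention; the
  term is used in the literature without a universal formula.

The growing season is split into day windows by one of four methods:
`fixed_number` (default 10 near-equal windows, remainder days to the earliest
windows so the construction is deterministic), `fixed_length` (last window
truncated), `user_defined` breakpoints (validated to cover the season), or
`gdd_stages` (a boundary at the first day cumulative GDD crosses each
threshold; unreached thresholds are absorbed by the final window with a
warning). Within each window the aggregation is: means for state variables
(temperatures, VPD, radiation, daylength), sums for fluxes (precipitation,
ET0, GDD, photothermal time), and the frequency of days with precipitation
above 10 mm. Covariate names are `variable_k` with a 1-based window index
(`freq_P_sup10_2` is the heavy-rain frequency of the second window); the
column set must be identical across environments, which restricts
`fixed_length`/`gdd_stages` to equal window counts.

## Cross-validation schemes

Four breeding scenarios, each with a checkable partition constraint:

* **CV1** (new genotypes): genotypes — not observations — are partitioned into
  folds by shuffled round-robin; all observations of a test genotype are test.
* **CV2** (sparse testing): single cells are held out under the constraint
  that every test genotype keeps at least one training observation in another
  environment. Construction: genotypes in shuffled order, each genotype's
  observations assigned greedily to the currently smallest folds not yet used
  by that genotype. Genotypes observed once stay in training (warning).
* **CV0** (new environments): leave-one-environment-out, leave-one-site-out,
  leave-one-year-out, and forward prediction (each test year predicted from
  strictly earlier years, requiring at least `min_train_years = 2` training
  years, matching the convention for single-location series).
* **CV00** (new genotypes in new environments): from a CV0 partition, a
  fraction of the genotypes occurring in the test environments (default 0.5,
  so training sets stay non-empty in single-location data) is sampled; their
  test-environment observations form the test set and *all* their observations
  leave the training set. Other genotypes keep their training-environment
  records — the scenario constrains overlap, not the construction, so this
  choice is the package's own.

Partitions store positional indices into the phenotype table, so every
invariant can be re-verified from the partition plus the table alone. All
randomness flows from one user seed through per-repeat/per-partition derived
seeds (`numpy.random.SeedSequence`).

## Preprocessing

All transforms are fitted on training rows only and applied unchanged to test
rows: zero-variance removal (a column constant in training is dropped even if
variable in test), standardization by training mean/sd, and optional
replacement of the marker block by its top `num_pcs` principal components
(from the SVD of the centered/scaled dosages, or from the eigenvectors of the
genomic relationship matrix G = XX′/p — the same column space, offered because
the GRM is the kernel models' native object). Default
`num_pcs = min(100, n_train − 1, p)`. PCA is restricted to the marker block;
environmental covariates enter the models directly. The fitted preprocessor
serializes to JSON for exact reuse when predicting new trials.

## Prediction models and evaluation

The registry holds gradient-boosted trees (`gbdt_pc_ec`, XGBoost), random
forest (`rf_pc_ec`), a multilayer perceptron (`mlp_pc_ec`; two hidden layers
64/32, ReLU, Adam with early stopping, patience 10 — the architecture is a
package default, deliberately modest), and a stacked ensemble
(`stacked_ensemble`): an RBF support-vector regression on the ECs, an elastic
net on the (standardized) marker dosages, and XGBoost on 40 marker principal
components plus the ECs. The base learners' 5-fold out-of-fold predictions
are combined by a Lasso meta-learner (LassoCV); base learners with a zero meta
coefficient are dropped. Non-negativity is not imposed on meta coefficients.

Evaluation is nested cross-validation: per outer partition, the preprocessor
is fitted on the outer-training rows, hyperparameters are tuned by seeded
random search (default budget 30 configurations, 5 inner folds; tuned
gradient-boosting parameters are boosting iterations 50–1000, learning rate
0.01–0.3 on a log scale, and tree depth 2–10), the winner is refit on all
outer-training data, and metrics are computed on the untouched test rows.
Pearson correlation is always computed within environment (undefined below 3
test observations per environment); RMSE is reported per environment and
pooled. Runs are reproducible: partitions and tuned hyperparameters are
bit-identical under the stored seed, predictions identical to 1e-6.

Step-3 prediction (`predict_new`) tunes on the full training set, fits once,
and predicts a phenotype-free test set; it refuses EC column mismatches and
aggregation-method mismatches between training and test. A ranking utility
returns the top-n genotypes per location-year, ties broken by genotype id.

## Reaction-norm benchmark

The linear benchmark is `y_ij = μ + g_i + w_j + gw_ij + ε_ij` with
`g ~ N(0, G σ²_g)`, `G = XX′/p` on centered/scaled markers;
`w ~ N(0, Ω σ²_w)`, `Ω = WW′/q` on centered/scaled ECs;
`gw ~ N(0, [Z_g G Z_g′] ∘ Ω_obs σ²_gw)` (Hadamard product at observation
level); and IID Gaussian residuals. Year and location main effects are
deliberately excluded so the comparison isolates marker, covariate and
interaction information.

Fitting is Gibbs sampling in the eigenbasis of each observation-level kernel
(eigenvalues below 1e-10 of the spectral radius dropped), which makes each
sweep a handful of matrix-vector products. Variance components get
scaled-inverse-chi-squared priors with df = 5 and scales set from the sample
variance: half the variance assigned a priori to the three random effects
jointly (split equally), half to the residual — a conventional weakly
informative default for this model family. Kernels must be PSD within 1e-8 of
the spectral radius; an optional diagonal jitter is available. Defaults match
the benchmark convention (20,000 iterations, 2,000 burn-in, thinning 5); the
test suite and acceptance script run 2,000-iteration chains, which the
recovery checks show are sufficient at those problem sizes. Prediction is
BLUP-style: `μ + Σ_k K_cross,k K_k⁺ û_k`, with cross-kernels computed from new
markers/ECs centered and scaled by the *training* statistics, so a new
environment at the training-mean covariates contributes zero through Ω.

## Interpretation

Permutation importance of variable j is the mean over repeated permutations of
`L(y, f(X_permuted_j)) − L(y, f(X_original))` with RMSE loss, computable on
the training or a stored unseen split; per-permutation values are returned.
Importances operate on post-preprocessing features (marker PCs, ECs) because
those are what the model consumes. Gain-based importance is available for
tree ensembles only and is rescaled so the maximum is 100. ALE curves use
empirical-quantile bins (midpoint interpolation, duplicate edges merged),
average the prediction difference between each bin's edges over the in-bin
observations only, accumulate across bins, and center by the count-weighted
mean — the conditional averaging is what keeps correlated, unused features
flat where a marginal sweep would not be.

## Environment clustering

K-means on standardized climate and/or soil covariates for K = 2…10 (best of
25 seeded initializations per K, plus a warm start that splits the best K−1
solution, which makes the elbow curve provably non-increasing). Average
silhouette is reported per K (undefined when every cluster is a singleton).
The package reports diagnostics only and leaves the choice of K to the user.

## Synthetic data generator

The generator is first-class, tested code; every module is testable offline
through it. Two trial shapes are built in: a rice-like series (320 genotypes,
one location, years 2009–2013, ~130-day seasons) and a maize-like network
(six North-American locations × 2014–2017 with two site-years missing,
22 environments, 120-day seasons).

Markers are binomial(2, f) dosages with allele frequencies uniform on a
configurable range (default 0.05–0.5). Weather is a latitude- and
day-of-year-dependent temperature sinusoid with AR(1) noise and a
per-environment year effect, Bernoulli–gamma precipitation, radiation bounded
by the clear-sky value for the site, and is constructed to pass quality
control with zero flags. Phenotypes follow

    y_ij = μ + x_i′β + w_j′γ + Σ_k (x_i′b_k)(w_j′c_k) + ε_ij

with a rank-3 product interaction — chosen so the reaction-norm kernel model
is well-specified for the interaction, keeping comparisons between linear and
ML models fair. Each component is rescaled *empirically on the realized
design* to hit the requested variance fractions (defaults for the maize-like
shape: genetic 0.35, environmental 0.25, interaction 0.15, residual 0.25 —
heritabilities in the range reported for yield in such networks); the full
truth record (effects and realized shares) is returned for oracle tests.
Every stage draws from an independent sub-stream of the master seed, so any
layer regenerates alone.

What the generator does **not** emulate: linkage disequilibrium and population
structure, dominance or epistasis beyond the product interaction,
genotype-specific phenology, spatial field trends, and trait-specific error
structures. Passing tests therefore demonstrate the *mechanics* of the
pipeline (constraints, exactness, recovery under a correctly specified
generative model), not predictive performance on real breeding data.

## Numerical choices and limitations

* Problem sizes in the test suite and acceptance script (e.g. 2,000-iteration
  chains, 20 replicates at n = 400, tuning budgets of 2–5 configurations) are
  deliberate desk-scale settings; the library defaults are larger.
* Random search replaces Bayesian hyperparameter optimization; at equal
  budget it explores the same spaces but makes no claim of parity with a
  surrogate-based optimizer.
* The silhouette is reported as NaN when K equals the number of environments.
* The variance floor in the Gibbs sampler is 1e-10, protecting degenerate
  (constant-response) inputs.
* ET0 requires wind and humidity; they are never silently defaulted.
* Whether base learners inside the stacked ensemble should themselves be tuned
  is an open design point; the package fits them at fixed, moderate settings
  and documents this, trading a small amount of accuracy for determinism and
  speed.
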