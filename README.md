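# metml — machine-learning genomic prediction for multi-environment trials

Plant breeders evaluate candidate genotypes in networks of field trials spread
over years and locations (multi-environment trials, METs). Two questions
dominate: how well will a genotype perform in an environment where it was
never grown, and which genetic and environmental factors drive the
genotype-by-environment (G×E) interactions that reshuffle rankings across
sites? `metml` is a Python library and command-line tool for both: it turns
daily weather into day-interval environmental covariates, generates the
cross-validation schemes breeders actually face, fits and evaluates
machine-learning and kernel-based prediction models, and interprets the
fitted models — all testable offline on synthetic data.

## What it computes

**Environmental covariates.** Daily weather per environment (in-field records
or a pluggable retrieval interface) is quality-controlled, enriched with
derived variables — vapour pressure deficit, FAO-56 Penman–Monteith reference
evapotranspiration ET₀, growing degree-days, daylength, photothermal time —
and aggregated over day windows of the growing season (a fixed number of
windows, fixed-length windows, user-defined phenological intervals, or
GDD-based stages) into the environment × covariate matrix **W**, with columns
like `sum_et0_3` or `freq_P_sup10_2` (variable, window index).

**Cross-validation schemes.** CV1 (new genotypes), CV2 (sparse testing),
CV0 (new environments: leave-one-environment/site/year-out and forward
prediction from past years only), and CV00 (new genotypes in new
environments). Every partition carries its scheme metadata and is
re-checkable against the phenotype table.

**Models.** Gradient-boosted trees, random forest and a multilayer perceptron
on marker principal components + covariates; a stacked ensemble (SVM on
covariates, elastic net on markers, XGBoost on 40 marker PCs + covariates,
combined by a Lasso meta-learner on out-of-fold predictions); and the linear
reaction-norm benchmark

    y_ij = μ + g_i + w_j + gw_ij + ε_ij,
    g ~ N(0, G σ²_g),  G = XX′/p        (centered/scaled markers X)
    w ~ N(0, Ω σ²_w),  Ω = WW′/q        (centered/scaled covariates W)
    gw ~ N(0, [Z_g G Z_g′] ∘ Ω σ²_gw)   (Hadamard product)

fitted by Gibbs sampling (`ReactionNormModel(...).fit()` returns a results
object with variance components, a `summary()` table, and BLUP-style
`predict()` for new genotypes/environments). Evaluation is nested CV with
seeded random-search tuning; Pearson r between observed and predicted values
is always computed within environment, alongside RMSE.

**Interpretation.** Permutation-based variable importance (mean loss increase
over repeated shuffles, on the training or an unseen split), gain importance
for tree models (scaled 0–100), and accumulated local effects (ALE) curves
with quantile bins, centered at zero.

## Worked example

Simulate a maize-like trial network (6 locations × 4 years, 22 environments —
two site-years missing, as in real networks) and ask how well a
gradient-boosted model predicts a *new year* (CV0, leave-one-year-out):

```python
from metml import nested_cv_evaluate, summarize_met_data
from metml.synthetic import make_g2f_like

met, truth = make_g2f_like(seed=42)
print(summarize_met_data(met))

result = nested_cv_evaluate(
    met, "grain_yield", model_id="xgb_reg_1",
    cv_type="cv0", cv0_type="leave-one-year-out",
    seed=100, inner_folds=3, tuning_budget=5, num_pcs=50,
)
print(result.summary())
print(result.metrics_by_env.head(6).to_string(index=False))
```

Output (a few minutes on one CPU):

```
MET data summary
  genotypes:    150 (400 markers)
  environments: 22 (4 years x 6 locations)
  covariates:   110 environmental covariates
  soil:         absent
  traits:       1
    grain_yield: 0.0% missing

gbdt_pc_ec / grain_yield / cv0: 4 partitions
  mean within-environment r: 0.669
  pooled RMSE:              0.868

 partition         env_id   n  pearson_r     rmse
         0      Ames_2014 150   0.627437 1.144732
         0 Champaign_2014 150   0.551924 0.822937
         0  Columbia_2014 150   0.641595 0.739400
         0  Kingston_2014 150   0.643034 0.874874
         0   Lincoln_2014 150   0.742719 0.699453
         1      Ames_2015 150   0.677278 1.009643
```

Each partition holds out one year; within each held-out environment the
Pearson r measures how well the model ranks the 150 genotypes there from
markers and that year's weather covariates, and the RMSE is in trait units
(here the simulated trait has total variance 1, so 0.87 means roughly one
standard deviation of error against a simulated heritability-limited optimum).

The same object fits the reaction-norm benchmark
(`model_id="reaction_norm"`), and the fitted pipelines feed
`permutation_importance`, `model_specific_importance` and `ale_curve`.

The command-line interface mirrors the library:

```bash
metml simulate --preset g2f --seed 42 --out data/
metml cv --data data/ --trait grain_yield --prediction-method xgb_reg_1 \
         --cv-type cv0 --cv0-type leave-one-year-out --seed 100 \
         --path-folder results/cv0
metml cluster --data data/ --k-min 2 --k-max 10 --seed 1 --out results/clusters
```

Every run writes its configuration, seed and outputs (predictions,
per-environment metrics, tuned hyperparameters) to the output directory, and
re-running with the recorded seed reproduces them.

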