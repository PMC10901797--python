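# connleak

Benchmarking **data leakage** in connectome-based predictive modeling
pipelines.

Predictive models that map brain connectivity (subject × edge matrices of
Fisher-z functional or structural connectivity) to phenotypes are easy to
contaminate: selecting features on the full dataset, harmonizing sites with
ComBat before splitting, regressing covariates out of the whole sample,
duplicating subjects, or letting relatives straddle the train/test boundary
all leak test information into training. `connleak` implements these five
forms of leakage as *explicit, declarative pipeline variants*, runs them
against a strictly non-leaky gold standard, and quantifies the damage as

* **Δr** — change in Pearson correlation between observed and predicted
  phenotype (predictions concatenated across folds), and
* **Δq²** — change in cross-validation R²,
  `q² = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²`, which is negative whenever the model
  is worse than predicting the mean,

plus coefficient-level distortion (fold-averaged coefficient correlations,
subnetwork-wise selection profiles over the 55 unordered pairs of 10
canonical networks).

The intended users are neuroimaging methodologists and reviewers who want
to reproduce, probe, or teach the directional effects of leakage without
access to restricted cohorts: the package ships a synthetic-cohort
generator with controllable brain–behavior effect size, twin-family
structure (shared latent signal, feature noise and phenotype noise),
additive/multiplicative site effects, and covariate confounding.

## The pipeline

The baseline learner is ridge regression with univariate feature selection
(top 5% of edges by |Pearson r| with the phenotype) and a nested k-fold
grid search over the L2 penalty α ∈ {10⁻³, …, 10³}, scored by the Pearson
r of concatenated inner-fold predictions. Connectome-based predictive
modeling (CPM: positive-edge sum minus negative-edge sum, univariate
regression on the score) and an RBF support-vector regressor conform to the
same contract. Around the learner sit three stages, each of which can run
`cv` (fit on training folds, applied to test), `leaky` (fit on the full
data before splitting), or `none`:

* **site correction** — ComBat location/scale harmonization with optional
  parametric empirical-Bayes shrinkage;
* **covariate regression** — OLS residualization of edges on
  [1, age, sex, motion], `X_test,adj = X_test − C_test β̂_train`;
* **feature selection** — the top-fraction edge set.

The outer split is either family-aware grouped k-fold (no family ever
spans folds) or a plain shuffled k-fold — which on data with families *is*
family leakage. Subject leakage duplicates a percentage of rows verbatim
before splitting.

## Worked example

Even with *no* true signal, selecting features on the whole dataset turns
a chance-level model into an apparently strong one:

```python
import connleak as cl

dataset = cl.null_dataset(n_subjects=200, n_nodes=100, seed=0)

leaky = cl.PipelineSpec(site_correction="none", covariate_regression="none",
                        feature_selection="leaky")
delta = cl.delta_vs_gold(dataset, leaky, cl.ModelSpec(), seed=1)
print(f"gold standard : r = {delta.gold.r:+.3f}, q2 = {delta.gold.q2:+.3f}")
print(f"leaky select  : r = {delta.leaky.r:+.3f}, q2 = {delta.leaky.q2:+.3f}")
print(f"inflation     : delta_r = {delta.delta_r:+.3f}")
```

prints

```
gold standard : r = -0.154, q2 = -0.566
leaky select  : r = +0.884, q2 = +0.570
inflation     : delta_r = +1.038
```

The phenotype here is independent of every edge, so the gold standard
honestly reports chance performance (r ≈ 0, q² < 0), while the leaky
pipeline — identical except that the 5% edge set was chosen using the test
subjects — reports r ≈ 0.88. Both pipelines used the same fold assignments
(same split seed), so the difference is leakage, not split luck.

A command-line interface mirrors the library: `connleak generate` writes
synthetic cohorts in the loadable text/HDF5 formats, `connleak run` and
`connleak benchmark` execute one or all eleven analysis variants,
`connleak subsample` runs the sample-size experiment and
`connleak family-sweep` the family-fraction sweep; results are tidy TSV.

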