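# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `connleak`.

## The prediction pipeline

**Learner.** Ridge regression on the top `feature_fraction` (default 0.05)
of edges ranked by |Pearson r| with the phenotype. For fixed n, p-value
ranking of the correlation test is a monotone function of |r|, so the |r|
ranking is used directly; ties break toward the smaller edge index and
zero-variance edges get r = 0 so they are never preferred. The L2 penalty
is chosen from a grid (default 10⁻³…10³, 7 values) by an inner k-fold
(default 5) search on the outer-training data: within each inner training
partition the features are *re-selected*, a ridge path over the whole grid
is computed from one SVD of the centered design, inner-fold predictions are
concatenated per grid value, and the value with the largest Pearson r wins.
Tie-break: the largest α (strongest regularization), for determinism.
Re-selecting inside each inner partition prevents the selection step from
leaking into the hyperparameter choice; selection once per outer-training
set is also non-leaky with respect to the outer test fold and can be
obtained by passing a fixed feature set. Concatenation (rather than
averaging per-fold r) was chosen to match the outer-loop metric convention.

**CPM.** The same selection step; selected edges are split by the sign of
their training correlation with the phenotype; the per-subject score is
(sum of positive edges) − (sum of negative edges); phenotype is regressed
on the score by univariate OLS. A single-sign selection is valid (the
missing sign contributes zero); a zero-variance score is an error.

**SVR.** An RBF support-vector regressor (scikit-learn) with a grid over
the penalty C conforms to the same fit/predict contract; it carries no
edge-level coefficients and no benchmark weight.

**Inner splits are plain, not family-aware.** They act inside an outer
training set that already respects families, so no test information is at
stake; this is recorded as a configurable convention.

## Correction stages

**Covariate regression.** β̂ = (CᵀC)⁻¹CᵀX with C = [1, age, sex, motion],
computed by a numerically stable least-squares solve (never an explicit
inverse — the explicit form appears only in test oracles). The intercept
column is always constructed internally; callers pass raw covariates.
Rank-deficient designs are rejected with the collinear columns named, and
`apply` refuses silently reordered covariate columns. The non-leaky form
estimates β̂ on training rows and applies it to both halves; the leaky form
is the same fit+apply composition on the concatenated data, exposed as a
separate entry point so pipelines must declare it. When the phenotype being
predicted is itself a covariate (e.g. age), it is excluded from C via the
pipeline spec's `covariate_exclusions`.

**ComBat.** Per feature, data are standardized by the overall mean α̂ and
the pooled within-site SD; per-site location γ̂ and scale δ̂ are estimated
on the standardized scale; the correction is
x_adj = ((x − α̂)/σ̂ − γ*) / δ* · σ̂ + α̂. With empirical Bayes (the
default), γ and δ² are shrunk toward across-feature priors (normal for γ;
inverse-gamma moment-matched for δ²) by the standard iterative
conditional-posterior solution (convergence 10⁻⁴, cap 200 iterations).
Without EB the raw estimates are used, which makes the transform exactly
idempotent and equalizes per-site means exactly — the form used in
algebraic tests. Numerical conventions: within-site variances use the
population (ddof = 0) denominator so that idempotence holds to machine
precision; a model fit on a single site is applied as an exact identity
(one batch means nothing to harmonize); unseen site labels at apply time
are an error naming the label, because a cross-validated ComBat cannot
harmonize a site it never saw. Degenerate EB inputs (a single feature, or
identical estimates across features, where the prior spread is zero) fall
back to the raw estimates. ComBat carries no covariate-preservation design
matrix here; site harmonization and covariate regression are deliberately
independent transforms, applied ComBat-first by default (site is an
artifact of the measurement, covariates are subject-level); the order is
configurable.

## Splitters and leakage injectors

`family_kfold` shuffles families with the seed, then deals them
largest-first to the fold with the fewest subjects (ties to the lowest fold
index). This balances fold sizes, and because family order is
seeded-random within size ties it is unbiased. `plain_kfold` is the same
procedure over singleton families, so on unrelated subjects the two
splitters coincide exactly for a given seed — which also makes the
family-leakage comparison collapse to exactly Δ = 0 when no families
exist. Subject-leakage injection duplicates `round(pct/100·n)` uniformly
chosen rows verbatim and gives the duplicates fresh singleton family ids,
so even a family-aware split can separate a duplicate from its source:
subject leakage deliberately ignores family structure.

`run_pipeline` executes: injection → full-data (leaky) stages → outer
split → per-fold cv stages → nested model fit → test-fold prediction →
concatenated r and q². The leaky feature set is computed on the raw,
uncorrected full data (per-fold corrections still run); this keeps exactly
one stage leaky per variant and is configurable in principle. Each run
asserts that the folds partition the rows and that family-aware folds never
split a family. `delta_vs_gold` pairs the leaky pipeline with its matched
gold spec under the *same* split seed, isolating the leakage effect from
split noise; stages a variant omits (`none`) stay omitted in the match so
the comparison changes one thing at a time.

## The synthetic cohort generator

The generator produces the statistical structure the benchmark needs, not
a facsimile of any real cohort:

* **Latent signal.** One standard-normal factor s per subject loads on
  `n_signal_edges` edges with per-edge coefficients N(0, signal_edge_sd²)
  (default 0.3 against unit edge noise, i.e. per-edge population
  correlations of roughly ±0.1–0.3, typical of edge-level brain–behavior
  effects). The phenotype is y = a·s + covariate effects + noise with a
  chosen in closed form so that the population R² of y on s equals
  `effect_size` exactly; the null (0), moderate (≈0.2) and strong (≈0.5)
  regimes mirror attention-problem-like, matrix-reasoning-like and
  age-like prediction difficulty.
* **Families.** `family_fraction` of subjects belong to two-member
  (twin-like) families; within a pair the latent factor, the edge-level
  noise, **and** the phenotype noise each share a common component with
  correlation `family_rho`, and age is shared exactly. Sharing the edge
  noise is essential: family leakage operates by an overfit model
  transferring memorized patterns between siblings, which requires the
  *whole* connectome — not just the signal edges — to be similar within a
  family (a stylized rendering of connectome heritability). Larger
  sibships are out of scope; size-2 families keep `family_rho` directly
  interpretable.
* **Sites.** Subjects are assigned uniformly to `n_sites`; each site
  applies x → δ·x + γ per edge with γ ~ N(0, site_shift_sd²) and δ ~
  U(site_scale_range) — the additive/multiplicative structure ComBat
  assumes.
* **Covariates.** Age ~ U(8, 22) years (a developmental-cohort range),
  sex ~ Bernoulli(0.5), head motion ~ log-normal (median ≈ 0.11 mm mean
  framewise displacement). Each covariate can load on all edges (per-edge
  coefficients N(0, on_features²) of the analytically standardized
  covariate) and on the phenotype (fixed coefficient `on_phenotype`),
  creating genuine confounding. Covariates are standardized by their
  population moments, not sample moments, so the generative law does not
  depend on the realized sample.

Everything is deterministic given the config seed; identical configs give
byte-identical datasets. What the generator does **not** emulate: realistic
marginal distributions or effect magnitudes of any named dataset,
heavy-tailed noise, larger sibships, site-by-covariate interactions, or
missing data. Passing direction-of-effect tests on these cohorts therefore
shows that the pipelines implement the leakage mechanisms correctly and
that the documented directions are reproducible under the stated
assumptions — not that effect magnitudes transfer to any particular real
cohort.

## Benchmark conditions and problem sizes

The direction-of-effect suite runs at n = 200 subjects and 100 nodes
(4950 edges, 5% selection = 247 edges), 20 paired comparisons (fresh
cohort + fresh split seed each) per leakage form, summarized by medians:
feature leakage on null data, 20% subject leakage and family leakage
(all-twin cohorts, family_rho = 0.9) at effect size 0.2, leaky ComBat under
modest harmonized site effects (3 sites, shift SD 0.2, scale 0.8–1.2), and
leaky covariate regression under a planted confound (age: 0.3 on features
/ 0.6 on phenotype; motion: 0.3/0.4). The confound and site magnitudes
were fixed by a pilot simulation before the verification thresholds were
frozen. The sample-size experiment subsamples a 600-subject, 50%-twin
cohort by family to N ∈ {100, 400}, 10 resamples × 10 split iterations.
The generator-recovery check uses n = 2000 over 50 seeds, where sampling
error of R² is well below the ±0.02 band. `scripts/acceptance.py` uses 10
paired comparisons per form (the medians are stable well before 20).

## Edge ordering and parcellations

Edges are ordered row-major over the strict upper triangle of the
node × node matrix (`numpy.triu_indices(n, 1)`); all analyses are
order-invariant, but fixing the convention makes coefficient vectors
comparable across pipelines and recoverable to node pairs via
`Parcellation.edge_index`. Subnetworks are unordered pairs of canonical
networks (K(K+1)/2 bins; 55 for 10 networks). The "size-adjusted"
subnetwork count is count/size (the selected fraction per subnetwork); the
adjustment formula is a recorded convention — any monotone alternative
changes Spearman comparisons only through the size profile — and raw
counts are available via `adjust=False`. Spearman uses average ranks for
ties. Empty subnetworks have undefined adjusted counts, returned as NaN
and excluded (with a log note) from rank correlations.

## Degenerate inputs and flagged values

Pearson r of a constant vector is undefined: it is returned as NaN with a
warning, never silently 0 (inside the nested grid search a constant
prediction vector scores −∞ so it can never win). q² of a constant
observed phenotype is an error. Zero-variance features make ComBat's
standardization undefined and are an error at fit time. Missing phenotypes
are dropped at load time with the count logged, never imputed; datasets
with missing family labels get singleton families at load time.

## Known limitations

Coefficient comparisons are defined for edge-linear models; CPM "edge
coefficients" (sign × slope) are a flagged convention, and the SVR has
none. No leave-one-site-out evaluation, lockbox validation,
hyperparameter-selection leakage, temporal leakage, longitudinal or
covariate-preserving ComBat, or reference-batch mode. Inputs are
already-parcellated connectivity; raw imaging formats are out of scope.
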