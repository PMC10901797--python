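"""Leakage injectors and the pipeline orchestrator.

A :class:`PipelineSpec` declares, stage by stage, whether site correction,
covariate regression and feature selection run inside the cross-validation
folds (``cv``), on the full dataset before splitting (``leaky``), or not at
all (``none``); whether the outer split respects families; and how many
duplicated subjects to inject.  The gold standard is everything ``cv`` with
a family-aware split and no duplicates.

Execution order of :func:`run_pipeline` (leakage happens before splitting,
family leakage during splitting):

1. subject-leakage injection (verbatim row duplication);
2. leaky stages applied once to the full data — leaky ComBat, leaky
   covariate regression, and/or the fixed leaky feature set (computed on
   the raw, uncorrected full data);
3. the outer split (family-aware honors family ids; a plain split on data
   with families IS family leakage);
4. per fold: ComBat fit on training / applied to both halves (if cv),
   covariate regression likewise (if cv), then the model's own nested
   fitting on the training half and prediction of the test half;
5. predictions concatenated across folds into one r and one q^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ConnectomeDataset
from .correction import (
    apply_combat,
    apply_covariates,
    fit_combat,
    fit_covariates,
    leaky_combat,
    leaky_covariates,
)
from .evaluation import pearson_r, q_squared
from .modeling import ModelSpec, fit_model, full_coefficients, predict_model, select_features
from .splits import family_kfold, plain_kfold
from .synthetic import SyntheticConfig, family_fraction_grid, generate_dataset

__all__ = [
    "PipelineSpec",
    "PipelineResult",
    "IterationResults",
    "LeakageDelta",
    "family_kfold",
    "plain_kfold",
    "inject_subject_leakage",
    "run_pipeline",
    "run_iterations",
    "delta_vs_gold",
    "gold_counterpart",
    "standard_variants",
    "subsample_experiment",
    "summarize_subsample",
    "family_sweep",
]

_STAGE3 = {"cv", "leaky", "none"}
_STAGE2 = {"cv", "leaky"}
_SPLITS = {"family_aware", "plain"}


@dataclass(frozen=True)
class PipelineSpec:
    """Declarative description of one analysis variant."""

    site_correction: str = "cv"
    covariate_regression: str = "cv"
    feature_selection: str = "cv"
    split: str = "family_aware"
    subject_leakage_pct: float = 0.0
    outer_k: int = 5
    covariate_exclusions: tuple[str, ...] = ()
    combat_eb: bool = True
    combat_before_covariates: bool = True
    name: Optional[str] = None

    def __post_init__(self):
        if self.site_correction not in _STAGE3:
            raise ValueError(f"site_correction must be one of {_STAGE3}")
        if self.covariate_regression not in _STAGE3:
            raise ValueError(f"covariate_regression must be one of {_STAGE3}")
        if self.feature_selection not in _STAGE2:
            raise ValueError(f"feature_selection must be one of {_STAGE2}")
        if self.split not in _SPLITS:
            raise ValueError(f"split must be one of {_SPLITS}")
        if not 0.0 <= self.subject_leakage_pct <= 100.0:
            raise ValueError("subject_leakage_pct must lie in [0, 100]")
        if self.outer_k < 2:
            raise ValueError("outer_k must be >= 2")
        object.__setattr__(
            self, "covariate_exclusions", tuple(self.covariate_exclusions)
        )

    @classmethod
    def gold(cls, **kwargs) -> "PipelineSpec":
        return cls(name=kwargs.pop("name", "gold_standard"), **kwargs)


def gold_counterpart(spec: PipelineSpec) -> PipelineSpec:
    """The matched non-leaky spec: leaky stages -> cv, plain -> family-aware,
    no duplicates.  Stages the spec omits (``none``) stay omitted so the
    comparison isolates the leakage itself."""
    return replace(
        spec,
        site_correction="cv" if spec.site_correction == "leaky" else spec.site_correction,
        covariate_regression=(
            "cv" if spec.covariate_regression == "leaky" else spec.covariate_regression
        ),
        feature_selection="cv",
        split="family_aware",
        subject_leakage_pct=0.0,
        name="gold_counterpart",
    )


def standard_variants(
    subject_pcts: Sequence[float] = (5.0, 10.0, 20.0), **common
) -> dict[str, PipelineSpec]:
    """The 11 benchmark variants: four non-leaky analysis choices and the
    five forms of leakage (subject leakage at three levels)."""
    v = {
        "gold_standard": PipelineSpec(name="gold_standard", **common),
        "no_site_correction": PipelineSpec(
            site_correction="none", name="no_site_correction", **common
        ),
        "no_covariate_regression": PipelineSpec(
            covariate_regression="none", name="no_covariate_regression", **common
        ),
        "no_site_no_covariates": PipelineSpec(
            site_correction="none",
            covariate_regression="none",
            name="no_site_no_covariates",
            **common,
        ),
        "leaky_feature_selection": PipelineSpec(
            feature_selection="leaky", name="leaky_feature_selection", **common
        ),
        "leaky_site_correction": PipelineSpec(
            site_correction="leaky", name="leaky_site_correction", **common
        ),
        "leaky_covariate_regression": PipelineSpec(
            covariate_regression="leaky", name="leaky_covariate_regression", **common
        ),
        "family_leakage": PipelineSpec(split="plain", name="family_leakage", **common),
    }
    for pct in subject_pcts:
        key = f"subject_leakage_{pct:g}pct"
        v[key] = PipelineSpec(subject_leakage_pct=float(pct), name=key, **common)
    return v


@dataclass
class PipelineResult:
    """One iteration of one pipeline: aligned predictions and per-fold fits."""

    predictions: np.ndarray  # aligned to the (possibly augmented) dataset rows
    y_true: np.ndarray
    r: float
    q2: float
    fold_test_indices: list[np.ndarray]
    selected_edges: list[np.ndarray]  # per outer fold
    coefficients: list[np.ndarray]  # per outer fold, full edge length
    chosen_alphas: list[Optional[float]]
    spec: PipelineSpec
    model_spec: ModelSpec
    seed: int


def inject_subject_leakage(
    dataset: ConnectomeDataset, pct: float, seed: int
) -> ConnectomeDataset:
    """Duplicate ``round(pct/100 * n)`` randomly chosen subjects verbatim.

    Duplicates get fresh subject ids and fresh singleton family ids, so a
    family-aware split can still separate a duplicate from its source —
    subject leakage deliberately ignores family structure.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError("pct must lie in [0, 100]")
    n = dataset.n_subjects
    m = int(round(pct / 100.0 * n))
    if m == 0:
        return dataset
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=m, replace=False)
    dup_ids = np.array(
        [f"{dataset.subject_ids[i]}__dup{j}" for j, i in enumerate(chosen)]
    )
    dup_fams = np.array([f"__dupfam{j:05d}" for j in range(m)])
    return ConnectomeDataset(
        subject_ids=np.concatenate([dataset.subject_ids, dup_ids]),
        X=np.vstack([dataset.X, dataset.X[chosen]]),
        y=np.concatenate([dataset.y, dataset.y[chosen]]),
        covariates=pd.concat(
            [dataset.covariates, dataset.covariates.iloc[chosen]], ignore_index=True
        ),
        site=np.concatenate([dataset.site, dataset.site[chosen]]),
        family_id=np.concatenate([dataset.family_id, dup_fams]),
    )


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 1000003 + fold) % (2**31 - 1)


def run_pipeline(
    dataset: ConnectomeDataset,
    spec: PipelineSpec,
    model_spec: ModelSpec,
    seed: int,
) -> PipelineResult:
    """Execute one pipeline variant once (see module docstring for order)."""
    data = inject_subject_leakage(dataset, spec.subject_leakage_pct, seed)
    n = data.n_subjects
    X = data.X
    y = data.y
    cov = data.covariates[
        [c for c in data.covariates.columns if c not in set(spec.covariate_exclusions)]
    ]

    fixed_features = None
    if spec.feature_selection == "leaky":
        # fixed edge set from the raw, uncorrected full data
        fixed_features = select_features(X, y, model_spec.feature_fraction)

    def _leaky_site(M):
        return leaky_combat(M, data.site, eb=spec.combat_eb)

    def _leaky_cov(M):
        return leaky_covariates(M, cov)

    stages = (
        (_leaky_site, _leaky_cov)
        if spec.combat_before_covariates
        else (_leaky_cov, _leaky_site)
    )
    for stage in stages:
        if stage is _leaky_site and spec.site_correction == "leaky":
            X = _leaky_site(X)
        if stage is _leaky_cov and spec.covariate_regression == "leaky":
            X = _leaky_cov(X)

    if spec.split == "family_aware":
        folds = family_kfold(data.family_id, spec.outer_k, seed)
    else:
        folds = plain_kfold(n, spec.outer_k, seed)
    _check_partition(folds, n, data.family_id, spec.split)

    predictions = np.empty(n)
    sel_per_fold, coef_per_fold, alpha_per_fold = [], [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr, Xte = X[train_idx], X[test_idx]
        ytr = y[train_idx]

        def _cv_site(A, B):
            m = fit_combat(A, data.site[train_idx], eb=spec.combat_eb)
            return (
                apply_combat(m, A, data.site[train_idx]),
                apply_combat(m, B, data.site[test_idx]),
            )

        def _cv_cov(A, B):
            m = fit_covariates(A, cov.iloc[train_idx])
            return (
                apply_covariates(m, A, cov.iloc[train_idx]),
                apply_covariates(m, B, cov.iloc[test_idx]),
            )

        cv_stages = (
            (_cv_site, _cv_cov)
            if spec.combat_before_covariates
            else (_cv_cov, _cv_site)
        )
        for stage in cv_stages:
            if stage is _cv_site and spec.site_correction == "cv":
                Xtr, Xte = _cv_site(Xtr, Xte)
            if stage is _cv_cov and spec.covariate_regression == "cv":
                Xtr, Xte = _cv_cov(Xtr, Xte)

        model = fit_model(
            Xtr, ytr, model_spec, _fold_seed(seed, f), fixed_features=fixed_features
        )
        predictions[test_idx] = predict_model(model, Xte)
        sel_per_fold.append(model.selected_edges)
        alpha_per_fold.append(model.chosen_alpha)
        try:
            coef_per_fold.append(full_coefficients(model))
        except ValueError:  # model kind without edge-level coefficients
            coef_per_fold.append(np.full(data.n_edges, np.nan))

    return PipelineResult(
        predictions=predictions,
        y_true=y,
        r=pearson_r(y, predictions),
        q2=q_squared(y, predictions),
        fold_test_indices=folds,
        selected_edges=sel_per_fold,
        coefficients=coef_per_fold,
        chosen_alphas=alpha_per_fold,
        spec=spec,
        model_spec=model_spec,
        seed=seed,
    )


def _check_partition(folds, n, family_id, split):
    """Every outer split must partition all rows; family-aware splits must
    never separate a family.  Asserted on every run."""
    allidx = np.concatenate(folds)
    if len(allidx) != n or len(np.unique(allidx)) != n:
        raise AssertionError("outer folds do not partition the subjects")
    if split == "family_aware":
        fold_of = np.empty(n, dtype=int)
        for f, idx in enumerate(folds):
            fold_of[idx] = f
        df = pd.DataFrame({"fam": family_id, "fold": fold_of})
        if (df.groupby("fam")["fold"].nunique() > 1).any():
            raise AssertionError("a family spans multiple folds")


@dataclass
class IterationResults:
    """Results of repeated k-fold iterations plus their median metrics."""

    results: list[PipelineResult]
    median_r: float
    median_q2: float

    def metrics_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": range(len(self.results)),
                "seed": [res.seed for res in self.results],
                "r": [res.r for res in self.results],
                "q2": [res.q2 for res in self.results],
            }
        )


def run_iterations(
    dataset: ConnectomeDataset,
    spec: PipelineSpec,
    model_spec: ModelSpec,
    n_iters: int,
    base_seed: int,
) -> IterationResults:
    """Repeat the pipeline over split seeds ``base_seed + i`` and take medians."""
    results = [
        run_pipeline(dataset, spec, model_spec, base_seed + i) for i in range(n_iters)
    ]
    return IterationResults(
        results=results,
        median_r=float(np.median([res.r for res in results])),
        median_q2=float(np.median([res.q2 for res in results])),
    )


@dataclass
class LeakageDelta:
    """Performance difference of a leaky pipeline against its gold match."""

    delta_r: float
    delta_q2: float
    leaky: PipelineResult
    gold: PipelineResult


def delta_vs_gold(
    dataset: ConnectomeDataset,
    leaky_spec: PipelineSpec,
    model_spec: ModelSpec,
    seed: int,
    gold_spec: Optional[PipelineSpec] = None,
) -> LeakageDelta:
    """Delta r and delta q^2 of ``leaky_spec`` against the gold standard.

    Both pipelines run with the same split seed, so fold assignments agree
    wherever the two splitting rules coincide and the difference isolates
    the leakage itself rather than split noise.
    """
    if gold_spec is None:
        gold_spec = gold_counterpart(leaky_spec)
    leaky = run_pipeline(dataset, leaky_spec, model_spec, seed)
    gold = run_pipeline(dataset, gold_spec, model_spec, seed)
    return LeakageDelta(
        delta_r=leaky.r - gold.r, delta_q2=leaky.q2 - gold.q2, leaky=leaky, gold=gold
    )


def _resample_families(dataset, size, rng) -> np.ndarray:
    """Indices of a family-wise subsample with at most ``size`` subjects.

    Families are drawn in random order and added while the running subject
    count stays <= size (stopping below rather than overshooting)."""
    codes, uniques = pd.factorize(dataset.family_id)
    members = [np.flatnonzero(codes == f) for f in range(len(uniques))]
    fam_sizes = np.array([len(m) for m in members])
    if size < fam_sizes.max():
        raise ValueError(
            f"target size {size} is smaller than the largest family "
            f"({fam_sizes.max()} subjects)"
        )
    order = rng.permutation(len(uniques))
    keep, total = [], 0
    for f in order:
        if total + fam_sizes[f] <= size:
            keep.append(f)
            total += fam_sizes[f]
    return np.sort(np.concatenate([members[f] for f in keep]))


def subsample_experiment(
    dataset: ConnectomeDataset,
    sizes: Sequence[int],
    n_resamples: int,
    n_iters: int,
    leaky_specs: dict[str, PipelineSpec],
    model_spec: ModelSpec,
    base_seed: int,
    largest_sites: Optional[int] = None,
) -> pd.DataFrame:
    """Delta r per (size, spec, resample, iteration), resampling by family.

    ``largest_sites`` optionally restricts the pool to the top-k sites by
    subject count before resampling (so cross-validated ComBat never sees a
    near-empty site).  Returns a tidy table; see
    :func:`summarize_subsample` for per-resample medians.
    """
    pool = dataset
    if largest_sites is not None:
        counts = pd.Series(dataset.site).value_counts()
        keep_sites = set(counts.index[:largest_sites])
        pool = dataset.subset(
            np.flatnonzero(np.isin(dataset.site, list(keep_sites)))
        )
    if max(sizes) > pool.n_subjects:
        raise ValueError("requested size exceeds the (filtered) dataset")

    rows = []
    for si, size in enumerate(sizes):
        for rs in range(n_resamples):
            ss = np.random.SeedSequence([base_seed, si, rs])
            rng = np.random.default_rng(ss)
            idx = _resample_families(pool, size, rng)
            sub = pool.subset(idx)
            iter_seeds = rng.integers(0, 2**31 - 1, size=n_iters)
            for name, lspec in leaky_specs.items():
                for it in range(n_iters):
                    d = delta_vs_gold(sub, lspec, model_spec, int(iter_seeds[it]))
                    rows.append(
                        {
                            "size": size,
                            "actual_n": sub.n_subjects,
                            "spec": name,
                            "resample": rs,
                            "iteration": it,
                            "delta_r": d.delta_r,
                            "delta_q2": d.delta_q2,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_subsample(table: pd.DataFrame) -> pd.DataFrame:
    """Median-across-iterations delta r/q^2 per (size, spec, resample)."""
    return (
        table.groupby(["size", "spec", "resample"])[["delta_r", "delta_q2"]]
        .median()
        .reset_index()
    )


def family_sweep(
    base_config: SyntheticConfig,
    fractions: Sequence[float],
    model_spec: ModelSpec,
    n_iters: int,
    outer_k: int = 5,
) -> pd.DataFrame:
    """Family-leakage delta r as a function of the multi-member-family share.

    For each fraction a fresh cohort is generated and the plain-split
    pipeline is compared against the family-aware gold standard over
    ``n_iters`` paired split seeds.  Site correction and covariate
    regression are left out: the sweep isolates the split rule.
    """
    leaky = PipelineSpec(
        site_correction="none",
        covariate_regression="none",
        split="plain",
        outer_k=outer_k,
        name="family_leakage",
    )
    rows = []
    for cfg in family_fraction_grid(base_config, fractions):
        ds = generate_dataset(cfg)
        for it in range(n_iters):
            d = delta_vs_gold(ds, leaky, model_spec, cfg.seed + it)
            rows.append(
                {
                    "family_fraction": cfg.family_fraction,
                    "iteration": it,
                    "delta_r": d.delta_r,
                    "delta_q2": d.delta_q2,
                }
            )
    return pd.DataFrame(rows)
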