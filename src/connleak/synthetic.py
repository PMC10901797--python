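"""Synthetic connectome-like datasets with known generative structure.

The generator emulates the statistical features of developmental
neuroimaging cohorts that matter for leakage benchmarking, without
attempting to match any real dataset's marginal distributions:

* a single latent brain-behavior factor ``s`` loading on a subset of edges,
  with the population R-squared of phenotype on ``s`` set exactly by
  ``effect_size`` (strong / moderate / null regimes);
* twin-like families (size 2): within a pair, the latent factor, the
  edge-level noise, and the phenotype noise each share a common component
  with correlation ``family_rho`` (a stylized rendering of connectome and
  phenotype heritability), and age is shared exactly;
* additive and multiplicative per-site, per-edge effects on the features;
* covariates (age, sex, head motion) that can load on both features and
  phenotype, creating genuine confounding.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ConnectomeDataset

__all__ = [
    "CovariateEffect",
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_dataset_with_truth",
    "null_dataset",
    "family_fraction_grid",
]


@dataclass(frozen=True)
class CovariateEffect:
    """Loadings of one covariate on features and on the phenotype.

    ``on_features`` is the SD of the per-edge loading (each edge gets its
    own coefficient drawn from N(0, on_features^2), applied to the
    population-standardized covariate); ``on_phenotype`` is the fixed
    coefficient of the standardized covariate in the phenotype model.
    """

    on_features: float = 0.0
    on_phenotype: float = 0.0


def _default_covariate_effects() -> dict[str, CovariateEffect]:
    return {
        "age": CovariateEffect(),
        "sex": CovariateEffect(),
        "motion": CovariateEffect(),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic cohort.

    Defaults describe a moderate-signal, single-site cohort of unrelated
    subjects: 200 subjects, a 100-node parcellation (4950 edges), 100 signal
    edges whose loadings have SD 0.3 in units of the unit-variance edge
    noise, and a phenotype with 20% of variance explained by the latent
    factor.
    """

    n_subjects: int = 200
    n_nodes: int = 100
    effect_size: float = 0.2
    n_signal_edges: int = 100
    signal_edge_sd: float = 0.3
    family_fraction: float = 0.0
    family_rho: float = 0.5
    n_sites: int = 1
    site_shift_sd: float = 0.0
    site_scale_range: tuple[float, float] = (1.0, 1.0)
    covariate_effects: Mapping[str, CovariateEffect] = field(
        default_factory=_default_covariate_effects
    )
    age_range: tuple[float, float] = (8.0, 22.0)
    motion_log_mean: float = -2.2  # median FD ~0.11 mm
    motion_log_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must lie in [0, 1)")
        if not 0.0 <= self.family_fraction <= 1.0:
            raise ValueError("family_fraction must lie in [0, 1]")
        if not 0.0 <= self.family_rho <= 1.0:
            raise ValueError("family_rho must lie in [0, 1]")
        if self.n_signal_edges > self.n_edges:
            raise ValueError(
                f"n_signal_edges={self.n_signal_edges} exceeds "
                f"n_edges={self.n_edges}"
            )
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.site_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("site_scale_range must be 0 < lo <= hi")
        effects = {
            k: v if isinstance(v, CovariateEffect) else CovariateEffect(*v)
            for k, v in dict(self.covariate_effects).items()
        }
        object.__setattr__(self, "covariate_effects", effects)

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2


@dataclass
class GroundTruth:
    """Oracle quantities of a generated dataset (not visible to pipelines)."""

    latent: np.ndarray  # per-subject latent factor s
    signal_edges: np.ndarray  # indices of edges carrying signal
    edge_loadings: np.ndarray  # loading w_e per signal edge
    phenotype_loading: float  # coefficient a of s in the phenotype model


def _paired_normal(rng, n_pairs: int, n_single: int, rho: float, size=()):
    """Draw values for paired + singleton subjects with within-pair corr rho.

    Returns an array of shape (2*n_pairs + n_single, *size); consecutive
    rows 0..2*n_pairs-1 are pairs.
    """
    shared = rng.standard_normal((n_pairs, *size))
    own = rng.standard_normal((2 * n_pairs, *size))
    paired = np.sqrt(rho) * np.repeat(shared, 2, axis=0) + np.sqrt(1 - rho) * own
    single = rng.standard_normal((n_single, *size))
    return np.concatenate([paired, single], axis=0)


def _covariate_standardizers(config: SyntheticConfig):
    """Population mean/SD of each raw covariate, for analytic standardization."""
    lo, hi = config.age_range
    age = ((lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0))
    sex = (0.5, 0.5)
    mu, sg = config.motion_log_mean, config.motion_log_sd
    m_mean = np.exp(mu + sg**2 / 2.0)
    m_sd = np.sqrt((np.exp(sg**2) - 1.0) * np.exp(2 * mu + sg**2))
    return {"age": age, "sex": sex, "motion": (m_mean, m_sd)}


def generate_dataset_with_truth(
    config: SyntheticConfig,
) -> tuple[ConnectomeDataset, GroundTruth]:
    """Generate a dataset and return the generative ground truth alongside it."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_edges
    n_paired = 2 * int(round(config.family_fraction * n / 2.0))
    n_pairs = n_paired // 2
    n_single = n - n_paired
    rho = config.family_rho

    # subjects 0..n_paired-1 are consecutive twin pairs, then singletons
    family_id = np.empty(n, dtype=object)
    family_id[:n_paired] = np.repeat(
        [f"fam{i:05d}" for i in range(n_pairs)], 2
    )
    family_id[n_paired:] = [f"solo{i:05d}" for i in range(n_single)]
    subject_ids = np.array([f"sub{i:05d}" for i in range(n)])

    # (1) latent brain-behavior factor, shared within pairs
    s = _paired_normal(rng, n_pairs, n_single, rho)

    # (2) covariates; age is shared exactly within a family
    lo, hi = config.age_range
    age_fam = rng.uniform(lo, hi, size=n_pairs)
    age = np.concatenate([np.repeat(age_fam, 2), rng.uniform(lo, hi, size=n_single)])
    sex = rng.integers(0, 2, size=n).astype(float)
    motion = np.exp(
        config.motion_log_mean + config.motion_log_sd * rng.standard_normal(n)
    )
    raw_cov = {"age": age, "sex": sex, "motion": motion}
    standardizers = _covariate_standardizers(config)
    std_cov = {
        k: (raw_cov[k] - m) / sd for k, (m, sd) in standardizers.items()
    }

    # (3) edge features: family-correlated unit noise + latent signal
    #     on the signal edges + covariate loadings, then site effects
    X = _paired_normal(rng, n_pairs, n_single, rho, size=(p,))
    signal_edges = np.sort(rng.choice(p, size=config.n_signal_edges, replace=False))
    w = config.signal_edge_sd * rng.standard_normal(config.n_signal_edges)
    X[:, signal_edges] += np.outer(s, w)
    for name, eff in config.covariate_effects.items():
        if eff.on_features != 0.0:
            loads = eff.on_features * rng.standard_normal(p)
            X += np.outer(std_cov[name], loads)

    site = rng.integers(0, config.n_sites, size=n)
    site_labels = np.array([f"site{i}" for i in range(config.n_sites)])
    if config.n_sites > 1:
        gamma = config.site_shift_sd * rng.standard_normal((config.n_sites, p))
        delta = rng.uniform(*config.site_scale_range, size=(config.n_sites, p))
        X = delta[site] * X + gamma[site]

    # (4) phenotype: a*s + covariate effects + family-correlated noise,
    #     with a set so the population R^2 of y on s equals effect_size
    var_cov = sum(e.on_phenotype**2 for e in config.covariate_effects.values())
    var_noise = config.noise_sd**2
    e = config.effect_size
    a = np.sqrt(e / (1.0 - e) * (var_cov + var_noise))
    eps = config.noise_sd * _paired_normal(rng, n_pairs, n_single, rho)
    y = a * s + eps
    for name, eff in config.covariate_effects.items():
        y = y + eff.on_phenotype * std_cov[name]

    dataset = ConnectomeDataset(
        subject_ids=subject_ids,
        X=X,
        y=y,
        covariates=pd.DataFrame(raw_cov),
        site=site_labels[site],
        family_id=family_id.astype(str),
    )
    truth = GroundTruth(
        latent=s, signal_edges=signal_edges, edge_loadings=w, phenotype_loading=a
    )
    return dataset, truth


def generate_dataset(config: SyntheticConfig) -> ConnectomeDataset:
    """Generate a synthetic cohort (see module docstring for the model)."""
    return generate_dataset_with_truth(config)[0]


def null_dataset(n_subjects: int, n_nodes: int, seed: int) -> ConnectomeDataset:
    """All structure off: iid normal edges, phenotype independent of them."""
    config = SyntheticConfig(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        effect_size=0.0,
        n_signal_edges=0,
        family_fraction=0.0,
        n_sites=1,
        site_shift_sd=0.0,
        site_scale_range=(1.0, 1.0),
        covariate_effects={},
        seed=seed,
    )
    return generate_dataset(config)


def family_fraction_grid(
    base_config: SyntheticConfig, fractions
) -> list[SyntheticConfig]:
    """Configs identical to ``base_config`` except for ``family_fraction``.

    Each config gets a deterministic per-fraction seed offset so the cohorts
    are independent draws.
    """
    fractions = list(fractions)
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    return [
        replace(base_config, family_fraction=f, seed=base_config.seed + 1000 * i)
        for i, f in enumerate(fractions)
    ]
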