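"""Site harmonization (ComBat) and covariate regression.

Both corrections come in a non-leaky form (parameters estimated on training
data only, then applied to unseen data) and a leaky form (parameters
estimated on the full dataset).  The leaky entry points are plain
compositions of fit + apply on the concatenated data; they exist so that
pipelines declare leakage explicitly rather than by accident.

Covariate regression residualizes each feature on a design matrix
C = [1, covariates] via ordinary least squares:

    beta_hat = argmin ||X - C beta||^2 ,    X_adjusted = X - C beta_hat

ComBat is the standard location/scale harmonization: per feature, the data
are standardized by the overall mean and pooled within-site SD; per-site
additive (gamma) and multiplicative (delta) effects are estimated on the
standardized scale and removed; optional parametric empirical-Bayes
shrinkage pulls the per-site, per-feature estimates toward across-feature
priors (normal for gamma, moment-matched inverse-gamma for delta squared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CovariateModel",
    "ComBatModel",
    "fit_covariates",
    "apply_covariates",
    "leaky_covariates",
    "fit_combat",
    "apply_combat",
    "leaky_combat",
]


def _as_design(covariates, covariate_names=None) -> tuple[np.ndarray, list[str]]:
    """Build C = [1, covariates] from a DataFrame or array; intercept first."""
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        raw = covariates.to_numpy(dtype=float)
    else:
        raw = np.asarray(covariates, dtype=float)
        if raw.ndim == 1:
            raw = raw[:, None]
        names = (
            list(covariate_names)
            if covariate_names is not None
            else [f"cov{i}" for i in range(raw.shape[1])]
        )
    if raw.shape[1] != len(names):
        raise ValueError("covariate_names length does not match column count")
    C = np.column_stack([np.ones(raw.shape[0]), raw])
    return C, names


def _collinear_columns(C: np.ndarray, names: list[str]) -> list[str]:
    """Names of covariate columns involved in a rank deficiency."""
    bad = []
    full = ["intercept"] + names
    for j in range(C.shape[1]):
        others = np.delete(C, j, axis=1)
        resid = C[:, j] - others @ np.linalg.lstsq(others, C[:, j], rcond=None)[0]
        denom = max(np.linalg.norm(C[:, j]), 1.0)
        if np.linalg.norm(resid) / denom < 1e-10:
            bad.append(full[j])
    return bad


@dataclass
class CovariateModel:
    """OLS coefficients for residualizing features on covariates.

    ``beta_hat`` has shape (k+1, p) with the intercept row first;
    ``covariate_names`` fixes the required column order of any covariates
    passed to :func:`apply_covariates`.
    """

    beta_hat: np.ndarray
    covariate_names: list[str]


def fit_covariates(X_train, covariates, covariate_names=None) -> CovariateModel:
    """Estimate beta_hat = (C'C)^-1 C'X on training data (stable lstsq solve).

    ``covariates`` is the raw covariate table (DataFrame or array); the
    intercept column is added internally.  Raises on rank-deficient designs,
    naming the collinear columns.
    """
    X = np.asarray(X_train, dtype=float)
    C, names = _as_design(covariates, covariate_names)
    if C.shape[0] != X.shape[0]:
        raise ValueError("covariates and X_train must have the same number of rows")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError(
            f"covariate design is rank-deficient; collinear columns: "
            f"{_collinear_columns(C, names)}"
        )
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    return CovariateModel(beta_hat=beta, covariate_names=names)


def apply_covariates(model: CovariateModel, X, covariates, covariate_names=None):
    """Residualize X on the model's covariates: X - C beta_hat.

    The covariate columns must match ``model.covariate_names`` by name and
    order; silent reordering is forbidden.
    """
    X = np.asarray(X, dtype=float)
    C, names = _as_design(covariates, covariate_names)
    if names != list(model.covariate_names):
        raise ValueError(
            f"covariate name/order mismatch: model expects "
            f"{list(model.covariate_names)}, got {names}"
        )
    if C.shape[1] != model.beta_hat.shape[0]:
        raise ValueError("covariate count does not match the fitted model")
    return X - C @ model.beta_hat


def leaky_covariates(X_full, covariates, covariate_names=None):
    """Full-data covariate regression (leaky): fit and apply on everything."""
    model = fit_covariates(X_full, covariates, covariate_names)
    return apply_covariates(model, X_full, covariates, covariate_names)


# ---------------------------------------------------------------------------
# ComBat


@dataclass
class ComBatModel:
    """Per-site location/scale harmonization parameters.

    ``gamma_star`` and ``delta_star`` are (n_sites, p) arrays on the
    standardized scale, one row per entry of ``known_sites``; ``alpha_hat``
    is the per-feature overall mean and ``pooled_sd`` the per-feature pooled
    within-site SD used for standardization.
    """

    alpha_hat: np.ndarray
    pooled_sd: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    known_sites: list
    eb: bool


def _eb_shrink(Z_site: np.ndarray, gamma_hat: np.ndarray, delta2_hat: np.ndarray):
    """Parametric empirical-Bayes shrinkage for one site (iterative solution).

    gamma ~ N(gamma_bar, tau2) across features; delta^2 ~ InvGamma with
    moments matched to the across-feature spread of delta2_hat.  Degenerate
    across-feature spreads (a single feature, or identical estimates) leave
    the raw estimates untouched.
    """
    n = Z_site.shape[0]
    gamma_bar = float(np.mean(gamma_hat))
    tau2 = float(np.var(gamma_hat, ddof=1)) if gamma_hat.size > 1 else 0.0
    m = float(np.mean(delta2_hat))
    s2 = float(np.var(delta2_hat, ddof=1)) if delta2_hat.size > 1 else 0.0
    if tau2 <= 0.0 or s2 <= 0.0:
        return gamma_hat.copy(), delta2_hat.copy()
    aprior = (2.0 * s2 + m**2) / s2
    bprior = (m * s2 + m**3) / s2

    g_new = gamma_hat.copy()
    d_new = delta2_hat.copy()
    for _ in range(200):
        g_old, d_old = g_new, d_new
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sum2 = np.sum((Z_site - g_new) ** 2, axis=0)
        d_new = (0.5 * sum2 + bprior) / (n / 2.0 + aprior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        if change < 1e-4:
            break
    return g_new, d_new


def fit_combat(X_train, sites_train, eb: bool = True) -> ComBatModel:
    """Estimate ComBat parameters on training data only.

    Every training site needs >= 2 subjects (the scale is undefined
    otherwise).  With ``eb`` the per-site parameters are shrunk toward
    across-feature priors; without, the raw location/scale estimates are
    used, which makes the correction exactly idempotent.
    """
    X = np.asarray(X_train, dtype=float)
    sites = np.asarray(sites_train)
    if X.shape[0] != sites.shape[0]:
        raise ValueError("sites_train must align with X_train rows")
    labels = list(pd.unique(sites))
    counts = {lab: int(np.sum(sites == lab)) for lab in labels}
    tiny = [lab for lab, c in counts.items() if c < 2]
    if tiny:
        raise ValueError(f"sites with a single training subject: {tiny}")

    alpha = X.mean(axis=0)
    site_means = np.vstack([X[sites == lab].mean(axis=0) for lab in labels])
    idx = np.array([labels.index(s) for s in sites])
    resid = X - site_means[idx]
    pooled_var = np.mean(resid**2, axis=0)
    if np.any(pooled_var <= 0.0):
        raise ValueError("zero pooled variance for some features; cannot standardize")
    pooled_sd = np.sqrt(pooled_var)

    Z = (X - alpha) / pooled_sd
    gamma = np.empty((len(labels), X.shape[1]))
    delta2 = np.empty_like(gamma)
    for i, lab in enumerate(labels):
        Zi = Z[sites == lab]
        gamma[i] = Zi.mean(axis=0)
        delta2[i] = Zi.var(axis=0)  # ddof=0: makes eb-off correction idempotent
        if np.any(delta2[i] <= 0.0):
            raise ValueError(f"zero within-site variance at site {lab!r}")
        if eb:
            gamma[i], delta2[i] = _eb_shrink(Zi, gamma[i], delta2[i])

    return ComBatModel(
        alpha_hat=alpha,
        pooled_sd=pooled_sd,
        gamma_star=gamma,
        delta_star=np.sqrt(delta2),
        known_sites=labels,
        eb=eb,
    )


def apply_combat(model: ComBatModel, X, sites) -> np.ndarray:
    """Harmonize X using training-derived parameters.

    Each subject is corrected with its own site's parameters; a site label
    absent from ``model.known_sites`` is an error (a cross-validated ComBat
    cannot harmonize a site it has never seen).  A model fit on a single
    site is an exact identity.
    """
    X = np.asarray(X, dtype=float)
    sites = np.asarray(sites)
    unknown = [s for s in pd.unique(sites) if s not in model.known_sites]
    if unknown:
        raise ValueError(f"unseen site label(s) in data: {unknown}")
    if len(model.known_sites) == 1:
        return X.copy()
    idx = np.array([model.known_sites.index(s) for s in sites])
    Z = (X - model.alpha_hat) / model.pooled_sd
    Z_adj = (Z - model.gamma_star[idx]) / model.delta_star[idx]
    return Z_adj * model.pooled_sd + model.alpha_hat


def leaky_combat(X_full, sites_full, eb: bool = True) -> np.ndarray:
    """Full-data ComBat (leaky): fit and apply on the concatenated data."""
    model = fit_combat(X_full, sites_full, eb=eb)
    return apply_combat(model, X_full, sites_full)
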