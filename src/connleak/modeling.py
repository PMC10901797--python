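"""Predictive models: ridge with nested hyperparameter search, and CPM.

All fitting functions operate strictly on the data they are handed; whether
that data is contaminated is the caller's (the pipeline's) decision.

The baseline model is ridge regression on the top fraction of edges most
correlated (in absolute value) with the phenotype.  The L2 penalty is chosen
by an inner k-fold grid search: within each inner training partition the
features are re-selected and a ridge path over the whole grid is fit via a
single SVD; inner-fold predictions are concatenated per grid value and the
penalty with the highest Pearson r wins (ties go to the strongest
regularization).

Connectome-based predictive modeling (CPM) selects the same top edges,
splits them by the sign of their training correlation with the phenotype,
sums positive-edge values minus negative-edge values into a single score
per subject, and fits a univariate regression of phenotype on that score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .splits import plain_kfold

__all__ = [
    "ModelSpec",
    "FittedModel",
    "select_features",
    "fit_ridge_nested",
    "predict_ridge",
    "fit_cpm",
    "predict_cpm",
    "fit_model",
    "predict_model",
    "full_coefficients",
]

_DEFAULT_GRID = tuple(10.0 ** np.arange(-3, 4))


@dataclass(frozen=True)
class ModelSpec:
    """Model family and its tuning parameters.

    ``alpha_grid`` is the ridge L2 grid (default 10^-3..10^3); ``inner_k``
    the nested fold count for the grid search; ``feature_fraction`` the
    fraction of edges kept by univariate selection.
    """

    kind: str = "ridge"
    alpha_grid: tuple[float, ...] = _DEFAULT_GRID
    c_grid: tuple[float, ...] = _DEFAULT_GRID
    inner_k: int = 5
    feature_fraction: float = 0.05

    def __post_init__(self):
        if self.kind not in {"ridge", "cpm", "rbf_svr"}:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(self.alpha_grid) == 0 or any(a <= 0 for a in self.alpha_grid):
            raise ValueError("alpha_grid must be non-empty and positive")
        if len(self.c_grid) == 0 or any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid must be non-empty and positive")
        if not 0.0 < self.feature_fraction <= 1.0:
            raise ValueError("feature_fraction must lie in (0, 1]")
        if self.inner_k < 2:
            raise ValueError("inner_k must be >= 2")


@dataclass
class FittedModel:
    """A trained model: selected edges plus kind-specific parameters.

    For ridge, ``coefficients`` aligns with ``selected_edges`` and
    ``intercept`` completes the linear predictor.  For CPM, ``cpm_signs``
    holds the +1/-1 edge signs and ``coefficients``/``intercept`` the slope
    and intercept of the univariate line on the summary score.
    """

    kind: str
    selected_edges: np.ndarray
    coefficients: np.ndarray
    intercept: float
    n_features_in: int
    chosen_alpha: Optional[float] = None
    cpm_signs: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X with y; zero-variance columns get r=0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    sy = np.sqrt(np.sum(yc**2))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
    r[denom == 0.0] = 0.0
    return np.nan_to_num(r, nan=0.0)


def select_features(X, y, fraction: float) -> np.ndarray:
    """Indices of the top ``max(1, floor(fraction*p))`` edges by |Pearson r|.

    For a fixed sample size, ranking by p-value of the correlation test is
    equivalent to ranking by |r|.  Ties break toward the smaller edge index;
    zero-variance edges get r = 0.  Returns sorted indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("feature selection needs at least 3 subjects")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    p = X.shape[1]
    k = max(1, int(np.floor(fraction * p)))
    r = _pearson_columns(X, y)
    order = np.argsort(-np.abs(r), kind="stable")  # ties -> smallest index
    return np.sort(order[:k])


def _ridge_path(X: np.ndarray, y: np.ndarray, alphas) -> tuple[np.ndarray, np.ndarray]:
    """Ridge solutions for every alpha from one SVD of the centered design.

    Solves min ||y - X b - b0||^2 + alpha ||b||^2 (intercept unpenalized).
    Returns (coefs, intercepts) with coefs of shape (n_alphas, p).
    """
    alphas = np.asarray(alphas, dtype=float)
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    yc = y - ybar
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    Uty = U.T @ yc
    # d has shape (n_alphas, rank)
    d = s[None, :] / (s[None, :] ** 2 + alphas[:, None])
    coefs = (d * Uty[None, :]) @ Vt
    intercepts = ybar - coefs @ xbar
    return coefs, intercepts


def fit_ridge_nested(
    X_train,
    y_train,
    spec: ModelSpec,
    seed: int,
    fixed_features: Optional[np.ndarray] = None,
) -> FittedModel:
    """Ridge with feature selection and an inner-k-fold grid search.

    Inner splits are plain shuffled folds of the training data.  Unless
    ``fixed_features`` is given (leaky-selection pipelines), features are
    re-selected inside each inner training partition and once more on the
    full training set for the final fit.  Per grid value, inner predictions
    are concatenated and scored with a single Pearson r; ties prefer the
    largest alpha.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape
    alphas = np.asarray(spec.alpha_grid, dtype=float)
    if n <= spec.inner_k:
        raise ValueError(f"need more than inner_k={spec.inner_k} training rows")

    if len(alphas) == 1:
        best_alpha = float(alphas[0])
    else:
        folds = plain_kfold(n, spec.inner_k, seed)
        preds = np.empty((n, len(alphas)))
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            Xi, yi = X[train_idx], y[train_idx]
            sel = (
                fixed_features
                if fixed_features is not None
                else select_features(Xi, yi, spec.feature_fraction)
            )
            coefs, intercepts = _ridge_path(Xi[:, sel], yi, alphas)
            preds[test_idx] = X[np.ix_(test_idx, sel)] @ coefs.T + intercepts
        scores = np.array([_safe_r(y, preds[:, j]) for j in range(len(alphas))])
        best = max(range(len(alphas)), key=lambda j: (scores[j], alphas[j]))
        best_alpha = float(alphas[best])

    sel = (
        np.asarray(fixed_features, dtype=int)
        if fixed_features is not None
        else select_features(X, y, spec.feature_fraction)
    )
    coefs, intercepts = _ridge_path(X[:, sel], y, np.array([best_alpha]))
    return FittedModel(
        kind="ridge",
        selected_edges=np.asarray(sel, dtype=int),
        coefficients=coefs[0],
        intercept=float(intercepts[0]),
        n_features_in=p,
        chosen_alpha=best_alpha,
    )


def _safe_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, or -inf when either vector is (numerically) constant."""
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


def predict_ridge(model: FittedModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in:
        raise ValueError(
            f"X has {X.shape[1]} edges; model was trained with {model.n_features_in}"
        )
    return X[:, model.selected_edges] @ model.coefficients + model.intercept


def fit_cpm(
    X_train,
    y_train,
    spec: ModelSpec,
    seed: int = 0,
    fixed_features: Optional[np.ndarray] = None,
) -> FittedModel:
    """Connectome-based predictive modeling on the selected edges.

    The per-subject score is (sum of positively correlated selected edges)
    minus (sum of negatively correlated selected edges); a single-sign
    selection is valid (the absent sign contributes nothing).
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    sel = (
        np.asarray(fixed_features, dtype=int)
        if fixed_features is not None
        else select_features(X, y, spec.feature_fraction)
    )
    r = _pearson_columns(X[:, sel], y)
    signs = np.where(r >= 0.0, 1.0, -1.0)
    score = X[:, sel] @ signs
    if np.std(score) == 0.0:
        raise ValueError("CPM summary score has zero variance")
    slope, intercept = np.polyfit(score, y, 1)
    return FittedModel(
        kind="cpm",
        selected_edges=sel,
        coefficients=np.array([slope]),
        intercept=float(intercept),
        n_features_in=X.shape[1],
        cpm_signs=signs,
    )


def predict_cpm(model: FittedModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in:
        raise ValueError(
            f"X has {X.shape[1]} edges; model was trained with {model.n_features_in}"
        )
    score = X[:, model.selected_edges] @ model.cpm_signs
    return model.coefficients[0] * score + model.intercept


def fit_model(
    X_train, y_train, spec: ModelSpec, seed: int, fixed_features=None
) -> FittedModel:
    """Dispatch to the model family named in ``spec.kind``."""
    if spec.kind == "ridge":
        return fit_ridge_nested(X_train, y_train, spec, seed, fixed_features)
    if spec.kind == "cpm":
        return fit_cpm(X_train, y_train, spec, seed, fixed_features)
    if spec.kind == "rbf_svr":
        return _fit_rbf_svr(X_train, y_train, spec, seed, fixed_features)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def predict_model(model: FittedModel, X) -> np.ndarray:
    if model.kind == "ridge":
        return predict_ridge(model, X)
    if model.kind == "cpm":
        return predict_cpm(model, X)
    if model.kind == "rbf_svr":
        return _predict_rbf_svr(model, X)
    raise ValueError(f"unknown model kind {model.kind!r}")


def _fit_rbf_svr(X_train, y_train, spec, seed, fixed_features=None) -> FittedModel:
    """RBF support-vector regression with an inner grid search over C.

    Delegates to scikit-learn; conforms to the same contract as the other
    models but carries no edge-level coefficients.
    """
    from sklearn.svm import SVR

    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n = X.shape[0]
    cs = np.asarray(spec.c_grid, dtype=float)
    if len(cs) == 1:
        best_c = float(cs[0])
    else:
        folds = plain_kfold(n, spec.inner_k, seed)
        preds = np.empty((n, len(cs)))
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            sel = (
                fixed_features
                if fixed_features is not None
                else select_features(X[train_idx], y[train_idx], spec.feature_fraction)
            )
            for j, c in enumerate(cs):
                est = SVR(kernel="rbf", C=c).fit(X[np.ix_(train_idx, sel)], y[train_idx])
                preds[test_idx, j] = est.predict(X[np.ix_(test_idx, sel)])
        scores = [_safe_r(y, preds[:, j]) for j in range(len(cs))]
        best = max(range(len(cs)), key=lambda j: (scores[j], cs[j]))
        best_c = float(cs[best])
    sel = (
        np.asarray(fixed_features, dtype=int)
        if fixed_features is not None
        else select_features(X, y, spec.feature_fraction)
    )
    est = SVR(kernel="rbf", C=best_c).fit(X[:, sel], y)
    return FittedModel(
        kind="rbf_svr",
        selected_edges=sel,
        coefficients=np.zeros(len(sel)),
        intercept=0.0,
        n_features_in=X.shape[1],
        chosen_alpha=best_c,
        extra={"estimator": est},
    )


def _predict_rbf_svr(model: FittedModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in:
        raise ValueError("edge dimensionality mismatch")
    return model.extra["estimator"].predict(X[:, model.selected_edges])


def full_coefficients(model: FittedModel, n_edges: Optional[int] = None) -> np.ndarray:
    """Embed a model's edge weights into full edge space (zeros elsewhere).

    For CPM the edge "coefficients" are the +/-1 signs times the univariate
    slope — a convention, flagged as such, since CPM is not edge-linear in
    the same sense as ridge.
    """
    p = n_edges if n_edges is not None else model.n_features_in
    out = np.zeros(p)
    if model.kind == "ridge":
        out[model.selected_edges] = model.coefficients
    elif model.kind == "cpm":
        out[model.selected_edges] = model.cpm_signs * model.coefficients[0]
    else:
        raise ValueError(f"no edge-level coefficients for kind {model.kind!r}")
    return out
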