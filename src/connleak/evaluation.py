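"""Performance metrics and model-interpretation comparisons.

Metrics follow the field's convention for connectome-based prediction:
Pearson's r between observed and predicted phenotype, and the
cross-validation R-squared

    q^2 = 1 - sum((y - y_pred)^2) / sum((y - ybar)^2)

with ybar the mean of the observed phenotype over the concatenated
predictions.  q^2 can be substantially negative when predictions are worse
than predicting the mean; it is never clipped.

Interpretation comparisons: fold-averaged coefficient vectors and their
Pearson similarity, and the distribution of selected edges over
subnetworks (unordered pairs of canonical networks), size-adjusted and
compared by Spearman rank correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Parcellation, edge_subnetwork_map, n_subnetworks

logger = logging.getLogger(__name__)

__all__ = [
    "MetricPair",
    "CoefficientVector",
    "pearson_r",
    "q_squared",
    "concat_metrics",
    "average_coefficients",
    "coefficient_similarity",
    "subnetwork_counts",
    "subnetwork_rank_similarity",
]


@dataclass(frozen=True)
class MetricPair:
    r: float
    q2: float


@dataclass
class CoefficientVector:
    """Fold-averaged, full-edge-length model weights plus provenance."""

    values: np.ndarray
    provenance: dict


def pearson_r(y, y_pred) -> float:
    """Pearson correlation of observed vs predicted phenotype.

    A constant input makes the correlation undefined; this is surfaced as
    NaN with a warning, never silently coerced to 0.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValueError("y and y_pred must be 1-d arrays of equal length")
    if y.size < 3:
        raise ValueError("pearson_r needs at least 3 observations")
    if np.std(y) == 0.0 or np.std(y_pred) == 0.0:
        warnings.warn("pearson_r undefined for constant input; returning NaN")
        return float("nan")
    return float(np.corrcoef(y, y_pred)[0, 1])


def q_squared(y, y_pred) -> float:
    """Cross-validation R-squared (may be negative; see module docstring)."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValueError("y and y_pred must be 1-d arrays of equal length")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("q_squared undefined: observed phenotype is constant")
    sse = float(np.sum((y - y_pred) ** 2))
    return 1.0 - sse / sst


def concat_metrics(fold_predictions) -> MetricPair:
    """One r and one q^2 on fold predictions concatenated into a single vector.

    ``fold_predictions`` is an iterable of (y_true, y_pred) pairs, one per
    fold.  Per-fold metrics are never averaged; this matches the convention
    of scoring each cross-validation iteration as a whole.
    """
    ys, preds = [], []
    for y_f, p_f in fold_predictions:
        ys.append(np.asarray(y_f, dtype=float))
        preds.append(np.asarray(p_f, dtype=float))
    y = np.concatenate(ys)
    y_pred = np.concatenate(preds)
    return MetricPair(r=pearson_r(y, y_pred), q2=q_squared(y, y_pred))


def average_coefficients(result) -> CoefficientVector:
    """Arithmetic mean over outer folds of full-edge-length coefficients.

    Accepts a :class:`~connleak.pipelines.PipelineResult` (or anything with
    ``coefficients`` as a list of full-length vectors).
    """
    coefs = np.vstack(result.coefficients)
    provenance = {"seed": getattr(result, "seed", None)}
    spec = getattr(result, "spec", None)
    if spec is not None:
        provenance["spec"] = spec
    return CoefficientVector(values=coefs.mean(axis=0), provenance=provenance)


def _values(v) -> np.ndarray:
    return np.asarray(v.values if isinstance(v, CoefficientVector) else v, dtype=float)


def coefficient_similarity(a, b) -> float:
    """Pearson correlation of two full-edge coefficient vectors."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError("coefficient vectors must have equal length")
    return pearson_r(va, vb)


def subnetwork_counts(
    selected_edges, parcellation: Parcellation, adjust: bool = True
) -> np.ndarray:
    """Selected-edge counts per subnetwork, optionally size-adjusted.

    The size adjustment divides each subnetwork's count by its total edge
    count, i.e. the selected fraction per subnetwork.  Subnetworks with no
    edges at all have an undefined adjusted count and are returned as NaN
    (and noted in the log) so downstream correlations can exclude them.
    """
    subnet = edge_subnetwork_map(parcellation)
    m = n_subnetworks(parcellation.n_networks)
    sizes = np.bincount(subnet, minlength=m).astype(float)
    sel = np.asarray(selected_edges, dtype=int)
    counts = np.bincount(subnet[sel], minlength=m).astype(float)
    if not adjust:
        return counts
    empty = sizes == 0.0
    if empty.any():
        logger.info(
            "%d subnetworks contain no edges; adjusted counts set to NaN",
            int(empty.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        adjusted = counts / sizes
    adjusted[empty] = np.nan
    return adjusted


def subnetwork_rank_similarity(counts_a, counts_b) -> float:
    """Spearman rank correlation with average-rank ties; NaN bins excluded."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 3:
        raise ValueError("need at least 3 finite subnetwork bins")
    rho = stats.spearmanr(a[keep], b[keep]).statistic
    return float(rho)
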