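"""Domain containers and low-level transforms for connectome data.

A connectome here is a subject-by-edge matrix of (typically Fisher-z
transformed) connectivity values, accompanied by a phenotype, nuisance
covariates (age, sex, head motion), an acquisition-site label, and a family
identifier per subject.  A :class:`Parcellation` describes how edge columns
map back onto node pairs and canonical networks.

The edge ordering convention is fixed package-wide: row-major over the
strict upper triangle of the node-by-node matrix, i.e. the ordering produced
by ``numpy.triu_indices(n, k=1)``.  All analyses are invariant to the choice,
but fixing it makes coefficient vectors comparable across pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectomeDataset",
    "Parcellation",
    "vectorize_upper_triangle",
    "unvectorize_upper_triangle",
    "fisher_z",
    "edge_subnetwork_map",
    "n_subnetworks",
]


def _n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def vectorize_upper_triangle(matrix: np.ndarray, *, atol: float = 1e-8) -> np.ndarray:
    """Flatten a symmetric node-by-node matrix into an edge vector.

    Uses row-major strict-upper-triangle ordering; the diagonal is ignored.
    Raises ``ValueError`` for non-square or asymmetric (beyond ``atol``) input.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=atol, rtol=0.0):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def unvectorize_upper_triangle(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle`; diagonal is set to zero."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (_n_edges(n_nodes),):
        raise ValueError(
            f"edge vector length {edges.shape} does not match n_nodes={n_nodes}"
        )
    out = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = edges
    out.T[iu] = edges
    return out


def fisher_z(r):
    """Fisher z-transform, ``z = atanh(r)``, for correlations with |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def n_subnetworks(n_networks: int) -> int:
    """Number of unordered network pairs (including within-network pairs)."""
    return n_networks * (n_networks + 1) // 2


@dataclass(frozen=True)
class Parcellation:
    """Node-to-network assignment plus the edge ordering it induces.

    Parameters
    ----------
    node_network:
        0-based network index per node, length ``n_nodes``.
    """

    node_network: np.ndarray

    def __post_init__(self):
        nn = np.asarray(self.node_network, dtype=int)
        if nn.ndim != 1 or nn.size < 2:
            raise ValueError("node_network must be a 1-d array with >= 2 nodes")
        if np.any(nn < 0):
            raise ValueError("network indices must be non-negative")
        object.__setattr__(self, "node_network", nn)

    @property
    def n_nodes(self) -> int:
        return int(self.node_network.size)

    @property
    def n_networks(self) -> int:
        return int(self.node_network.max()) + 1

    @property
    def n_edges(self) -> int:
        return _n_edges(self.n_nodes)

    @property
    def edge_index(self) -> np.ndarray:
        """(n_edges, 2) array of node pairs (a, b) with a < b, row-major."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return np.column_stack(iu)


def edge_subnetwork_map(parcellation: Parcellation) -> np.ndarray:
    """Subnetwork index per edge.

    A subnetwork is an unordered pair of canonical networks {i, j} with
    i <= j; with K networks there are K(K+1)/2 subnetworks, indexed
    row-major over the (i <= j) pairs.  Every edge maps to exactly one
    subnetwork, so the subnetworks partition the edge set.
    """
    nn = parcellation.node_network
    K = parcellation.n_networks
    a, b = parcellation.edge_index.T
    i = np.minimum(nn[a], nn[b])
    j = np.maximum(nn[a], nn[b])
    # row-major index of pair (i, j), i <= j, in the upper triangle incl. diag
    return i * K - i * (i - 1) // 2 + (j - i)


@dataclass
class ConnectomeDataset:
    """Subject-by-edge features with phenotype, covariates, site and family.

    Invariants enforced at construction: all per-subject containers share the
    same length (>= 2); ``X`` is finite; ``y`` has no missing values (rows
    with missing phenotype must be dropped by the loader); every subject has
    a family label (singletons are their own family).
    """

    subject_ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame
    site: np.ndarray
    family_id: np.ndarray

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.site = np.asarray(self.site)
        self.family_id = np.asarray(self.family_id)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        n = self.subject_ids.shape[0]
        if n < 2:
            raise ValueError("dataset needs at least 2 subjects")
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValueError("X must be 2-d with one row per subject")
        for name, arr in (("y", self.y), ("site", self.site), ("family_id", self.family_id)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != n_subjects {n}")
        if len(self.covariates) != n:
            raise ValueError("covariates must have one row per subject")
        if len(np.unique(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("y contains missing/non-finite values")
        if pd.isna(pd.Series(self.family_id)).any():
            raise ValueError("family_id must be defined for every subject")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.X.shape[1])

    def covariate_matrix(
        self, exclusions: Sequence[str] = ()
    ) -> tuple[np.ndarray, list[str]]:
        """Design matrix C = [1, covariates] minus excluded columns.

        Returns the matrix (intercept first) and the retained raw covariate
        names (intercept not listed).
        """
        names = [c for c in self.covariates.columns if c not in set(exclusions)]
        C = np.column_stack(
            [np.ones(self.n_subjects)]
            + [self.covariates[c].to_numpy(dtype=float) for c in names]
        )
        return C, names

    def subset(self, indices: np.ndarray) -> "ConnectomeDataset":
        """Row subset (copy) preserving all per-subject fields."""
        idx = np.asarray(indices)
        return ConnectomeDataset(
            subject_ids=self.subject_ids[idx].copy(),
            X=self.X[idx].copy(),
            y=self.y[idx].copy(),
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            site=self.site[idx].copy(),
            family_id=self.family_id[idx].copy(),
        )

    def with_features(self, X: np.ndarray) -> "ConnectomeDataset":
        """Same dataset with the feature matrix replaced (used after correction)."""
        return replace(self, X=X, covariates=self.covariates.copy())
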