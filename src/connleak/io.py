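"""Reading and writing connectome datasets and parcellations.

Features are stored either as delimited text (one row per subject, first
column ``subject_id``, remaining columns edge values with edge ids as the
header) or as an HDF5 container with datasets ``subject_ids`` and ``X``.
Phenotype, covariates, site and family live in a separate delimited table
keyed by ``subject_id``; the two tables are joined strictly, with an error
on unmatched subjects.  Rows with a missing phenotype are dropped and the
count logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .core import ConnectomeDataset, Parcellation

logger = logging.getLogger(__name__)

__all__ = [
    "load_dataset",
    "save_dataset",
    "load_parcellation",
    "save_parcellation",
]


def _read_features(path: Path, sep: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (subject_ids, X) from a text table or HDF5 file."""
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            ids = f["subject_ids"][()]
            X = f["X"][()]
        ids = np.array([s.decode() if isinstance(s, bytes) else str(s) for s in ids])
        return ids, np.asarray(X, dtype=float)
    df = pd.read_csv(path, sep=sep)
    ids = df.iloc[:, 0].astype(str).to_numpy()
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    return ids, X


def load_dataset(
    features_path: str | Path,
    phenotype_path: str | Path,
    phenotype: str,
    covariates: Sequence[str] = ("age", "sex", "motion"),
    site: str = "site",
    family: str = "family_id",
    sep: str = "\t",
) -> ConnectomeDataset:
    """Load a :class:`ConnectomeDataset` from features + phenotype tables.

    ``phenotype`` names the target column; ``covariates`` the nuisance
    columns; ``site``/``family`` may be absent from the table, in which case
    a single site / all-singleton families are assumed.
    """
    features_path = Path(features_path)
    phenotype_path = Path(phenotype_path)
    ids, X = _read_features(features_path, sep)
    table = pd.read_csv(phenotype_path, sep=sep)
    if "subject_id" not in table.columns:
        raise ValueError("phenotype table must have a 'subject_id' column")
    table = table.copy()
    table["subject_id"] = table["subject_id"].astype(str)

    feat_ids = set(ids)
    tab_ids = set(table["subject_id"])
    if feat_ids != tab_ids:
        missing = sorted(feat_ids ^ tab_ids)[:5]
        raise ValueError(
            "features and phenotype tables do not describe the same subjects; "
            f"first mismatches: {missing}"
        )
    table = table.set_index("subject_id").loc[ids].reset_index()

    n0 = len(table)
    keep = table[phenotype].notna().to_numpy()
    n_dropped = int(n0 - keep.sum())
    if n_dropped:
        logger.info(
            "dropped %d/%d subjects with missing phenotype %r", n_dropped, n0, phenotype
        )
    table = table.loc[keep].reset_index(drop=True)
    ids = ids[keep]
    X = X[keep]

    missing_cov = [c for c in covariates if c not in table.columns]
    if missing_cov:
        raise ValueError(f"covariate columns not found: {missing_cov}")
    cov = table[list(covariates)].astype(float)
    if cov.isna().any().any():
        raise ValueError("covariates contain missing values")

    site_arr = (
        table[site].astype(str).to_numpy()
        if site in table.columns
        else np.array(["site0"] * len(table))
    )
    if family in table.columns:
        fam = table[family].astype(object)
        # subjects without a family label become their own singleton family
        fam = np.where(fam.isna(), "fam_" + table["subject_id"], fam.astype(str))
    else:
        fam = ("fam_" + table["subject_id"]).to_numpy()

    return ConnectomeDataset(
        subject_ids=ids,
        X=X,
        y=table[phenotype].to_numpy(dtype=float),
        covariates=cov,
        site=site_arr,
        family_id=np.asarray(fam),
    )


def save_dataset(
    dataset: ConnectomeDataset,
    features_path: str | Path,
    phenotype_path: str | Path,
    phenotype: str = "phenotype",
    sep: str = "\t",
) -> None:
    """Write a dataset in the formats :func:`load_dataset` reads."""
    features_path = Path(features_path)
    if features_path.suffix in {".h5", ".hdf5"}:
        with h5py.File(features_path, "w") as f:
            f.create_dataset(
                "subject_ids", data=np.asarray(dataset.subject_ids, dtype="S")
            )
            f.create_dataset("X", data=dataset.X)
    else:
        cols = [f"edge_{i}" for i in range(dataset.n_edges)]
        df = pd.DataFrame(dataset.X, columns=cols)
        df.insert(0, "subject_id", dataset.subject_ids)
        df.to_csv(features_path, sep=sep, index=False)
    table = dataset.covariates.copy()
    table.insert(0, "subject_id", dataset.subject_ids)
    table[phenotype] = dataset.y
    table["site"] = dataset.site
    table["family_id"] = dataset.family_id
    table.to_csv(phenotype_path, sep=sep, index=False)


def load_parcellation(path: str | Path, sep: str | None = None) -> Parcellation:
    """Read a two-column text file: node index (1-based), network index (1-based)."""
    arr = pd.read_csv(path, sep=sep or r"\s+", header=None, engine="python").to_numpy()
    if arr.shape[1] != 2:
        raise ValueError("parcellation file must have exactly two columns")
    nodes = arr[:, 0].astype(int)
    nets = arr[:, 1].astype(int)
    order = np.argsort(nodes)
    nodes, nets = nodes[order], nets[order]
    if not np.array_equal(nodes, np.arange(1, len(nodes) + 1)):
        raise ValueError("node indices must be 1..n_nodes with no gaps")
    if nets.min() < 1:
        raise ValueError("network indices must be 1-based positive integers")
    return Parcellation(node_network=nets - 1)


def save_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    nodes = np.arange(1, parcellation.n_nodes + 1)
    pd.DataFrame({"node": nodes, "network": parcellation.node_network + 1}).to_csv(
        path, sep="\t", header=False, index=False
    )
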