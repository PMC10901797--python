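"""Cross-validation splitters: family-aware grouped k-fold and plain k-fold.

The family-aware splitter never lets a family span folds.  Families are
shuffled by the seed, then dealt largest-first to the fold with the fewest
subjects (ties broken by fold index), which balances fold sizes.  The plain
splitter is the same procedure over singleton families, so on a dataset of
unrelated subjects the two coincide exactly for a given seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["family_kfold", "plain_kfold"]


def family_kfold(family_ids, k: int, seed: int) -> list[np.ndarray]:
    """Split subjects into k disjoint test folds without splitting families.

    Returns a list of k sorted index arrays whose union is all subjects.
    Raises if ``k`` exceeds the number of families.
    """
    family_ids = np.asarray(family_ids)
    n = family_ids.shape[0]
    codes, uniques = pd.factorize(family_ids)  # first-appearance order
    n_families = len(uniques)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_families:
        raise ValueError(f"k={k} exceeds the number of families ({n_families})")

    members = [[] for _ in range(n_families)]
    for subj, fam in enumerate(codes):
        members[fam].append(subj)
    sizes = np.array([len(m) for m in members])

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_families)
    # stable sort by decreasing size keeps the shuffled order within ties
    order = order[np.argsort(-sizes[order], kind="stable")]

    fold_counts = np.zeros(k, dtype=int)
    folds = [[] for _ in range(k)]
    for fam in order:
        dest = int(np.argmin(fold_counts))  # ties -> lowest fold index
        folds[dest].extend(members[fam])
        fold_counts[dest] += sizes[fam]
    return [np.array(sorted(f), dtype=int) for f in folds]


def plain_kfold(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Ordinary shuffled k-fold: singleton-family case of :func:`family_kfold`."""
    return family_kfold(np.arange(n), k, seed)
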