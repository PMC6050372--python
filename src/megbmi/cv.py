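"""Stratified cross-validation fold construction.

Folds are built by an explicitly documented rule so the logic has a simple
independent oracle: within each class (classes taken in sorted order), trial
indices are shuffled by the seeded generator, then dealt round-robin to folds
``0, 1, ..., k-1``; a fold's test set is everything dealt to it.  Fold sizes
therefore differ by at most one per class, and every index appears in exactly
one test fold.
"""

from __future__ import annotations

import numpy as np

__all__ = ["stratified_folds"]


def stratified_folds(labels, n_folds: int, rng: np.random.Generator) -> list:
    """Return ``n_folds`` test-index arrays (sorted within each fold)."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    if min(counts.values()) < n_folds:
        raise ValueError(
            f"need >= {n_folds} trials per class for {n_folds}-fold CV, got {counts}"
        )
    folds = [[] for _ in range(n_folds)]
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        for j, trial in enumerate(idx):
            folds[j % n_folds].append(int(trial))
    return [np.asarray(sorted(f), dtype=np.int64) for f in folds]
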