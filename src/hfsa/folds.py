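"""Stratified fold assignment shared by the fitness function and the CV harness."""

from __future__ import annotations

import numpy as np


def stratified_fold_assignment(labels, k: int, seed: int) -> np.ndarray:
    """Assign each row a fold id in [0, k) with classes spread evenly.

    Within each class, members are shuffled and dealt round-robin to folds,
    with the starting fold rotating per class so small classes do not all land
    in fold 0.  Deterministic given the seed.
    """
    labels = np.asarray(labels).astype(str)
    n = labels.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        assignment[members] = (np.arange(members.size) + offset) % k
        offset += members.size
    return assignment
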