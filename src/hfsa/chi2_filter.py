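"""Fast filter stage: chi-square ranking of binary features against the label.

For every feature the full 2 x n_classes contingency table (feature value
vs. class) is formed and the Pearson chi-square statistic summed over cells
with positive expected count.  Features are ranked by descending statistic,
ties broken by ascending column index, and the top ``v`` survive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import DatasetError, SymptomDataset


@dataclass
class ChiScores:
    scores: np.ndarray          # length u, one statistic per original column
    kept_indices: np.ndarray    # ordered by descending score, ties by column index

    @property
    def v(self) -> int:
        return self.kept_indices.size


def chi_square_scores(ds: SymptomDataset) -> np.ndarray:
    """Pearson chi-square statistic of each binary feature vs. the class label."""
    labels = ds.labels.astype(str)
    classes = np.unique(labels)
    if classes.size < 2:
        raise DatasetError("chi-square scoring needs at least 2 classes")
    n = ds.n_cases
    onehot = (labels[:, None] == classes[None, :]).astype(np.float64)
    class_totals = onehot.sum(axis=0)                      # column totals
    ones = onehot.T @ ds.cases.astype(np.float64)          # (n_classes, u) observed 1s
    zeros = class_totals[:, None] - ones
    row1 = ones.sum(axis=0)                                # per-feature count of 1s
    row0 = n - row1
    expected1 = np.outer(class_totals, row1) / n
    expected0 = np.outer(class_totals, row0) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(expected1 > 0, (ones - expected1) ** 2 / expected1, 0.0)
        term0 = np.where(expected0 > 0, (zeros - expected0) ** 2 / expected0, 0.0)
    return term1.sum(axis=0) + term0.sum(axis=0)


def rank_features(scores: np.ndarray) -> np.ndarray:
    """Column indices sorted by descending score, ties by ascending index."""
    return np.lexsort((np.arange(scores.size), -scores))


def resolve_v(v, u: int) -> int:
    """Integer v as given; fractional v as ceil(fraction * u); default u // 2 + remainder."""
    if v is None:
        return max(1, math.ceil(u / 2))
    if isinstance(v, float) and not v.is_integer():
        if not 0.0 < v < 1.0:
            raise DatasetError("fractional v must lie in (0, 1)")
        return max(1, math.ceil(v * u))
    return int(v)


def run_fast_stage(
    ds: SymptomDataset, v=None
) -> tuple[SymptomDataset, ChiScores]:
    """Keep the top-v features by chi-square score, preserving column order."""
    u = ds.n_features
    v_int = resolve_v(v, u)
    if not 1 <= v_int < u:
        raise DatasetError(f"v must satisfy 1 <= v < {u}, got {v_int}")
    scores = chi_square_scores(ds)
    kept = rank_features(scores)[:v_int]
    keep_sorted = np.sort(kept)  # survivors follow original dataset order
    reduced = SymptomDataset(
        ds.cases[:, keep_sorted],
        ds.labels.copy(),
        [ds.feature_names[i] for i in keep_sorted],
    )
    return reduced, ChiScores(scores=scores, kept_indices=kept)
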