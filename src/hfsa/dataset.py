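"""Binary symptom-disease tables: data model, CSV I/O, masking and splitting.

The core container is :class:`SymptomDataset`, an immutable-by-convention
bundle of a 0/1 case-by-symptom matrix, one disease label per case, and the
symptom (feature) names.  :class:`FeatureMask` is a binary vector over the
columns of a dataset; a 1 marks a selected feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_LABEL_COLUMN = "prognosis"


class DatasetError(ValueError):
    """Raised on malformed dataset input."""


@dataclass(frozen=True)
class FeatureMask:
    """Binary selection vector over the columns of a dataset (1 = selected)."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1:
            raise DatasetError("mask bits must be a 1-d vector")
        if not np.isin(bits, (0, 1)).all():
            raise DatasetError("mask bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return self.bits.size

    @classmethod
    def from_indices(cls, indices, length: int) -> "FeatureMask":
        bits = np.zeros(length, dtype=np.int8)
        bits[list(indices)] = 1
        return cls(bits)

    @classmethod
    def ones(cls, length: int) -> "FeatureMask":
        return cls(np.ones(length, dtype=np.int8))

    def indices(self) -> np.ndarray:
        """Original column indices of the selected features, ascending."""
        return np.flatnonzero(self.bits == 1)

    def key(self) -> bytes:
        """Hashable identity of the bit pattern (cache key)."""
        return self.bits.tobytes()


@dataclass
class SymptomDataset:
    """A case-by-symptom binary matrix with one disease label per case."""

    cases: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=np.int8)
        self.labels = np.asarray(self.labels)
        if self.cases.ndim != 2:
            raise DatasetError("cases must be a 2-d matrix")
        if not np.isin(self.cases, (0, 1)).all():
            raise DatasetError("case matrix entries must be 0 or 1")
        if self.labels.shape[0] != self.cases.shape[0]:
            raise DatasetError(
                f"labels length {self.labels.shape[0]} != number of rows "
                f"{self.cases.shape[0]}"
            )
        if not self.feature_names:
            self.feature_names = [f"symptom_{i}" for i in range(self.cases.shape[1])]
        if len(self.feature_names) != self.cases.shape[1]:
            raise DatasetError(
                f"feature_names length {len(self.feature_names)} != number of "
                f"columns {self.cases.shape[1]}"
            )

    @property
    def n_cases(self) -> int:
        return self.cases.shape[0]

    @property
    def n_features(self) -> int:
        return self.cases.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def copy(self) -> "SymptomDataset":
        return SymptomDataset(
            self.cases.copy(), self.labels.copy(), list(self.feature_names)
        )

    def equals(self, other: "SymptomDataset") -> bool:
        return (
            self.cases.shape == other.cases.shape
            and np.array_equal(self.cases, other.cases)
            and np.array_equal(self.labels.astype(str), other.labels.astype(str))
            and self.feature_names == other.feature_names
        )


def load_dataset(path, label_column: str = DEFAULT_LABEL_COLUMN) -> SymptomDataset:
    """Read a delimited 0/1 table with a header and one label column."""
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[0] == 0:
        raise DatasetError(f"{path}: file contains no data rows")
    if label_column not in frame.columns:
        raise DatasetError(f"{path}: missing label column {label_column!r}")
    feature_cols = [c for c in frame.columns if c != label_column]
    if not feature_cols:
        raise DatasetError(f"{path}: no feature columns besides the label")
    values = frame[feature_cols].to_numpy()
    parsed = np.zeros(values.shape, dtype=np.int8)
    for j, col in enumerate(feature_cols):
        for i, raw in enumerate(values[:, j]):
            text = str(raw).strip()
            if text not in ("0", "1"):
                raise DatasetError(
                    f"{path}: non-binary cell at row {i}, column {col!r}: "
                    f"value {raw!r}"
                )
            parsed[i, j] = int(text)
    labels = frame[label_column].to_numpy(dtype=str)
    return SymptomDataset(parsed, labels, feature_cols)


def save_dataset(
    ds: SymptomDataset, path, label_column: str = DEFAULT_LABEL_COLUMN
) -> None:
    """Write the dataset as CSV; :func:`load_dataset` inverts it bit-exactly."""
    if ds.n_features == 0:
        raise DatasetError("refusing to save a dataset with zero feature columns")
    frame = pd.DataFrame(ds.cases, columns=ds.feature_names)
    frame[label_column] = ds.labels.astype(str)
    frame.to_csv(path, index=False)


def stratified_split(
    ds: SymptomDataset, train_fraction: float, seed: int
) -> tuple[SymptomDataset, SymptomDataset]:
    """Label-stratified train/test split; train size = round(n * fraction).

    Per-label training counts are allocated by the largest-remainder method so
    the total is exact and class proportions are preserved to within rounding.
    Falls back to a plain shuffled split (with a warning) when any label has
    fewer than 2 cases.
    """
    if not 0.0 < train_fraction < 1.0:
        raise DatasetError("train_fraction must lie strictly between 0 and 1")
    n = ds.n_cases
    n_train = int(round(n * train_fraction))
    if n_train < 1 or n_train >= n:
        raise DatasetError("split would leave an empty partition")
    rng = np.random.default_rng(seed)

    labels = ds.labels.astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        warnings.warn(
            "a label has fewer than 2 cases; falling back to a plain split",
            stacklevel=2,
        )
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        exact = counts * train_fraction
        base = np.floor(exact).astype(int)
        remainder = exact - base
        deficit = n_train - int(base.sum())
        # largest remainders get the leftover slots; ties by class order
        order = np.argsort(-remainder, kind="stable")
        for cls_pos in order[:deficit]:
            base[cls_pos] += 1
        # never strip a class entirely from either side when avoidable
        base = np.clip(base, 1, counts - 1)
        drift = n_train - int(base.sum())
        if drift != 0:
            room = (counts - 1 - base) if drift > 0 else (base - 1)
            for cls_pos in np.argsort(-room, kind="stable"):
                if drift == 0:
                    break
                step = 1 if drift > 0 else -1
                if (base[cls_pos] + step >= 1) and (
                    base[cls_pos] + step <= counts[cls_pos] - 1
                ):
                    base[cls_pos] += step
                    drift -= step
        train_parts = []
        test_parts = []
        for cls, k in zip(classes, base):
            members = np.flatnonzero(labels == cls)
            members = rng.permutation(members)
            train_parts.append(members[:k])
            test_parts.append(members[k:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))

    train = SymptomDataset(
        ds.cases[train_idx], ds.labels[train_idx], list(ds.feature_names)
    )
    test = SymptomDataset(
        ds.cases[test_idx], ds.labels[test_idx], list(ds.feature_names)
    )
    return train, test


def apply_mask(ds: SymptomDataset, mask: FeatureMask) -> SymptomDataset:
    """Restrict the dataset to the masked-in columns, preserving order."""
    if len(mask) != ds.n_features:
        raise DatasetError(
            f"mask length {len(mask)} != feature count {ds.n_features}"
        )
    if mask.popcount == 0:
        raise DatasetError("empty feature mask: at least one feature must be selected")
    keep = mask.indices()
    return SymptomDataset(
        ds.cases[:, keep],
        ds.labels.copy(),
        [ds.feature_names[i] for i in keep],
    )


def remove_rows(ds: SymptomDataset, indices) -> SymptomDataset:
    """Drop the given row indices; survivor order is preserved."""
    idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= ds.n_cases):
        raise DatasetError("row index out of range")
    if idx.size == ds.n_cases:
        raise DatasetError("cannot remove every row")
    keep = np.setdiff1d(np.arange(ds.n_cases), idx)
    return SymptomDataset(ds.cases[keep], ds.labels[keep], list(ds.feature_names))
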