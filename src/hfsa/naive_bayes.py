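"""Bernoulli naive-Bayes diagnostic classifier and the wrapper fitness function.

The classifier estimates, per class, the probability that each binary symptom
is present, with additive (Laplace) smoothing.  Posteriors are computed in log
space and normalized.  :class:`FitnessEvaluator` turns a feature mask into a
scalar objective — the stratified cross-validated accuracy of the classifier
restricted to the masked features — with a mask-keyed cache so wrapper
searches never refit a subset they have already scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import DatasetError, FeatureMask, SymptomDataset
from .folds import stratified_fold_assignment


@dataclass
class NBModel:
    classes: np.ndarray            # ordered label list
    class_log_priors: np.ndarray   # shape (n_classes,)
    conditionals: np.ndarray       # P(feature=1 | class), shape (n_classes, n_features)
    alpha: float

    @property
    def feature_count(self) -> int:
        return self.conditionals.shape[1]

    @property
    def class_priors(self) -> np.ndarray:
        return np.exp(self.class_log_priors)


def fit(train: SymptomDataset, alpha: float = 1.0) -> NBModel:
    """Estimate priors and per-class Bernoulli conditionals.

    conditional(c, f) = (count of 1s in class c, feature f + alpha) / (n_c + 2*alpha)
    """
    if train.n_features < 1:
        raise DatasetError("cannot fit with zero features")
    labels = train.labels.astype(str)
    classes = np.unique(labels)
    if classes.size < 2:
        raise DatasetError("need at least 2 distinct labels to fit a classifier")
    onehot = (labels[:, None] == classes[None, :]).astype(np.float64)
    class_counts = onehot.sum(axis=0)
    ones = onehot.T @ train.cases.astype(np.float64)
    conditionals = (ones + alpha) / (class_counts[:, None] + 2.0 * alpha)
    log_priors = np.log(class_counts / labels.shape[0])
    return NBModel(classes, log_priors, conditionals, alpha)


def predict_log_proba(model: NBModel, ds: SymptomDataset) -> np.ndarray:
    if ds.n_features != model.feature_count:
        raise DatasetError(
            f"feature count mismatch: dataset has {ds.n_features}, "
            f"model expects {model.feature_count}"
        )
    X = ds.cases.astype(np.float64)
    with np.errstate(divide="ignore"):
        log_p1 = np.log(model.conditionals)
        log_p0 = np.log1p(-model.conditionals)
    # joint log-likelihood: X @ log(p) + (1-X) @ log(1-p)
    joint = X @ log_p1.T + (1.0 - X) @ log_p0.T + model.class_log_priors[None, :]
    joint = np.nan_to_num(joint, nan=-np.inf)
    shifted = joint - joint.max(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        log_norm = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return shifted - log_norm


def predict_proba(model: NBModel, ds: SymptomDataset) -> np.ndarray:
    """Posterior matrix, rows summing to 1; computed in log space."""
    return np.exp(predict_log_proba(model, ds))


def predict(model: NBModel, ds: SymptomDataset) -> np.ndarray:
    """Argmax-posterior label per row; ties go to the first class in order."""
    posteriors = predict_log_proba(model, ds)
    return model.classes[np.argmax(posteriors, axis=1)]


class FitnessEvaluator:
    """Mask -> cross-validated accuracy of the restricted classifier.

    Fold assignment is fixed once from the seed, so the objective is a pure
    deterministic function of the mask bits and results can be cached.
    """

    def __init__(
        self,
        train: SymptomDataset,
        eval_folds: int = 3,
        seed: int = 0,
        alpha: float = 1.0,
    ) -> None:
        self.train = train
        self.eval_folds = eval_folds
        self.alpha = alpha
        self.fold_of = stratified_fold_assignment(train.labels, eval_folds, seed)
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0
        # per-fold sufficient statistics over ALL features, so restricting to a
        # mask is a column slice instead of a refit
        labels = train.labels.astype(str)
        self.classes = np.unique(labels)
        onehot = (labels[:, None] == self.classes[None, :]).astype(np.float64)
        self._folds = []
        for fold in range(eval_folds):
            holdout = self.fold_of == fold
            ones = onehot[~holdout].T @ train.cases[~holdout].astype(np.float64)
            class_counts = onehot[~holdout].sum(axis=0)
            with np.errstate(divide="ignore"):
                log_priors = np.log(class_counts / class_counts.sum())
            self._folds.append(
                {
                    "ones": ones,                      # (n_classes, n_features)
                    "class_counts": class_counts,
                    "log_priors": log_priors,
                    "X_test": train.cases[holdout].astype(np.float64),
                    "y_test_idx": np.argmax(onehot[holdout], axis=1),
                }
            )

    def __call__(self, mask: FeatureMask) -> float:
        if len(mask) != self.train.n_features:
            raise DatasetError(
                f"mask length {len(mask)} != training feature count "
                f"{self.train.n_features}"
            )
        if mask.popcount == 0:
            return 0.0
        key = mask.key()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        self.n_evaluations += 1
        cols = mask.indices()
        correct = 0
        for fold in self._folds:
            cond = (fold["ones"][:, cols] + self.alpha) / (
                fold["class_counts"][:, None] + 2.0 * self.alpha
            )
            log_p1 = np.log(cond)
            log_p0 = np.log1p(-cond)
            # joint = X @ log_p1 + (1-X) @ log_p0 + prior, rearranged
            scores = (
                fold["X_test"][:, cols] @ (log_p1 - log_p0).T
                + log_p0.sum(axis=1)[None, :]
                + fold["log_priors"][None, :]
            )
            correct += int((np.argmax(scores, axis=1) == fold["y_test_idx"]).sum())
        value = correct / self.train.n_cases
        self._cache[key] = value
        return value


def fitness_accuracy(
    mask: FeatureMask,
    train: SymptomDataset,
    eval_folds: int = 3,
    seed: int = 0,
    alpha: float = 1.0,
) -> float:
    """One-shot form of :class:`FitnessEvaluator` (no cross-call caching)."""
    return FitnessEvaluator(train, eval_folds=eval_folds, seed=seed, alpha=alpha)(mask)


def save_model(model: NBModel, path) -> None:
    """Serialize to a flat key/value text file."""
    with open(path, "w") as handle:
        handle.write(f"alpha\t{float(model.alpha)!r}\n")
        handle.write("classes\t" + ",".join(str(c) for c in model.classes) + "\n")
        for i, cls in enumerate(model.classes):
            handle.write(f"log_prior\t{cls}\t{float(model.class_log_priors[i])!r}\n")
            row = ",".join(repr(float(v)) for v in model.conditionals[i])
            handle.write(f"conditionals\t{cls}\t{row}\n")


def load_model(path) -> NBModel:
    alpha = 1.0
    classes: list[str] = []
    log_priors: dict[str, float] = {}
    conditionals: dict[str, np.ndarray] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "alpha":
                alpha = float(parts[1])
            elif parts[0] == "classes":
                classes = parts[1].split(",")
            elif parts[0] == "log_prior":
                log_priors[parts[1]] = float(parts[2])
            elif parts[0] == "conditionals":
                conditionals[parts[1]] = np.array(
                    [float(v) for v in parts[2].split(",")]
                )
    return NBModel(
        np.array(classes),
        np.array([log_priors[c] for c in classes]),
        np.vstack([conditionals[c] for c in classes]),
        alpha,
    )
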