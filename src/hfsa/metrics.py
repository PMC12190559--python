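"""Evaluation harness: confusion metrics, macro ROC-AUC, KNN baseline,
stratified k-fold cross-validation and multi-run summaries.

All percentage-scale metrics are reported on [0, 100].  Precision and recall
are macro-averaged over classes; ROC-AUC is the macro one-vs-rest reduction
computed from the rank statistic (ties contribute one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .dataset import DatasetError, SymptomDataset
from .folds import stratified_fold_assignment


@dataclass
class ConfusionMatrix:
    counts: np.ndarray      # rows = true class, columns = predicted class
    classes: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float         # all on the 0..100 percent scale
    error: float
    precision: float
    recall: float
    auc: float | None = None
    per_fold: list["MetricsReport"] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "error": self.error,
            "precision": self.precision,
            "recall": self.recall,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def confusion(true_labels, predicted_labels, classes=None) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels).astype(str)
    predicted_labels = np.asarray(predicted_labels).astype(str)
    if true_labels.shape[0] != predicted_labels.shape[0]:
        raise DatasetError("true and predicted label vectors differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([true_labels, predicted_labels]))
    else:
        classes = np.asarray(classes).astype(str)
        seen = set(classes)
        for lab in np.concatenate([true_labels, predicted_labels]):
            if lab not in seen:
                raise DatasetError(f"label {lab!r} absent from the class list")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy/error plus macro precision and recall, all in percent."""
    total = cm.total
    if total == 0:
        raise DatasetError("empty confusion matrix")
    diag = np.diag(cm.counts).astype(float)
    accuracy = 100.0 * diag.sum() / total
    col_sums = cm.counts.sum(axis=0).astype(float)
    row_sums = cm.counts.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision_per = np.where(col_sums > 0, diag / col_sums, 0.0)
        recall_per = np.where(row_sums > 0, diag / row_sums, 0.0)
    return MetricsReport(
        accuracy=accuracy,
        error=100.0 - accuracy,
        precision=100.0 * float(precision_per.mean()),
        recall=100.0 * float(recall_per.mean()),
    )


def roc_auc_macro(true_labels, posterior_matrix, classes) -> float:
    """Macro one-vs-rest AUC in percent, via the Mann-Whitney rank statistic.

    Classes with zero positives or zero negatives in the truth are skipped
    with a warning.
    """
    true_labels = np.asarray(true_labels).astype(str)
    scores = np.asarray(posterior_matrix, dtype=float)
    classes = np.asarray(classes).astype(str)
    if scores.shape != (true_labels.shape[0], classes.size):
        raise DatasetError("posterior matrix shape does not match labels/classes")
    aucs = []
    for j, cls in enumerate(classes):
        positives = true_labels == cls
        n_pos = int(positives.sum())
        n_neg = positives.size - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(
                f"class {cls!r} lacks positives or negatives; skipped in macro AUC",
                stacklevel=2,
            )
            continue
        ranks = rankdata(scores[:, j])  # average ranks give the tie-half credit
        auc = (ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise DatasetError("no class had both positives and negatives")
    return 100.0 * float(np.mean(aucs))


def knn_predict(
    train: SymptomDataset, test: SymptomDataset, k: int = 7
) -> np.ndarray:
    """Hamming-distance k-nearest-neighbour majority vote.

    Distance ties break toward the lower training-row index; vote ties toward
    the earlier class in sorted class order.
    """
    if not 1 <= k <= train.n_cases:
        raise DatasetError(f"k must lie in [1, {train.n_cases}]")
    if train.n_features != test.n_features:
        raise DatasetError("train and test feature counts differ")
    train_labels = train.labels.astype(str)
    classes = np.unique(train_labels)
    class_index = {c: i for i, c in enumerate(classes)}
    Xtr = train.cases.astype(np.int16)
    Xte = test.cases.astype(np.int16)
    # Hamming distance between 0/1 rows = squared Euclidean, via inner products
    distances = (
        (Xte**2).sum(axis=1)[:, None]
        - 2 * (Xte @ Xtr.T)
        + (Xtr**2).sum(axis=1)[None, :]
    )
    out = np.empty(test.n_cases, dtype=train_labels.dtype)
    for i in range(test.n_cases):
        order = np.argsort(distances[i], kind="stable")[:k]  # stable = index tiebreak
        votes = np.zeros(classes.size, dtype=int)
        for t in order:
            votes[class_index[train_labels[t]]] += 1
        out[i] = classes[int(np.argmax(votes))]
    return out


def aggregate_folds(per_fold: list[MetricsReport]) -> MetricsReport:
    """Average row: the arithmetic mean of the per-fold metrics."""
    if not per_fold:
        raise DatasetError("no folds to aggregate")
    acc = float(np.mean([f.accuracy for f in per_fold]))
    aucs = [f.auc for f in per_fold if f.auc is not None]
    return MetricsReport(
        accuracy=acc,
        error=100.0 - acc,
        precision=float(np.mean([f.precision for f in per_fold])),
        recall=float(np.mean([f.recall for f in per_fold])),
        auc=float(np.mean(aucs)) if len(aucs) == len(per_fold) else None,
        per_fold=list(per_fold),
    )


def kfold_cv(
    ds: SymptomDataset, pipeline_fn, k: int = 10, seed: int = 0
) -> MetricsReport:
    """Stratified k-fold cross-validation of an arbitrary train/test pipeline.

    ``pipeline_fn(train, test) -> (predicted labels, posterior matrix or None,
    class order)`` is called once per fold; the report carries per-fold metrics
    and their arithmetic means.
    """
    if k > ds.n_cases:
        raise DatasetError("k exceeds the number of cases")
    fold_of = stratified_fold_assignment(ds.labels, k, seed)
    per_fold: list[MetricsReport] = []
    for fold in range(k):
        holdout = fold_of == fold
        train = SymptomDataset(
            ds.cases[~holdout], ds.labels[~holdout], list(ds.feature_names)
        )
        test = SymptomDataset(
            ds.cases[holdout], ds.labels[holdout], list(ds.feature_names)
        )
        predicted, posteriors, classes = pipeline_fn(train, test)
        report = metrics(confusion(test.labels, predicted, classes=classes))
        if posteriors is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report.auc = roc_auc_macro(test.labels, posteriors, classes)
        per_fold.append(report)
    return aggregate_folds(per_fold)


def multirun_summary(run_metrics: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Five-number summary (Tukey hinges) of each metric across runs."""
    if not run_metrics:
        raise DatasetError("empty run list")

    def five_number(values: np.ndarray) -> dict[str, float]:
        values = np.sort(np.asarray(values, dtype=float))
        n = values.size
        half = (n + 1) // 2  # inclusive halves: odd n keeps the median in both
        return {
            "min": float(values[0]),
            "q1": float(np.median(values[:half])),
            "median": float(np.median(values)),
            "q3": float(np.median(values[n - half :])),
            "max": float(values[-1]),
        }

    names = ["accuracy", "error", "precision", "recall"]
    if all(r.auc is not None for r in run_metrics):
        names.append("auc")
    return {
        name: five_number(np.array([getattr(r, name) for r in run_metrics]))
        for name in names
    }
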