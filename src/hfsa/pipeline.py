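"""End-to-end orchestration: split, reject outliers, select features, diagnose.

The pipeline touches only the training partition during outlier rejection and
feature selection; the test partition is used exactly once, for the final
metrics.  Every stage draws its seed deterministically from the single global
seed via a seed sequence, so an identical config reproduces identical output.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import naive_bayes
from .dataset import FeatureMask, SymptomDataset, apply_mask
from .metrics import confusion, metrics, roc_auc_macro, knn_predict
from .outliers import ORConfig, reject_outliers
from .selector import HOAConfig, select_features


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    rl_enabled: bool = True
    sl_enabled: bool = True
    rl: ORConfig = field(default_factory=ORConfig)
    fs_v: float | int | None = None      # int, fraction in (0,1), or None for u/2
    hoa: HOAConfig = field(default_factory=HOAConfig)
    sl_method: str = "hfsa"
    classifier: str = "nb"               # "nb" or "knn"
    nb_alpha: float = 1.0
    knn_k: int = 7
    train_fraction: float = 0.70
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        rl = ORConfig(**raw.pop("rl", {}))
        hoa = HOAConfig(**raw.pop("hoa", {}))
        return cls(rl=rl, hoa=hoa, **raw)


def stage_seeds(global_seed: int, names: tuple[str, ...]) -> dict[str, int]:
    """Derive one independent integer seed per stage from the global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0]) for name, child in zip(names, children)
    }


def run_pipeline(config: PipelineConfig, ds: SymptomDataset) -> dict:
    """Split -> (RL) -> (FS+AS) -> fit classifier -> test metrics; returns a report."""
    from dataclasses import replace

    from .dataset import stratified_split

    seeds = stage_seeds(config.seed, ("split", "rl", "sl", "fit"))
    report: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": []}

    def log(stage: str, started: float, **info) -> None:
        report["stages"].append(
            {"stage": stage, "seconds": round(time.perf_counter() - started, 4), **info}
        )

    t0 = time.perf_counter()
    try:
        train, test = stratified_split(ds, config.train_fraction, seeds["split"])
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("split", exc) from exc
    log("split", t0, n_train=train.n_cases, n_test=test.n_cases)

    removed_rows: list[int] = []
    if config.rl_enabled:
        t0 = time.perf_counter()
        try:
            rl_config = replace(config.rl, seed=seeds["rl"])
            train, removed_rows = reject_outliers(train, rl_config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("reject_outliers", exc) from exc
        log("reject_outliers", t0, n_removed=len(removed_rows))
    report["removed_rows"] = removed_rows

    if config.sl_enabled:
        t0 = time.perf_counter()
        try:
            hoa = replace(config.hoa, seed=seeds["sl"])
            selection = select_features(
                train, method=config.sl_method, v=config.fs_v, config=hoa
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("select_features", exc) from exc
        kept = selection.kept_original_indices
        mask = FeatureMask.from_indices(kept, ds.n_features)
        train = apply_mask(train, mask)
        test_view = apply_mask(test, mask)
        log(
            "select_features",
            t0,
            best_fitness=selection.best_fitness,
            m=selection.m,
            cycles=len(selection.history),
        )
        report["selected_features"] = [ds.feature_names[i] for i in kept]
        report["best_fitness"] = selection.best_fitness
        report["history"] = selection.history
    else:
        test_view = test
        report["selected_features"] = list(ds.feature_names)

    t0 = time.perf_counter()
    try:
        if config.classifier == "nb":
            model = naive_bayes.fit(train, alpha=config.nb_alpha)
            predicted = naive_bayes.predict(model, test_view)
            posteriors = naive_bayes.predict_proba(model, test_view)
            classes = model.classes
        elif config.classifier == "knn":
            predicted = knn_predict(train, test_view, k=config.knn_k)
            posteriors = None
            classes = np.unique(train.labels.astype(str))
        else:
            raise ValueError(f"unknown classifier {config.classifier!r}")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("diagnose", exc) from exc
    log("diagnose", t0, classifier=config.classifier)

    cm = confusion(test.labels, predicted, classes=classes)
    result = metrics(cm)
    if posteriors is not None:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result.auc = roc_auc_macro(test.labels, posteriors, classes)
    report["metrics"] = result.as_dict()
    report["confusion_total"] = cm.total
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")


def config_to_dict(config: PipelineConfig) -> dict:
    return asdict(config)
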