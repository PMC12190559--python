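"""Synthetic symptom-disease generator with known ground truth.

Each disease owns a disjoint set of characteristic symptoms.  A case of a
disease turns each characteristic symptom on with probability ``p_on`` and
every other symptom on with probability ``p_noise``, so the union of the
characteristic sets is an unambiguous informative feature mask.  Outliers can
be planted by shuffling labels or scrambling symptom rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dataset import DatasetError, FeatureMask, SymptomDataset

OUTLIER_MODES = ("label_shuffle", "symptom_scramble")


@dataclass
class GeneratorConfig:
    # defaults emulate a 41-disease, 132-symptom, 4920-case table
    n_diseases: int = 41
    n_features: int = 132
    informative_per_disease: int = 3
    p_on: float = 0.9
    p_noise: float = 0.05
    cases_per_disease: int = 120
    outlier_fraction: float = 0.0
    outlier_mode: str = "label_shuffle"
    seed: int = 0

    def validate(self) -> None:
        if self.n_diseases < 1 or self.n_features < 1:
            raise DatasetError("n_diseases and n_features must be positive")
        if self.informative_per_disease < 1:
            raise DatasetError("informative_per_disease must be >= 1")
        if self.n_diseases * self.informative_per_disease > self.n_features:
            raise DatasetError(
                "n_diseases * informative_per_disease exceeds n_features; "
                "characteristic symptom sets cannot be disjoint"
            )
        if not (0.0 <= self.p_noise < self.p_on <= 1.0):
            raise DatasetError("require 0 <= p_noise < p_on <= 1")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise DatasetError("outlier_fraction must lie in [0, 0.5)")
        if self.outlier_mode not in OUTLIER_MODES:
            raise DatasetError(f"unknown outlier_mode {self.outlier_mode!r}")
        if self.cases_per_disease < 1:
            raise DatasetError("cases_per_disease must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)


@dataclass
class GroundTruth:
    informative_mask: FeatureMask
    outlier_indices: set[int] = field(default_factory=set)
    characteristic_sets: dict[str, list[int]] = field(default_factory=dict)


def generate(config: GeneratorConfig) -> tuple[SymptomDataset, GroundTruth]:
    """Generate a dataset plus its ground truth; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cases = config.n_diseases * config.cases_per_disease
    feature_order = rng.permutation(config.n_features)
    char_sets: dict[str, list[int]] = {}
    width = len(str(config.n_diseases - 1))
    disease_names = [f"disease_{i:0{width}d}" for i in range(config.n_diseases)]
    for d, name in enumerate(disease_names):
        start = d * config.informative_per_disease
        block = feature_order[start : start + config.informative_per_disease]
        char_sets[name] = sorted(int(i) for i in block)

    cases = (
        rng.random((n_cases, config.n_features)) < config.p_noise
    ).astype(np.int8)
    labels = np.repeat(disease_names, config.cases_per_disease)
    for d, name in enumerate(disease_names):
        rows = slice(d * config.cases_per_disease, (d + 1) * config.cases_per_disease)
        cols = char_sets[name]
        cases[rows, :][:, cols] = (
            rng.random((config.cases_per_disease, len(cols))) < config.p_on
        ).astype(np.int8)

    informative = sorted(i for cols in char_sets.values() for i in cols)
    truth = GroundTruth(
        informative_mask=FeatureMask.from_indices(informative, config.n_features),
        characteristic_sets=char_sets,
    )
    ds = SymptomDataset(
        cases,
        labels,
        [f"symptom_{i:03d}" for i in range(config.n_features)],
    )
    if config.outlier_fraction > 0:
        # derive a distinct stream so generation stays stable as fraction varies
        ds, corrupted = inject_outliers(
            ds,
            config.outlier_fraction,
            config.outlier_mode,
            seed=int(rng.integers(2**31)),
        )
        truth.outlier_indices = corrupted
    return ds, truth


def inject_outliers(
    ds: SymptomDataset, fraction: float, mode: str, seed: int
) -> tuple[SymptomDataset, set[int]]:
    """Corrupt round(fraction * n) rows; returns (new dataset, corrupted indices).

    ``label_shuffle`` reassigns each chosen row's label to a different
    uniformly random label; ``symptom_scramble`` resamples the row's bits
    i.i.d. Bernoulli(0.5).
    """
    if not (0.0 <= fraction < 0.5):
        raise DatasetError("outlier fraction must lie in [0, 0.5)")
    if mode not in OUTLIER_MODES:
        raise DatasetError(f"unknown outlier_mode {mode!r}")
    out = ds.copy()
    n_corrupt = int(round(fraction * ds.n_cases))
    if n_corrupt == 0:
        return out, set()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(ds.n_cases, size=n_corrupt, replace=False)
    classes = [str(c) for c in np.unique(ds.labels)]
    if mode == "label_shuffle":
        if len(classes) < 2:
            raise DatasetError("label_shuffle requires at least 2 distinct labels")
        labels = out.labels.astype(object)
        for row in chosen:
            others = [c for c in classes if c != str(labels[row])]
            labels[row] = others[int(rng.integers(len(others)))]
        out.labels = labels.astype(str)
    else:
        out.cases[chosen] = (
            rng.random((n_corrupt, ds.n_features)) < 0.5
        ).astype(np.int8)
    return out, set(int(i) for i in chosen)
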