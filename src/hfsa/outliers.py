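"""Rejection layer: evolve a binary inlier mask over training rows with a GA.

A candidate solution marks each training row as inlier (1) or outlier (0).
Its fitness is the cross-validated accuracy of the diagnostic classifier
trained on the masked-in rows, minus a penalty proportional to the fraction
removed, so deleting easy-to-misclassify but genuine rows does not pay.
Masks that remove more than ``max_removal_fraction`` of rows, or starve any
class below ``min_per_class``, are infeasible and score zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import naive_bayes
from .dataset import SymptomDataset, remove_rows
from .folds import stratified_fold_assignment


@dataclass
class ORConfig:
    pop_size: int = 20
    p_sel: float = 0.8
    p_cross: float = 0.9   # GA defaults shared with the selection stage
    p_mut: float = 0.01
    max_it: int = 30
    max_removal_fraction: float = 0.10
    min_per_class: int = 2
    penalty_weight: float = 0.5
    init_keep_prob: float = 0.95
    eval_folds: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_sel", "p_cross", "p_mut"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_it < 1 or self.pop_size < 2:
            raise ValueError("max_it must be >= 1 and pop_size >= 2")
        if not 0.0 <= self.max_removal_fraction < 1.0:
            raise ValueError("max_removal_fraction must lie in [0, 1)")


class _RowFitness:
    """Cached penalized fitness of inlier masks over a fixed dataset."""

    def __init__(self, ds: SymptomDataset, config: ORConfig) -> None:
        self.ds = ds
        self.config = config
        self.labels = ds.labels.astype(str)
        self.classes = np.unique(self.labels)
        self.fold_of = stratified_fold_assignment(
            self.labels, config.eval_folds, config.seed
        )
        self._cache: dict[bytes, float] = {}

    def feasible(self, bits: np.ndarray) -> bool:
        n = bits.size
        if (n - bits.sum()) > self.config.max_removal_fraction * n + 1e-9:
            return False
        for cls in self.classes:
            if bits[self.labels == cls].sum() < self.config.min_per_class:
                return False
        return True

    def __call__(self, bits: np.ndarray) -> float:
        key = bits.tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if not self.feasible(bits):
            self._cache[key] = 0.0
            return 0.0
        keep = bits.astype(bool)
        correct = 0
        total = 0
        for fold in range(self.config.eval_folds):
            train_rows = keep & (self.fold_of != fold)
            test_rows = keep & (self.fold_of == fold)
            if test_rows.sum() == 0 or np.unique(self.labels[train_rows]).size < 2:
                continue
            model = naive_bayes.fit(
                SymptomDataset(self.ds.cases[train_rows], self.labels[train_rows])
            )
            predicted = naive_bayes.predict(
                model, SymptomDataset(self.ds.cases[test_rows], self.labels[test_rows])
            )
            correct += int((predicted == self.labels[test_rows]).sum())
            total += int(test_rows.sum())
        accuracy = correct / total if total else 0.0
        removed_fraction = 1.0 - bits.sum() / bits.size
        value = accuracy - self.config.penalty_weight * removed_fraction
        self._cache[key] = value
        return value


def inlier_fitness(bits: np.ndarray, ds: SymptomDataset, config: ORConfig) -> float:
    """Penalized CV accuracy of one inlier mask (uncached convenience form)."""
    return _RowFitness(ds, config)(np.asarray(bits, dtype=np.int8))


def _roulette_pair(pop, fitness, rng, p_sel):
    total = fitness.sum()
    if rng.random() >= p_sel or total <= 0:
        i, j = rng.integers(len(pop)), rng.integers(len(pop))
    else:
        probs = fitness / total
        i = rng.choice(len(pop), p=probs)
        j = rng.choice(len(pop), p=probs)
    return pop[int(i)], pop[int(j)]


def reject_outliers(
    ds: SymptomDataset, config: ORConfig | None = None
) -> tuple[SymptomDataset, list[int]]:
    """GA over inlier masks; returns (filtered dataset, removed row indices)."""
    config = config or ORConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = ds.n_cases
    objective = _RowFitness(ds, config)

    def random_mask() -> np.ndarray:
        bits = (rng.random(n) < config.init_keep_prob).astype(np.int8)
        if not objective.feasible(bits):
            bits = np.ones(n, dtype=np.int8)
        return bits

    pop = [random_mask() for _ in range(config.pop_size)]
    if not any(np.array_equal(m, np.ones(n, dtype=np.int8)) for m in pop):
        pop[0] = np.ones(n, dtype=np.int8)  # keep-everything is always feasible
    fitness = np.array([objective(m) for m in pop])
    best_idx = int(np.argmax(fitness))
    best_bits, best_fitness = pop[best_idx].copy(), float(fitness[best_idx])

    for _ in range(config.max_it):
        offspring: list[np.ndarray] = []
        while len(offspring) < config.pop_size:
            pa, pb = _roulette_pair(pop, fitness, rng, config.p_sel)
            if n >= 2 and rng.random() < config.p_cross:
                cut = int(rng.integers(1, n))
                ca = np.concatenate([pa[:cut], pb[cut:]])
                cb = np.concatenate([pb[:cut], pa[cut:]])
            else:
                ca, cb = pa.copy(), pb.copy()
            for child in (ca, cb):
                if len(offspring) >= config.pop_size:
                    break
                flips = rng.random(n) < config.p_mut  # per-bit flip mutation
                child = child ^ flips.astype(np.int8)
                offspring.append(child)
        fitness = np.array([objective(m) for m in offspring])
        # elitism of one: incumbent best replaces the worst offspring if absent
        if not any(np.array_equal(m, best_bits) for m in offspring):
            worst = int(np.argmin(fitness))
            offspring[worst] = best_bits.copy()
            fitness[worst] = best_fitness
        pop = offspring
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fitness:
            best_fitness = float(fitness[gen_best])
            best_bits = pop[gen_best].copy()

    removed = [int(i) for i in np.flatnonzero(best_bits == 0)]
    filtered = remove_rows(ds, removed) if removed else ds.copy()
    return filtered, removed
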