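from __future__ import annotations

import numpy as np
import pytest

from hfsa.dataset import SymptomDataset
from hfsa.synth import GeneratorConfig, generate


class QueuedRng:
    """Deterministic rng stub: hands out pre-queued uniforms.

    ``random()`` returns the next scalar; ``random(shape)`` fills the shape by
    cycling the remaining queue; ``integers(n)`` returns queued ints.
    """

    def __init__(self, uniforms=(), ints=()):
        self.uniforms = list(uniforms)
        self.ints = list(ints)

    def random(self, shape=None):
        if shape is None:
            return self.uniforms.pop(0)
        size = int(np.prod(shape))
        values = [self.uniforms.pop(0) for _ in range(size)]
        return np.array(values).reshape(shape)

    def integers(self, low, high=None):
        return self.ints.pop(0)


@pytest.fixture
def toy_ds() -> SymptomDataset:
    cases = np.array(
        [[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 1]], dtype=np.int8
    )
    labels = np.array(["flu", "flu", "cold", "cold"])
    return SymptomDataset(cases, labels, ["fever", "cough", "ache"])


@pytest.fixture
def separable_ds() -> SymptomDataset:
    """Noiseless two-class fixture: feature 0 alone is perfectly predictive."""
    cases = np.array(
        [[1, 0], [1, 1], [1, 0], [0, 1], [0, 0], [0, 1]], dtype=np.int8
    )
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    return SymptomDataset(cases, labels, ["signal", "noise"])


@pytest.fixture
def small_synth():
    """5 diseases x 40 cases, 30 features, 3 informative each, light noise."""
    config = GeneratorConfig(
        n_diseases=5,
        n_features=30,
        informative_per_disease=3,
        cases_per_disease=40,
        p_on=0.9,
        p_noise=0.05,
        seed=11,
    )
    return generate(config)


def random_binary_ds(rng: np.random.Generator, n: int, u: int, n_classes: int = 2):
    """Random dataset with mild class-dependent feature probabilities."""
    probs = rng.uniform(0.2, 0.8, size=(n_classes, u))
    labels_idx = rng.integers(n_classes, size=n)
    cases = (rng.random((n, u)) < probs[labels_idx]).astype(np.int8)
    labels = np.array([f"c{i}" for i in labels_idx])
    if np.unique(labels).size < 2:  # force both classes present
        labels[0], labels[1] = "c0", "c1"
    return SymptomDataset(cases, labels)
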