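"""Synthetic generators emulating the structure the method assumes.

Three generators, all pure functions of their parameters and seed:

* feature matrices with a known subset of informative columns (the
  ground truth for selector-recovery experiments),
* prediction-vector ensembles with controlled per-model accuracies and
  independent errors (the regime in which majority voting provably
  helps),
* toy labeled corpora whose classes draw tokens from pools with a
  controllable overlap fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledMatrix
from .text import Corpus
from .voting import PredictionSet

__all__ = [
    "PlantedSpec",
    "make_planted_features",
    "make_prediction_ensemble",
    "make_text_corpus",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Design of a planted-feature matrix.

    ``class_sep`` is the distance between adjacent class means on each
    informative column, in units of the within-class standard deviation
    (which is 1); noise columns are standard normal, independent of the
    labels.  Classes are balanced to within one sample.
    """

    n: int = 200
    classes: int = 2
    informative: int = 3
    noise: int = 17
    class_sep: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.classes < 2 or self.informative < 1 or self.noise < 0:
            raise ValueError("counts out of range")
        if self.class_sep < 0:
            raise ValueError("class_sep must be >= 0")


def make_planted_features(spec: PlantedSpec) -> LabeledMatrix:
    """Class-conditional Gaussian matrix with named informative columns.

    Informative columns are ``inf1..inf{k}``; noise columns ``noise1..``.
    Column order is informative-first; the selector is never told which
    is which.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n) % spec.classes  # balanced +-1
    labels = rng.permutation(labels)
    d = spec.informative + spec.noise
    X = rng.standard_normal((spec.n, d))
    means = labels[:, None] * spec.class_sep  # class c centered at c * sep
    X[:, : spec.informative] += means
    names = [f"inf{j + 1}" for j in range(spec.informative)] + [
        f"noise{j + 1}" for j in range(spec.noise)
    ]
    return LabeledMatrix(X, labels, names)


def make_prediction_ensemble(
    n: int, model_accuracies: list[float], classes: int = 2, seed: int = 0
) -> PredictionSet:
    """Ensemble whose model i matches the truth with the given probability,
    otherwise emits a uniformly random wrong label; errors independent
    across models.  Realized (not requested) accuracies are recorded.
    """
    accs = np.asarray(model_accuracies, dtype=float)
    if classes < 2:
        raise ValueError("need >= 2 classes")
    if ((accs < 0) | (accs > 1)).any():
        raise ValueError("accuracies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, classes, size=n)
    preds = np.empty((accs.size, n), dtype=int)
    for i, a in enumerate(accs):
        correct = rng.random(n) < a
        wrong = (truth + rng.integers(1, classes, size=n)) % classes
        preds[i] = np.where(correct, truth, wrong)
    return PredictionSet(preds, truth, [f"model_{i + 1}" for i in range(accs.size)])


def make_text_corpus(
    n: int,
    classes: int = 2,
    vocab_per_class: int = 50,
    overlap: float = 0.0,
    seed: int = 0,
) -> Corpus:
    """Toy corpus: each class samples 5-20 tokens from its pool; a fraction
    ``overlap`` of each pool is shared across all classes."""
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    if n < 2 or classes < 2 or vocab_per_class < 1:
        raise ValueError("counts out of range")
    rng = np.random.default_rng(seed)
    n_shared = int(round(overlap * vocab_per_class))
    shared = [f"shared{t}" for t in range(n_shared)]
    pools = [
        shared + [f"c{c}tok{t}" for t in range(vocab_per_class - n_shared)]
        for c in range(classes)
    ]
    labels = rng.integers(0, classes, size=n)
    texts = []
    for lab in labels:
        length = int(rng.integers(5, 21))
        pool = pools[lab]
        texts.append(" ".join(pool[k] for k in rng.integers(0, len(pool), length)))
    return Corpus(texts, labels)
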