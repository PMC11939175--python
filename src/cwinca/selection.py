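"""Cumulative Weight-based Iterative NCA (CWINCA) feature selection.

The selector wraps the NCA feature weights in a deterministic subset
search: min-max normalize the matrix, fit NCA weights, rank features by
descending weight, bound the candidate subset sizes by where the
normalized cumulative weight crosses a start threshold (default 0.5) and
a stop threshold (default 0.999), then evaluate every prefix size in
that window with a 1-nearest-neighbor 10-fold cross-validation error and
keep the smallest size attaining the minimum.  The chosen subsets are
nested by construction: the set at size ``s`` is a prefix of the set at
``s + 1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold, StratifiedKFold

from .data import LabeledMatrix
from .nca import NcaConfig, fit_nca_weights

__all__ = [
    "CwincaConfig",
    "SelectionTrace",
    "minmax_normalize",
    "cumulative_bounds",
    "knn_cv_loss",
    "cwinca_select",
    "nested_selection_loss",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CwincaConfig:
    """Knobs of the cumulative-weight subset search.

    ``start_threshold``/``stop_threshold`` are fractions of the total
    feature weight; ``fallback_start`` is the start size used when the
    thresholds are unreachable (total weight zero), clamped to d.
    ``epsilon`` pads the min-max denominator so constant columns map to
    zeros instead of 0/0.  ``seed`` controls cross-validation fold
    assignment.
    """

    start_threshold: float = 0.5
    stop_threshold: float = 0.999
    fallback_start: int = 10
    cv_folds: int = 10
    knn_neighbors: int = 1
    knn_metric: str = "cityblock"
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.start_threshold <= 1 and 0 < self.stop_threshold <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.start_threshold > self.stop_threshold:
            raise ValueError("start_threshold must be <= stop_threshold")
        if self.fallback_start < 1:
            raise ValueError("fallback_start must be a positive integer")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.knn_neighbors < 1:
            raise ValueError("knn_neighbors must be >= 1")
        if self.knn_metric != "cityblock":
            raise ValueError("knn_metric must be 'cityblock'")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class SelectionTrace:
    """Complete record of one CWINCA run.

    ``losses[k]`` is the CV misclassification rate of the prefix of size
    ``start_size + k``; ``chosen_size`` is the smallest size attaining
    ``best_loss``; ``selected_features`` is the corresponding prefix of
    ``ranked_features``.
    """

    ranked_features: list[str]
    cumulative_weights: np.ndarray
    start_size: int
    stop_size: int
    losses: np.ndarray
    best_loss: float
    chosen_size: int
    selected_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cumulative_weights = np.asarray(self.cumulative_weights, dtype=float)
        self.losses = np.asarray(self.losses, dtype=float)
        d = len(self.ranked_features)
        assert (np.diff(self.cumulative_weights) >= -1e-12).all()
        assert 1 <= self.start_size <= self.stop_size <= d
        assert self.start_size <= self.chosen_size <= self.stop_size
        assert len(self.losses) == self.stop_size - self.start_size + 1
        assert np.isclose(self.best_loss, self.losses.min())
        assert np.isclose(self.losses[self.chosen_size - self.start_size], self.best_loss)
        assert self.selected_features == self.ranked_features[: self.chosen_size]

    def to_dict(self) -> dict:
        return {
            "ranked_features": self.ranked_features,
            "cumulative_weights": self.cumulative_weights.tolist(),
            "start_size": self.start_size,
            "stop_size": self.stop_size,
            "losses": self.losses.tolist(),
            "best_loss": self.best_loss,
            "chosen_size": self.chosen_size,
            "selected_features": self.selected_features,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def minmax_normalize(data: LabeledMatrix, epsilon: float = 1e-8) -> LabeledMatrix:
    """Map each column to (x - min) / (max - min + epsilon).

    Outputs lie in [0, 1); constant columns become all-zeros (the epsilon
    pad avoids 0/0).  Labels and feature names pass through unchanged.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    X = data.values
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    normed = (X - lo) / (hi - lo + epsilon)
    return LabeledMatrix(normed, data.labels, list(data.feature_names))


def cumulative_bounds(
    weights: np.ndarray, config: CwincaConfig = CwincaConfig()
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Rank features by weight and locate the subset-size search window.

    Returns ``(order, cumulative_weights, start_size, stop_size)`` where
    ``order`` holds 0-based feature positions sorted by descending weight
    (ties by ascending original position) and sizes are 1-based counts.
    If the total weight is zero no cumulative threshold is reachable and
    the fallbacks apply: start = min(fallback_start, d), stop = d.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise ValueError("weights must be a non-empty 1-D vector")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    d = w.size
    order = np.argsort(-w, kind="stable")  # descending, ties by position
    total = w.sum()
    if total > 0:
        cum = np.cumsum(w[order]) / total
    else:
        cum = np.zeros(d)
    start_hits = np.nonzero(cum >= config.start_threshold)[0]
    stop_hits = np.nonzero(cum >= config.stop_threshold)[0]
    start_size = int(start_hits[0]) + 1 if start_hits.size else min(config.fallback_start, d)
    stop_size = int(stop_hits[0]) + 1 if stop_hits.size else d
    start_size = min(start_size, stop_size)
    return order, cum, start_size, stop_size


def _nn1_predict(
    train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray
) -> np.ndarray:
    """1-NN under cityblock distance; equal distances resolve to the
    lowest training-row index."""
    dist = cdist(test_X, train_X, metric="cityblock")
    return train_y[np.argmin(dist, axis=1)]


def _standardize_pair(
    train_X: np.ndarray, test_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean/unit-variance scaling fit on the training fold only;
    zero-variance columns are left centered but unscaled."""
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train_X - mu) / sd, (test_X - mu) / sd


def make_folds(labels: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified k-fold test-index sets; degrades to plain k-fold
    with a logged warning when some class has fewer members than folds."""
    _, counts = np.unique(labels, return_counts=True)
    idx = np.arange(labels.size)
    if counts.min() < n_folds:
        logger.warning(
            "class with %d members < %d folds; falling back to non-stratified k-fold",
            counts.min(),
            n_folds,
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(idx)]
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(idx, labels)]


def knn_cv_loss(data: LabeledMatrix, config: CwincaConfig = CwincaConfig()) -> float:
    """Misclassification rate of a 1-NN (cityblock) classifier under
    seeded stratified k-fold CV with per-fold train-only standardization.
    """
    n = data.n_samples
    if n < config.cv_folds:
        raise ValueError(f"n={n} < cv_folds={config.cv_folds}")
    folds = make_folds(data.labels, config.cv_folds, config.seed)
    X, y = data.values, data.labels
    errors = 0
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        tr_X, te_X = _standardize_pair(X[mask], X[test_idx])
        pred = _nn1_predict(tr_X, y[mask], te_X)
        errors += int((pred != y[test_idx]).sum())
    return errors / n


def cwinca_select(
    data: LabeledMatrix,
    config: CwincaConfig = CwincaConfig(),
    nca_config: NcaConfig = NcaConfig(),
) -> SelectionTrace:
    """Run the full CWINCA pipeline and return its trace.

    Normalize, fit NCA weights, bound the size window by cumulative
    weight, score every prefix size with :func:`knn_cv_loss` (identical
    folds across sizes), and keep the smallest size attaining the minimal
    loss.  Deterministic given the two seeds.
    """
    normed = minmax_normalize(data, config.epsilon)
    model = fit_nca_weights(normed, nca_config)
    order, cum, start_size, stop_size = cumulative_bounds(model.weights, config)
    ranked = [data.feature_names[j] for j in order]
    losses = []
    for size in range(start_size, stop_size + 1):
        subset = LabeledMatrix(
            normed.values[:, order[:size]], normed.labels, ranked[:size]
        )
        losses.append(knn_cv_loss(subset, config))
    losses_arr = np.asarray(losses)
    offset = int(np.argmin(losses_arr))  # first minimum -> smallest size
    chosen_size = start_size + offset
    return SelectionTrace(
        ranked_features=ranked,
        cumulative_weights=cum,
        start_size=start_size,
        stop_size=stop_size,
        losses=losses_arr,
        best_loss=float(losses_arr[offset]),
        chosen_size=chosen_size,
        selected_features=ranked[:chosen_size],
    )


def nested_selection_loss(
    data: LabeledMatrix,
    config: CwincaConfig = CwincaConfig(),
    nca_config: NcaConfig = NcaConfig(),
) -> float:
    """Leakage-safe estimate: re-run CWINCA inside each outer fold.

    The default :func:`cwinca_select` replicates the select-then-CV order
    (selection sees every label once), which optimistically biases the
    reported loss.  Here feature selection is refit on each outer
    training fold and the held-out fold is scored on that fold's selected
    features only.
    """
    n = data.n_samples
    folds = make_folds(data.labels, config.cv_folds, config.seed)
    errors = 0
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        train = LabeledMatrix(
            data.values[mask], data.labels[mask], list(data.feature_names)
        )
        trace = cwinca_select(train, config, nca_config)
        keep = [data.feature_names.index(f) for f in trace.selected_features]
        # normalize with the training fold's ranges, as the inner run did
        lo = train.values[:, keep].min(axis=0)
        hi = train.values[:, keep].max(axis=0)
        denom = hi - lo + config.epsilon
        tr = (train.values[:, keep] - lo) / denom
        te = (data.values[test_idx][:, keep] - lo) / denom
        tr_s, te_s = _standardize_pair(tr, te)
        pred = _nn1_predict(tr_s, train.labels, te_s)
        errors += int((pred != data.labels[test_idx]).sum())
    return errors / n
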