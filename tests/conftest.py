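"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the vectorized code paths of the
package: objectives are accumulated pair by pair, cross-validation folds
are scored point by point, and candidate subset sizes are enumerated
naively.  They exist so the fast implementations can be checked against
slow, obviously-correct ones.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from cwinca.data import LabeledMatrix
from cwinca.selection import make_folds


def brute_nca_objective(X, y, w, lam) -> float:
    """Pairwise-enumeration evaluation of the NCA objective; no vectorization."""
    n, d = X.shape
    total = 0.0
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            dij = 0.0
            for r in range(d):
                dij += (w[r] ** 2) * abs(X[i][r] - X[j][r])
            dists.append((j, dij))
        mx = max(-dij for _, dij in dists)
        denom = sum(math.exp(-dij - mx) for _, dij in dists)
        p_i = 0.0
        for j, dij in dists:
            if y[j] == y[i]:
                p_i += math.exp(-dij - mx) / denom
        total += p_i
    penalty = lam * sum(wr ** 2 for wr in w)
    return total / n - penalty


def brute_knn_fold_loss(X, y, fold_test_sets) -> float:
    """Fold-by-fold 1-NN (cityblock) with train-only standardization,
    scored one test point at a time; nearest-neighbor ties go to the
    lowest training index."""
    n = len(y)
    errors = 0
    for test_idx in fold_test_sets:
        test_set = set(int(t) for t in test_idx)
        train_idx = [i for i in range(n) if i not in test_set]
        mu = np.mean(X[train_idx], axis=0)
        sd = np.std(X[train_idx], axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        for t in test_set:
            xt = (X[t] - mu) / sd
            best_d, best_i = None, None
            for i in train_idx:
                xi = (X[i] - mu) / sd
                dist = float(np.abs(xt - xi).sum())
                if best_d is None or dist < best_d:
                    best_d, best_i = dist, i
            if y[best_i] != y[t]:
                errors += 1
    return errors / n


def brute_size_sweep(data: LabeledMatrix, order, start, stop, folds):
    """Naive enumeration of candidate prefix sizes; returns
    (losses, chosen_size, best_loss) with first-minimum tie-break."""
    losses = []
    for size in range(start, stop + 1):
        losses.append(
            brute_knn_fold_loss(data.values[:, order[:size]], data.labels, folds)
        )
    best = min(losses)
    chosen = start + losses.index(best)
    return losses, chosen, best


def random_labeled_matrix(rng, n_max=12, d_max=5, n_min=4) -> LabeledMatrix:
    """Small random two-class instance; guaranteed two classes."""
    n = int(rng.integers(n_min, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    X = rng.normal(size=(n, d))
    y = rng.integers(0, 2, size=n)
    y[0], y[1] = 0, 1
    return LabeledMatrix(X, y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_fixture():
    """Frozen n=6, d=2 instance used by hand-verified objective checks."""
    X = np.array(
        [[0.0, 1.0], [0.2, 0.9], [1.0, 0.0], [0.9, 0.1], [0.5, 0.5], [0.4, 0.6]]
    )
    y = np.array(["A", "A", "B", "B", "A", "B"])
    return LabeledMatrix(X, y)


@pytest.fixture
def shared_folds():
    def _make(labels, n_folds, seed):
        return make_folds(np.asarray(labels), n_folds, seed)

    return _make
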