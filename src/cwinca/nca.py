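"""Neighborhood Component Analysis for feature weighting.

This is the feature-selection variant of NCA: instead of learning a full
linear transformation, it learns one nonnegative weight per feature by
maximizing the expected leave-one-out accuracy of a stochastic 1-NN
classifier under a softmax over weighted cityblock (L1) distances,

    d_w(i, j) = sum_r  w_r^2 * |x_ir - x_jr|
    p_ij      = exp(-d_w(i, j)) / sum_{k != i} exp(-d_w(i, k)),   p_ii = 0
    p_i       = sum_{j in class(i), j != i} p_ij
    F(w)      = (1/n) * sum_i p_i  -  lambda * sum_r w_r^2

F is maximized by per-sample stochastic gradient ascent.  Weights enter
the distance only through their squares, so the sign of each weight is
immaterial; the fitted model stores the nonnegative representative.
Features with large fitted weight are those whose scale helps same-class
samples be each other's soft nearest neighbors — the importance score
the downstream cumulative-weight selection ranks on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import LabeledMatrix

__all__ = ["NcaConfig", "NcaModel", "nca_objective", "nca_gradient", "fit_nca_weights"]


@dataclass(frozen=True)
class NcaConfig:
    """Hyperparameters of the SGD fit.

    ``regularization`` is the L2 penalty lambda; ``None`` resolves to the
    documented default ``1/n`` at fit time.  The seed fully determines the
    per-epoch sample visit order, making fits bit-reproducible.
    """

    regularization: float | None = None
    learning_rate: float = 0.01
    epochs: int = 50
    seed: int = 0
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.regularization is not None and self.regularization < 0:
            raise ValueError("regularization must be nonnegative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be a positive integer")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class NcaModel:
    """Fitted per-feature weights plus fit diagnostics."""

    weights: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")

    def to_json(self, path: str | Path, config: NcaConfig | None = None) -> None:
        doc = {
            "weights": self.weights.tolist(),
            "config": (
                {
                    "regularization": config.regularization,
                    "learning_rate": config.learning_rate,
                    "epochs": config.epochs,
                    "seed": config.seed,
                    "tolerance": config.tolerance,
                }
                if config is not None
                else {}
            ),
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NcaModel":
        doc = json.loads(Path(path).read_text())
        return cls(np.asarray(doc["weights"], dtype=float), converged=doc["converged"])


def _check_weights(data: LabeledMatrix, weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (data.n_features,):
        raise ValueError(
            f"expected weights of length d={data.n_features}, got {w.shape}"
        )
    if not np.isfinite(w).all():
        raise ValueError("weights contain non-finite values")
    return w


def _softmax_rows(neg_dist: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction; the diagonal must already be -inf."""
    shifted = neg_dist - neg_dist.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=1, keepdims=True)


def _pairwise_terms(
    X: np.ndarray, labels: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return (p, same) where p[i, j] = p_ij and same[i, j] = 1{class match, i != j}."""
    w2 = w * w
    # d[i, j] = sum_r w_r^2 |x_ir - x_jr|
    d = np.abs(X[:, None, :] - X[None, :, :]) @ w2
    neg = -d
    np.fill_diagonal(neg, -np.inf)
    p = _softmax_rows(neg)
    same = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    return p, same


def nca_objective(
    data: LabeledMatrix, weights: np.ndarray, regularization: float = 0.0
) -> float:
    """Regularized expected leave-one-out 1-NN accuracy F(w).

    Deterministic and invariant under permutation of the samples.  For a
    two-sample data set whose samples belong to different classes every
    p_i is zero and F(w) = -lambda * ||w||^2.
    """
    w = _check_weights(data, weights)
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    p, same = _pairwise_terms(data.values, data.labels, w)
    p_i = (p * same).sum(axis=1)
    return float(p_i.mean() - regularization * np.sum(w * w))


def nca_gradient(
    data: LabeledMatrix, weights: np.ndarray, regularization: float = 0.0
) -> np.ndarray:
    """Closed-form gradient of :func:`nca_objective` with respect to w.

    With D[i, j, r] = |x_ir - x_jr|,

        dF/dw_r = (2 w_r / n) * sum_i [ p_i * sum_k p_ik D_ikr
                                        - sum_{j in class(i)} p_ij D_ijr ]
                  - 2 * lambda * w_r
    """
    w = _check_weights(data, weights)
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    X, labels = data.values, data.labels
    p, same = _pairwise_terms(X, labels, w)
    diffs = np.abs(X[:, None, :] - X[None, :, :])  # (n, n, d)
    p_i = (p * same).sum(axis=1)
    # sum over k of p_ik * D_ikr  -> (n, d); likewise restricted to same class
    weighted_all = np.einsum("ij,ijr->ir", p, diffs)
    weighted_same = np.einsum("ij,ijr->ir", p * same, diffs)
    data_term = (p_i[:, None] * weighted_all - weighted_same).mean(axis=0)
    return 2.0 * w * data_term - 2.0 * regularization * w


def _sample_gradient(
    X: np.ndarray, same_i: np.ndarray, i: int, w: np.ndarray, lam: float
) -> np.ndarray:
    """Gradient of p_i - lambda*||w||^2 for a single anchor sample i."""
    w2 = w * w
    diffs = np.abs(X - X[i])  # (n, d)
    neg = -(diffs @ w2)
    neg[i] = -np.inf
    shifted = neg - neg.max()
    expd = np.exp(shifted)
    p = expd / expd.sum()
    p_i = float(p @ same_i)
    data_term = p_i * (p @ diffs) - (p * same_i) @ diffs
    return 2.0 * w * data_term - 2.0 * lam * w


def fit_nca_weights(data: LabeledMatrix, config: NcaConfig = NcaConfig()) -> NcaModel:
    """Fit per-feature NCA weights by stochastic gradient ascent.

    One epoch visits every sample once in a seeded random order and applies
    the per-sample gradient with step ``learning_rate / sqrt(epoch)``.  The
    full objective is evaluated at the end of each epoch; fitting stops
    early once its relative change stays below ``tolerance`` for three
    consecutive epochs.  Identical data and config give bit-identical
    weights.
    """
    n, d = data.values.shape
    if len(set(data.labels.tolist())) < 2:
        raise ValueError("need >= 2 classes")
    lam = config.regularization if config.regularization is not None else 1.0 / n
    X = data.values
    same = (data.labels[:, None] == data.labels[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    rng = np.random.default_rng(config.seed)
    w = np.ones(d)
    trace: list[float] = []
    converged = False
    quiet_epochs = 0
    for epoch in range(1, config.epochs + 1):
        lr = config.learning_rate / np.sqrt(epoch)
        for i in rng.permutation(n):
            w = w + lr * _sample_gradient(X, same[i], int(i), w, lam)
        trace.append(nca_objective(data, w, lam))
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            rel = abs(cur - prev) / max(abs(prev), 1e-12)
            quiet_epochs = quiet_epochs + 1 if rel < config.tolerance else 0
            if quiet_epochs >= 3:
                converged = True
                break
    return NcaModel(weights=np.abs(w), objective_trace=trace, converged=converged)
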