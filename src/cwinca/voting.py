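"""Iterative hybrid majority voting (IHMV) over prediction vectors.

Each classifier run contributes a prediction vector (its out-of-fold
label for every sample).  IHMV sorts the vectors by accuracy, applies
plain mode voting to the top-k for every k from 3 to m, and keeps the
voted labeling with the highest accuracy (smallest k on ties).  Because
k = m is always evaluated, the result can never be worse than a single
majority vote over all models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PredictionSet", "VotedResult", "mode_vote", "ihmv", "vote_with_k"]


@dataclass
class PredictionSet:
    """m prediction vectors over n samples plus the ground truth.

    ``accuracies`` may be omitted, in which case they are recomputed from
    the predictions; when given they are verified against the data.
    """

    predictions: np.ndarray  # (m, n) labels
    truth: np.ndarray  # (n,) labels
    model_names: list[str] = field(default_factory=list)
    accuracies: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions)
        self.truth = np.asarray(self.truth)
        if self.predictions.ndim != 2:
            raise ValueError("predictions must be an m x n matrix")
        m, n = self.predictions.shape
        if m < 1 or n < 1:
            raise ValueError("need m >= 1 models and n >= 1 samples")
        if self.truth.shape != (n,):
            raise ValueError(
                f"truth length {self.truth.shape} does not match n={n}"
            )
        if not self.model_names:
            self.model_names = [f"model_{i + 1}" for i in range(m)]
        if len(self.model_names) != m:
            raise ValueError("model_names length must equal m")
        recomputed = (self.predictions == self.truth[None, :]).mean(axis=1)
        if self.accuracies is None:
            self.accuracies = recomputed
        else:
            self.accuracies = np.asarray(self.accuracies, dtype=float)
            if not np.allclose(self.accuracies, recomputed):
                raise ValueError("accuracies do not match predictions vs truth")

    @property
    def n_models(self) -> int:
        return self.predictions.shape[0]

    @property
    def n_samples(self) -> int:
        return self.predictions.shape[1]


@dataclass
class VotedResult:
    """Output of the k-sweep: the winning voted labeling and the sweep itself."""

    voted_labels: np.ndarray
    ensemble_size: int
    ensemble_members: list[str]
    accuracy: float
    per_k_accuracies: np.ndarray
    k_values: np.ndarray

    def to_dict(self) -> dict:
        return {
            "voted_labels": np.asarray(self.voted_labels).tolist(),
            "ensemble_size": self.ensemble_size,
            "ensemble_members": self.ensemble_members,
            "accuracy": self.accuracy,
            "per_k_accuracies": np.asarray(self.per_k_accuracies).tolist(),
            "k_values": np.asarray(self.k_values).tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def mode_vote(predictions: np.ndarray, model_order: np.ndarray | None = None) -> np.ndarray:
    """Per-sample most frequent label among k model rows.

    ``model_order`` ranks the rows by decreasing accuracy (best first;
    default: row order).  A tied count is resolved by the vote of the
    best-ranked model that voted for one of the tied labels; a residual
    tie falls back to the smallest label in canonical order.
    """
    predictions = np.asarray(predictions)
    if predictions.ndim != 2 or predictions.size == 0:
        raise ValueError("predictions must be a non-empty k x n matrix")
    k, n = predictions.shape
    order = np.arange(k) if model_order is None else np.asarray(model_order)
    out = np.empty(n, dtype=predictions.dtype)
    for s in range(n):
        votes = predictions[:, s]
        labels, counts = np.unique(votes, return_counts=True)
        top = labels[counts == counts.max()]
        if top.size == 1:
            out[s] = top[0]
            continue
        tied = set(top.tolist())
        winner = None
        for row in order:  # best-ranked voter for a tied label decides
            if votes[row] in tied:
                winner = votes[row]
                break
        out[s] = winner if winner is not None else np.sort(top)[0]
    return out


def _rank_models(pset: PredictionSet) -> np.ndarray:
    """Model indices by descending accuracy, ties by original order."""
    return np.argsort(-np.asarray(pset.accuracies), kind="stable")


def ihmv(pset: PredictionSet) -> VotedResult:
    """Accuracy-sorted k-sweep of mode votes, k = 3..m (k = m when m < 3).

    Returns the voted labeling with maximal accuracy against the truth,
    taking the smallest k on ties, together with the full sweep.
    """
    m = pset.n_models
    rank = _rank_models(pset)
    ks = np.arange(3, m + 1) if m >= 3 else np.array([m])
    accs = np.empty(ks.size)
    votes = []
    for j, k in enumerate(ks):
        members = rank[:k]
        voted = mode_vote(pset.predictions[members], np.arange(k))
        votes.append(voted)
        accs[j] = float((voted == pset.truth).mean())
    best = int(np.argmax(accs))  # first maximum -> smallest k
    k_best = int(ks[best])
    return VotedResult(
        voted_labels=votes[best],
        ensemble_size=k_best,
        ensemble_members=[pset.model_names[i] for i in rank[:k_best]],
        accuracy=float(accs[best]),
        per_k_accuracies=accs,
        k_values=ks,
    )


def vote_with_k(predictions: np.ndarray, accuracies: np.ndarray, k: int) -> np.ndarray:
    """Deployment-mode vote: apply a frozen ensemble depth k chosen during
    calibration, ranking models by the calibration accuracies (no truth
    needed at prediction time)."""
    predictions = np.asarray(predictions)
    rank = np.argsort(-np.asarray(accuracies, dtype=float), kind="stable")
    k = min(int(k), predictions.shape[0])
    return mode_vote(predictions[rank[:k]], np.arange(k))
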