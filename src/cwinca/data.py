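"""Labeled feature matrices and their CSV/TSV round trip.

The whole toolkit operates on one container: an ``n x d`` numeric feature
matrix with an ``n``-vector of class labels.  Rows are samples (texts,
embeddings, ...), columns are features, and labels may be strings or
integers — they are carried through opaquely and only compared for
equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LabeledMatrix", "read_labeled_csv", "write_labeled_csv"]


@dataclass
class LabeledMatrix:
    """An ``n x d`` feature matrix with per-row class labels.

    Parameters
    ----------
    values
        Real-valued matrix of shape ``(n, d)``; must be finite.
    labels
        Length-``n`` vector of class identifiers with at least two
        distinct values, each class non-empty.
    feature_names
        Optional length-``d`` unique names; autogenerated ``f1..fd``
        when omitted.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise ValueError(f"need n >= 2 and d >= 1, got shape {(n, d)}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,):
            raise ValueError(
                f"labels must have length {n}, got {self.labels.shape}"
            )
        if len(set(self.labels.tolist())) < 2:
            raise ValueError("need >= 2 classes")
        if not self.feature_names:
            self.feature_names = [f"f{j + 1}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError(
                f"expected {d} feature names, got {len(self.feature_names)}"
            )
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Distinct labels in canonical (sorted) order."""
        return np.unique(self.labels)

    def select_features(self, names: list[str]) -> "LabeledMatrix":
        """Return the sub-matrix restricted to the named columns, in order."""
        pos = {name: j for j, name in enumerate(self.feature_names)}
        missing = [name for name in names if name not in pos]
        if missing:
            raise KeyError(f"unknown feature names: {missing}")
        idx = [pos[name] for name in names]
        return LabeledMatrix(self.values[:, idx], self.labels, list(names))


def read_labeled_csv(
    path: str | Path, label_col: str = "label", sep: str | None = None
) -> LabeledMatrix:
    """Read a feature matrix from CSV/TSV (header row required).

    Every column other than ``label_col`` must be numeric and becomes a
    feature.  Missing values are an error, never imputed.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not in {list(df.columns)}")
    labels = df[label_col].to_numpy()
    feats = df.drop(columns=[label_col])
    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()
        raise ValueError(f"missing values in feature columns {bad}")
    values = feats.to_numpy(dtype=float)
    return LabeledMatrix(values, labels, [str(c) for c in feats.columns])


def write_labeled_csv(
    data: LabeledMatrix, path: str | Path, label_col: str = "label"
) -> None:
    df = pd.DataFrame(data.values, columns=data.feature_names)
    df[label_col] = data.labels
    df.to_csv(path, index=False)
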