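"""End-to-end orchestration: selection, classifier bank, voting, metrics.

For each named feature set (one per embedding backend) plus their
column-wise concatenation, the pipeline runs CWINCA selection, trains a
bank of classifiers under seeded stratified k-fold cross-validation,
records every out-of-fold prediction vector, fuses them with iterative
hybrid majority voting, and reports confusion matrices with per-class
and macro-averaged precision/recall/F1.  Out-of-fold vectors are used
throughout because only they carry honest accuracies for ranking the
ensemble.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import LabeledMatrix
from .nca import NcaConfig
from .selection import (
    CwincaConfig,
    SelectionTrace,
    _nn1_predict,
    _standardize_pair,
    cwinca_select,
    make_folds,
)
from .text import concat_features
from .voting import PredictionSet, VotedResult, ihmv

__all__ = [
    "ClassifierSpec",
    "MetricsReport",
    "crossval_predictions",
    "compute_metrics",
    "run_pipeline",
    "Report",
    "DEFAULT_BANK",
]

logger = logging.getLogger(__name__)

SUPPORTED_KINDS = ("svm_poly", "knn", "tree", "neural_net", "logistic", "ensemble_bag")


@dataclass(frozen=True)
class ClassifierSpec:
    """One member of the classifier bank.

    Defaults mirror common presets: cubic-kernel SVM with C=1, 1-NN with
    cityblock distance, CART tree, one-hidden-layer network of 100
    units, L2 logistic regression, and bagging over 30 trees.  Any
    hyperparameter can be overridden through ``hyperparameters``.
    """

    kind: str
    hyperparameters: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SUPPORTED_KINDS:
            raise ValueError(
                f"unsupported classifier kind {self.kind!r}; "
                f"supported: {list(SUPPORTED_KINDS)}"
            )

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)

    def build(self):
        p = self.params
        if self.kind == "svm_poly":
            return SVC(
                kernel="poly",
                degree=p.get("degree", 3),
                C=p.get("C", 1.0),
                gamma=p.get("gamma", "scale"),
                coef0=p.get("coef0", 1.0),
                random_state=self.seed,
            )
        if self.kind == "tree":
            return DecisionTreeClassifier(random_state=self.seed, **p)
        if self.kind == "neural_net":
            return MLPClassifier(
                hidden_layer_sizes=p.get("hidden_layer_sizes", (100,)),
                max_iter=p.get("max_iter", 300),
                random_state=self.seed,
            )
        if self.kind == "logistic":
            return LogisticRegression(
                C=p.get("C", 1.0), max_iter=p.get("max_iter", 1000)
            )
        if self.kind == "ensemble_bag":
            return BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=self.seed),
                n_estimators=p.get("n_estimators", 30),
                random_state=self.seed,
            )
        raise AssertionError(self.kind)  # knn handled separately


DEFAULT_BANK = (
    ClassifierSpec("svm_poly"),
    ClassifierSpec("knn"),
    ClassifierSpec("tree"),
    ClassifierSpec("neural_net"),
    ClassifierSpec("logistic"),
    ClassifierSpec("ensemble_bag"),
)


@dataclass
class MetricsReport:
    """Confusion matrix plus percentage metrics.

    Rows of ``confusion`` are true classes, columns predicted, in the
    canonical order of ``class_labels``.  Per-class and macro values are
    percentages; macro values are unweighted class means.
    """

    confusion: np.ndarray
    class_labels: list
    accuracy: float
    per_class: dict
    macro: dict

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion)
        n = int(self.confusion.sum())
        assert abs(self.accuracy - 100.0 * np.trace(self.confusion) / n) < 1e-9
        for key in ("precision", "recall", "f1"):
            vals = [self.per_class[c][key] for c in map(str, self.class_labels)]
            assert abs(self.macro[key] - float(np.mean(vals))) < 1e-9

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_labels": [str(c) for c in self.class_labels],
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro": self.macro,
        }


def compute_metrics(truth: np.ndarray, predicted: np.ndarray) -> MetricsReport:
    """Confusion matrix, accuracy, per-class and macro P/R/F1 (percent).

    The label alphabet is the sorted union of truth and predictions.  A
    class never predicted gets precision 0 (logged); a class absent from
    the truth gets recall 0.
    """
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: truth {truth.shape} vs predicted {predicted.shape}"
        )
    labels = np.unique(np.concatenate([truth, predicted]))
    conf = confusion_matrix(truth, predicted, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, predicted, labels=labels, zero_division=0
    )
    missing = set(labels.tolist()) - set(np.unique(predicted).tolist())
    if missing:
        logger.warning("classes never predicted (precision set to 0): %s", missing)
    per_class = {
        str(lab): {
            "precision": 100.0 * prec[j],
            "recall": 100.0 * rec[j],
            "f1": 100.0 * f1[j],
        }
        for j, lab in enumerate(labels)
    }
    macro = {
        "precision": 100.0 * float(prec.mean()),
        "recall": 100.0 * float(rec.mean()),
        "f1": 100.0 * float(f1.mean()),
    }
    accuracy = 100.0 * float((truth == predicted).mean())
    return MetricsReport(conf, labels.tolist(), accuracy, per_class, macro)


def crossval_predictions(
    data: LabeledMatrix, spec: ClassifierSpec, folds: int = 10, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Out-of-fold prediction vector of one classifier.

    Each sample is predicted by a model trained on the other folds
    (seeded stratified assignment).  Returns (predictions, accuracy).
    The knn member uses the same standardized 1-NN as the selection
    stage, so its error equals ``knn_cv_loss`` under shared folds.
    """
    n = data.n_samples
    if n < folds:
        raise ValueError(f"n={n} < folds={folds}")
    fold_sets = make_folds(data.labels, folds, seed)
    X, y = data.values, data.labels
    preds = np.empty(n, dtype=y.dtype)
    for test_idx in fold_sets:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        if spec.kind == "knn":
            tr, te = _standardize_pair(X[mask], X[test_idx])
            preds[test_idx] = _nn1_predict(tr, y[mask], te)
        else:
            clf = spec.build()
            clf.fit(X[mask], y[mask])
            preds[test_idx] = clf.predict(X[test_idx])
    accuracy = float((preds == y).mean())
    return preds, accuracy


@dataclass
class Report:
    """Everything one pipeline run produced, JSON-serializable."""

    selection_traces: dict = field(default_factory=dict)
    model_accuracies: dict = field(default_factory=dict)
    model_metrics: dict = field(default_factory=dict)
    voted: VotedResult | None = None
    voted_metrics: MetricsReport | None = None

    def to_dict(self) -> dict:
        return {
            "selection_traces": {k: t.to_dict() for k, t in self.selection_traces.items()},
            "model_accuracies": self.model_accuracies,
            "model_metrics": {k: m.to_dict() for k, m in self.model_metrics.items()},
            "voted": self.voted.to_dict() if self.voted else None,
            "voted_metrics": self.voted_metrics.to_dict() if self.voted_metrics else None,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(
    feature_sets: dict[str, LabeledMatrix],
    classifiers: tuple[ClassifierSpec, ...] = DEFAULT_BANK,
    cwinca_config: CwincaConfig = CwincaConfig(),
    nca_config: NcaConfig = NcaConfig(),
    folds: int = 10,
    seed: int = 0,
    select: bool = True,
) -> Report:
    """Full run over every named feature set plus the combined set.

    Stages per set: CWINCA selection (optional), out-of-fold predictions
    for every classifier in the bank, then one IHMV fusion over all
    recorded vectors, each named ``<set>/<classifier>``.  Reproducible
    from the seeds alone.
    """
    if not feature_sets:
        raise ValueError("need at least one feature set")
    sets = dict(feature_sets)
    if len(sets) > 1:
        sets["combined"] = concat_features(list(feature_sets.values()))

    report = Report()
    vectors: list[np.ndarray] = []
    names: list[str] = []
    truth = next(iter(sets.values())).labels
    for set_name, matrix in sets.items():
        working = matrix
        if select:
            try:
                trace: SelectionTrace = cwinca_select(matrix, cwinca_config, nca_config)
            except Exception as exc:
                raise RuntimeError(f"selection failed on set {set_name!r}") from exc
            report.selection_traces[set_name] = trace
            from .selection import minmax_normalize

            working = minmax_normalize(matrix, cwinca_config.epsilon).select_features(
                trace.selected_features
            )
        for spec in classifiers:
            run_name = f"{set_name}/{spec.kind}"
            try:
                preds, acc = crossval_predictions(working, spec, folds, seed)
            except Exception as exc:
                raise RuntimeError(
                    f"classifier {spec.kind!r} failed on set {set_name!r}"
                ) from exc
            vectors.append(preds)
            names.append(run_name)
            report.model_accuracies[run_name] = acc
            report.model_metrics[run_name] = compute_metrics(truth, preds)
            logger.info("%s: out-of-fold accuracy %.4f", run_name, acc)

    pset = PredictionSet(np.stack(vectors), truth, names)
    report.voted = ihmv(pset)
    report.voted_metrics = compute_metrics(truth, report.voted.voted_labels)
    logger.info(
        "voted: k=%d accuracy %.4f", report.voted.ensemble_size, report.voted.accuracy
    )
    return report
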