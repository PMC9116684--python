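"""Classifiers over regulatory-effect features and repeated k-fold CV.

Three model families are supported: an RBF-kernel support vector machine,
a random forest, and a fully connected feed-forward network with six ReLU
hidden layers.  Evaluation is repeated stratified k-fold cross-validation;
the per-iteration score is the mean of per-fold accuracies and F1 is
computed on the pooled out-of-fold predictions (positive class: sensitive).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .feature_builder import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "CVResult",
    "train_classifier",
    "accuracy",
    "f1_score",
    "confusion_counts",
    "repeated_stratified_cv",
]


@dataclass
class ClassifierConfig:
    """Model family plus the (paper-unspecified) hyperparameters, all logged."""

    kind: str = "ksvm"
    rbf_width: float | str = "auto"  # sigma of the RBF kernel, or "auto"
    svm_cost: float = 1.0
    n_trees: int = 500
    features_per_split: str | int | float = "sqrt"
    hidden_layers: Sequence[int] = (512, 256, 128, 64, 32, 16)
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ksvm", "rf", "dnn"):
            raise ValueError(f"unknown classifier kind: {self.kind!r}")
        if self.kind == "dnn" and len(self.hidden_layers) != 6:
            raise ValueError("the network uses exactly 6 hidden layers")
        if isinstance(self.rbf_width, str) and self.rbf_width != "auto":
            raise ValueError("rbf_width must be positive or 'auto'")
        if not isinstance(self.rbf_width, str) and self.rbf_width <= 0:
            raise ValueError("rbf_width must be positive or 'auto'")

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return ClassifierConfig(self.kind, self.rbf_width, self.svm_cost, self.n_trees,
                                self.features_per_split, tuple(self.hidden_layers),
                                self.epochs, self.learning_rate, seed)


def _build_estimator(config: ClassifierConfig):
    if config.kind == "ksvm":
        # G(r, r') = exp(-||r - r'||^2 / (2 sigma^2))  =>  gamma = 1/(2 sigma^2).
        # "auto" width uses gamma = 1 / (n_features * Var(X)), sklearn's "scale".
        gamma = "scale" if config.rbf_width == "auto" else 1.0 / (2.0 * float(config.rbf_width) ** 2)
        return SVC(C=config.svm_cost, kernel="rbf", gamma=gamma, random_state=config.seed)
    if config.kind == "rf":
        return RandomForestClassifier(n_estimators=config.n_trees,
                                      max_features=config.features_per_split,
                                      random_state=config.seed)
    return MLPClassifier(hidden_layer_sizes=tuple(config.hidden_layers),
                         activation="relu", solver="adam",
                         learning_rate_init=config.learning_rate,
                         max_iter=config.epochs, random_state=config.seed)


@dataclass
class TrainedModel:
    """A fitted classifier bound to the column map it was trained on."""

    kind: str
    estimator: object
    columns: list[tuple[str, str]]

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        if features.columns != self.columns:
            raise ValueError("feature columns differ from the training column map")
        return self.estimator.predict(features.values)

    def predict_values(self, values: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(values, dtype=float))


def train_classifier(features: FeatureMatrix, config: ClassifierConfig) -> TrainedModel:
    y = features.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    est = _build_estimator(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence warnings at small epoch budgets
        est.fit(features.values, y)
    return TrainedModel(config.kind, est, list(features.columns))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    return (tp + tn) / total


def f1_score(tp: int, fp: int, fn: int) -> float:
    """2 TP / (2 TP + FP + FN); positive class is 'sensitive'."""
    for v in (tp, fp, fn):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("F1 undefined with no positives anywhere; returning 1.0")
        return 1.0
    return 2 * tp / denom


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, tn, fp, fn


# ---------------------------------------------------------------------------
# Repeated stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_accuracies: list[list[float]]  # one list of k accuracies per iteration
    iteration_accuracies: list[float]  # mean over folds, per iteration
    iteration_f1: list[float]  # pooled out-of-fold F1, per iteration
    n_iterations: int
    k: int
    base_seed: int
    fold_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.iteration_accuracies) != self.n_iterations:
            raise ValueError("iteration count mismatch")
        for a in self.iteration_accuracies:
            if not 0.0 <= a <= 1.0:
                raise ValueError("accuracy outside [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.iteration_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.iteration_accuracies, ddof=1)) if self.n_iterations > 1 else 0.0

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.iteration_f1))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "fold_accuracies": self.fold_accuracies,
            "iteration_accuracies": self.iteration_accuracies,
            "iteration_f1": self.iteration_f1,
            "n_iterations": self.n_iterations,
            "k": self.k,
            "base_seed": self.base_seed,
            "fold_seeds": self.fold_seeds,
            "mean_accuracy": self.mean_accuracy,
            "mean_f1": self.mean_f1,
        }, indent=1))


def repeated_stratified_cv(
    features: FeatureMatrix,
    config: ClassifierConfig,
    k: int = 10,
    n_iterations: int = 50,
    base_seed: int = 0,
) -> CVResult:
    """Repeat stratified k-fold CV with fresh fold assignments per iteration.

    Iteration ``i`` uses fold seed ``base_seed + i`` for both the fold split
    and the model seed, so the whole procedure is deterministic.
    """
    y = features.labels
    n_min = int(min((y == 0).sum(), (y == 1).sum()))
    if n_min < 2:
        raise ValueError("need at least 2 samples in each class")
    if n_min < k:
        logger.warning("repeated_stratified_cv: lowering k from %d to %d (smallest class)", k, n_min)
        k = n_min
    fold_acc_all: list[list[float]] = []
    it_acc: list[float] = []
    it_f1: list[float] = []
    seeds: list[int] = []
    for it in range(n_iterations):
        seed = base_seed + it
        seeds.append(seed)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_accs = []
        pooled_true: list[int] = []
        pooled_pred: list[int] = []
        cfg = config.with_seed(seed)
        for train_idx, val_idx in skf.split(features.values, y):
            est = _build_estimator(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(features.values[train_idx], y[train_idx])
            pred = est.predict(features.values[val_idx])
            tp, tn, fp, fn = confusion_counts(y[val_idx], pred)
            fold_accs.append(accuracy(tp, tn, fp, fn))
            pooled_true.extend(y[val_idx].tolist())
            pooled_pred.extend(np.asarray(pred, dtype=int).tolist())
        fold_acc_all.append(fold_accs)
        it_acc.append(float(np.mean(fold_accs)))
        tp, _, fp, fn = confusion_counts(np.array(pooled_true), np.array(pooled_pred))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            it_f1.append(f1_score(tp, fp, fn))
    return CVResult(fold_acc_all, it_acc, it_f1, n_iterations, k, base_seed, seeds)
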