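"""Diagnostic evaluation: confusion-matrix indices, ROC/AUC, and
stratified k-fold cross-validation.

All indices are percentages: accuracy (TP+TN)/total, sensitivity
TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN).
The k-fold protocol is stratified (per-fold positive counts differ by
at most one) and seeded; cross-validation fits the feature normalizer
and the classifier on each training portion only, so no information
leaks from a test fold.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from . import mnn
from .gabor_features import MinMaxNormalizer


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero for this confusion matrix."""


@dataclasses.dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true: Sequence[int],
                         y_pred: Sequence[int]) -> "ConfusionMatrix":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        return cls(tp=int(np.sum((t == 1) & (p == 1))),
                   tn=int(np.sum((t == 0) & (p == 0))),
                   fp=int(np.sum((t == 0) & (p == 1))),
                   fn=int(np.sum((t == 1) & (p == 0))))


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy (TP+TN)/(TP+TN+FP+FN) x 100%."""
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total * 100.0


def sensitivity(cm: ConfusionMatrix) -> float:
    """True positive rate TP/(TP+FN) x 100%."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no positive cases")
    return cm.tp / (cm.tp + cm.fn) * 100.0


def specificity(cm: ConfusionMatrix) -> float:
    """True negative rate TN/(TN+FP) x 100%."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no negative cases")
    return cm.tn / (cm.tn + cm.fp) * 100.0


def predictive_values(cm: ConfusionMatrix
                      ) -> Tuple[Optional[float], Optional[float]]:
    """(PPV, NPV) as percentages; a zero-denominator value is None."""
    ppv = cm.tp / (cm.tp + cm.fp) * 100.0 if cm.tp + cm.fp > 0 else None
    npv = cm.tn / (cm.tn + cm.fn) * 100.0 if cm.tn + cm.fn > 0 else None
    return ppv, npv


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, e.g. 96.875 -> 96.87."""
    return math.floor(x * 100.0) / 100.0


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area under the curve by the rank (midrank-tie) method."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclasses.dataclass
class FoldSplit:
    fold_assignments: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_assignments != fold)[0]


def stratified_kfold(labels: Sequence[int], k: int = 5,
                     seed: int = 0) -> FoldSplit:
    """Stratified fold assignment: seeded shuffle within each class,
    then round-robin distribution, so per-fold class counts differ by
    at most one."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} members, "
                             f"fewer than k={k}")
        rng.shuffle(idx)
        assignments[idx] = np.arange(len(idx)) % k
    return FoldSplit(fold_assignments=assignments, k=k, seed=seed)


@dataclasses.dataclass
class EvalReport:
    """Pooled diagnostic indices over a cross-validation run.

    Indices are computed on the pooled confusion counts; ``printed``
    carries the 2-decimal presentation (specificity truncated, the
    others rounded).  ``auc`` is the pooled-score AUC, ``auc_per_fold``
    the per-fold mean.
    """

    pooled: ConfusionMatrix
    per_fold: List[ConfusionMatrix]
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    auc: Optional[float]
    auc_per_fold: Optional[float] = None
    scores: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    predictions: Optional[np.ndarray] = None
    folds: Optional[np.ndarray] = None

    @property
    def printed(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 2),
            "sensitivity": round(self.sensitivity, 2),
            "specificity": truncate2(self.specificity),
            "ppv": None if self.ppv is None else round(self.ppv, 1),
            "npv": None if self.npv is None else round(self.npv, 1),
        }

    def to_dict(self) -> dict:
        return {
            "pooled": dataclasses.asdict(self.pooled),
            "per_fold": [dataclasses.asdict(cm) for cm in self.per_fold],
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
            "auc_per_fold": self.auc_per_fold,
            "printed": self.printed,
        }


def report_from_counts(cm: ConfusionMatrix,
                       per_fold: Optional[List[ConfusionMatrix]] = None,
                       auc: Optional[float] = None) -> EvalReport:
    """All diagnostic indices for one confusion matrix."""
    ppv, npv = predictive_values(cm)
    return EvalReport(pooled=cm, per_fold=per_fold or [cm],
                      accuracy=accuracy(cm), sensitivity=sensitivity(cm),
                      specificity=specificity(cm), ppv=ppv, npv=npv, auc=auc)


def cross_validate(features: np.ndarray, labels: Sequence[int], k: int = 5,
                   seed: int = 0,
                   layer_sizes: Optional[Sequence[int]] = None,
                   hidden_activation: Optional[mnn.ActivationSpec] = None,
                   output_activation: Optional[mnn.ActivationSpec] = None,
                   train_config: Optional[mnn.TrainConfig] = None,
                   threshold: float = 0.5) -> EvalReport:
    """Stratified k-fold CV of the MNN on a raw feature matrix.

    Per fold, the min-max normalizer and the network are fitted on the
    training portion only; held-out scores and predictions are pooled.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    split = stratified_kfold(y, k=k, seed=seed)
    if layer_sizes is None:
        layer_sizes = (X.shape[1], 10, 10, 1)
    train_config = train_config or mnn.TrainConfig()

    scores = np.zeros(len(y))
    preds = np.zeros(len(y), dtype=int)
    per_fold: List[ConfusionMatrix] = []
    fold_aucs: List[float] = []
    for fold in range(k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        norm = MinMaxNormalizer(data_min=X[tr].min(axis=0),
                                data_max=X[tr].max(axis=0))
        Xtr = norm.transform_matrix(X[tr])
        Xte = norm.transform_matrix(X[te])
        model = mnn.init_model(layer_sizes, seed=seed * 1000 + fold,
                               hidden_activation=hidden_activation,
                               output_activation=output_activation)
        model, _ = mnn.train(model, Xtr, y[tr], train_config)
        s = mnn.predict_scores(model, Xte)
        scores[te] = s
        preds[te] = (s >= threshold).astype(int)
        per_fold.append(ConfusionMatrix.from_predictions(y[te], preds[te]))
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(roc_auc(s, y[te]))

    pooled = ConfusionMatrix.from_predictions(y, preds)
    ppv, npv = predictive_values(pooled)
    return EvalReport(
        pooled=pooled, per_fold=per_fold,
        accuracy=accuracy(pooled), sensitivity=sensitivity(pooled),
        specificity=specificity(pooled), ppv=ppv, npv=npv,
        auc=roc_auc(scores, y),
        auc_per_fold=float(np.mean(fold_aucs)) if fold_aucs else None,
        scores=scores, labels=y, predictions=preds,
        folds=split.fold_assignments)


def bootstrap_ci(metric_values: Sequence[float], n_resamples: int = 2000,
                 seed: int = 0, level: float = 0.95) -> Tuple[float, float]:
    """Percentile bootstrap CI of the mean of per-sample metric values."""
    rng = np.random.default_rng(seed)
    values = np.asarray(metric_values, dtype=float)
    means = rng.choice(values, size=(n_resamples, len(values)),
                       replace=True).mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(means, lo)),
            float(np.quantile(means, 1.0 - lo)))
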