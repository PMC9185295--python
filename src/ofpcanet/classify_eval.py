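"""Clip-level classification and leave-one-subject-out evaluation.

Per-tensor PCANet+ features are aggregated into one vector per clip, a
linear one-vs-rest SVM is trained on the clips of all-but-one subject, and
the held-out subject's clips are predicted.  Per-fold predictions are pooled
into a single confusion matrix before computing accuracy, per-class
precision/recall, macro-F1 and macro-recall, so that each clip contributes
exactly once to the reported metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .clip_io import DatasetIndex
from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)


def aggregate_clip_feature(
    features: list[np.ndarray] | np.ndarray, mode: str = "mean"
) -> np.ndarray:
    """Combine the per-tensor features of one clip into a single vector.

    ``mode='mean'`` (default) averages element-wise; ``'sum'`` adds.  The
    output length equals the per-tensor feature length.
    """
    features = [np.asarray(f, dtype=np.float64) for f in features]
    if len(features) == 0:
        raise InputError("cannot aggregate an empty feature list")
    lengths = {f.shape for f in features}
    if len(lengths) > 1:
        raise InputError(f"feature lengths differ: {sorted(lengths)}")
    stacked = np.stack(features)
    if mode == "mean":
        return stacked.mean(axis=0)
    if mode == "sum":
        return stacked.sum(axis=0)
    raise ConfigError(f"unknown aggregation mode {mode!r}")


@dataclass(frozen=True)
class LosoFold:
    subject: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def loso_split(index: DatasetIndex) -> list[LosoFold]:
    """Leave-one-subject-out folds in first-appearance subject order.

    Each fold tests on all clips of one subject and trains on every other
    clip; folds partition the dataset and no subject ever appears on both
    sides of a fold.
    """
    subjects = index.subjects
    if len(subjects) < 2:
        raise ConfigError(
            f"LOSO requires at least 2 subjects, found {len(subjects)}"
        )
    folds = []
    for subj in subjects:
        test = tuple(e.clip_id for e in index.entries if e.subject == subj)
        train = tuple(e.clip_id for e in index.entries if e.subject != subj)
        folds.append(LosoFold(subject=subj, train_ids=train, test_ids=test))
    return folds


def fit_predict_linear_svm(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    *,
    C: float = 1.0,
    standardize: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Train a linear one-vs-rest SVM and predict the test clips.

    Features are standardized (zero mean, unit variance per dimension) using
    training-fold statistics only.  Regularization ``C`` defaults to 1.0 with
    no inner tuning loop.
    """
    train_features = np.asarray(train_features, dtype=np.float64)
    train_labels = np.asarray(train_labels)
    if train_features.shape[0] == 0:
        raise InputError("empty training set")
    if len(np.unique(train_labels)) < 2:
        raise ConfigError(
            f"training fold contains a single class "
            f"({np.unique(train_labels).tolist()}); cannot fit an SVM"
        )
    X_train, X_test = train_features, np.asarray(test_features, dtype=np.float64)
    if standardize:
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
    clf = LinearSVC(C=C, multi_class="ovr", max_iter=20000, random_state=seed)
    clf.fit(X_train, train_labels)
    return clf.predict(X_test)


@dataclass
class ConfusionMatrix:
    """C x C count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise InputError(
                f"counts shape {self.counts.shape} does not match "
                f"{c} class names"
            )
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise InputError("confusion counts must be non-negative integers")

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, class_names: list[str]
    ) -> "ConfusionMatrix":
        lut = {c: i for i, c in enumerate(class_names)}
        counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[lut[t], lut[p]] += 1
        return cls(counts=counts, class_names=list(class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Accuracy, per-class precision/recall, macro-F1 and macro-recall.

    ``macro_recall`` averages R_i = TP_i / (TP_i + FN_i) over classes (the
    headline value); ``macro_precision`` averages P_i = TP_i / (TP_i + FP_i)
    and is reported alongside for completeness.
    """

    accuracy: float
    macro_f1: float
    macro_recall: float
    macro_precision: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "per_class": self.per_class,
        }


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute classification metrics from a confusion matrix.

    Accuracy is trace/total.  Per-class precision and recall use the
    convention 0/0 = 0 (with a logged warning), as can happen when a class is
    absent from a small fold; the per-class F1 term is likewise 0 when
    P_i + R_i = 0.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise InputError("confusion matrix is empty")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
        out = np.zeros_like(num)
        zero = den == 0
        if np.any(zero):
            logger.warning(
                "%s undefined for class(es) %s (0/0); reporting 0",
                what,
                [cm.class_names[i] for i in np.flatnonzero(zero)],
            )
        out[~zero] = num[~zero] / den[~zero]
        return out

    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    pr = precision + recall
    f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    per_class = {
        name: {
            "precision": float(precision[i]),
            "recall": float(recall[i]),
            "f1": float(f1[i]),
        }
        for i, name in enumerate(cm.class_names)
    }
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        macro_f1=float(f1.mean()),
        macro_recall=float(recall.mean()),
        macro_precision=float(precision.mean()),
        per_class=per_class,
    )


def evaluate_loso(
    clip_features: dict[str, np.ndarray],
    index: DatasetIndex,
    *,
    C: float = 1.0,
    standardize: bool = True,
    seed: int = 0,
) -> dict:
    """Run the full LOSO protocol on precomputed per-clip features.

    Returns a results document with per-fold predictions, the pooled
    confusion matrix and the metrics report.  (When filters must be learned
    per fold, use the pipeline runner instead, which retrains the bank on
    each fold's training subjects before extracting features.)
    """
    labels = {e.clip_id: e.label for e in index.entries}
    folds = loso_split(index)
    fold_records = []
    y_true_all: list[str] = []
    y_pred_all: list[str] = []
    for fold in folds:
        X_train = np.stack([clip_features[c] for c in fold.train_ids])
        y_train = np.array([labels[c] for c in fold.train_ids])
        X_test = np.stack([clip_features[c] for c in fold.test_ids])
        y_pred = fit_predict_linear_svm(
            X_train, y_train, X_test, C=C, standardize=standardize, seed=seed
        )
        y_true = [labels[c] for c in fold.test_ids]
        fold_records.append(
            {
                "subject": fold.subject,
                "clip_ids": list(fold.test_ids),
                "y_true": list(y_true),
                "y_pred": [str(p) for p in y_pred],
            }
        )
        y_true_all.extend(y_true)
        y_pred_all.extend(str(p) for p in y_pred)
    cm = ConfusionMatrix.from_predictions(y_true_all, y_pred_all, index.class_names)
    report = compute_metrics(cm)
    return {
        "folds": fold_records,
        "confusion_matrix": cm.counts.tolist(),
        "class_names": index.class_names,
        "metrics": report.as_dict(),
    }
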