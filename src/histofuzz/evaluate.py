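"""Stratified splits and the multi-class evaluation metric suite.

Per-class metrics are computed one-vs-rest from the C x C confusion
matrix: collapsing to (TP, FP, FN, TN) for class k gives binary accuracy
(TP+TN)/N, precision, recall, F1 and the Matthews correlation coefficient;
AUC uses the class-k score column against the rest with per-sample min-max
normalized scores.  The "average" row is the unweighted macro mean across
classes.  Per-class accuracy is one-vs-rest binary accuracy — the
convention under which per-class accuracy values differ from the overall
multiclass accuracy.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from histofuzz.synth import DatasetManifest

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "stratified_split",
    "stratified_split_indices",
    "confusion_and_metrics",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f_score", "auc", "mcc")


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split: per-class train count = round(f * n_k)."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_split_indices(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index arrays, stratified by label.

    Within each class the train count is ``round(train_fraction * n_k)``
    (half away from zero), clipped so both sides keep at least one sample.
    Deterministic under ``spec.seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts = [], []
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        if idx.size < 2:
            raise ValueError(
                f"class {value!r} has {idx.size} sample(s); need >= 2 to split")
        n_train = int(np.floor(spec.train_fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def stratified_split(
    manifest: DatasetManifest, spec: SplitSpec
) -> tuple[DatasetManifest, DatasetManifest]:
    """Split a manifest into stratified train and test manifests."""
    labels = manifest.frame["label"].to_numpy()
    train_idx, test_idx = stratified_split_indices(labels, spec)
    return (
        DatasetManifest(manifest.frame.iloc[train_idx].reset_index(drop=True)),
        DatasetManifest(manifest.frame.iloc[test_idx].reset_index(drop=True)),
    )


@dataclasses.dataclass
class EvaluationReport:
    """Per-class and macro metrics plus the confusion matrix."""

    class_names: tuple[str, ...]
    per_class: dict[str, dict[str, float]]  # class -> metric -> value
    average: dict[str, float]
    confusion: np.ndarray  # rows = true, cols = predicted
    n_test: int
    split: dict | None = None

    @property
    def overall_accuracy(self) -> float:
        """Plain multiclass accuracy, trace(confusion) / n."""
        return float(np.trace(self.confusion) / max(self.n_test, 1))

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "overall_accuracy": self.overall_accuracy,
            "per_class": {c: {m: self.per_class[c][m] for m in METRIC_NAMES}
                          for c in self.class_names},
            "average": {m: self.average[m] for m in METRIC_NAMES},
            "confusion_matrix": self.confusion.tolist(),
            "n_test": self.n_test,
            "split": self.split,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.class_names),
                            columns=list(self.class_names))


def _binary_mcc(tp: float, fp: float, fn: float, tn: float) -> float:
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


def confusion_and_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
    class_names: tuple[str, ...] | None = None,
) -> EvaluationReport:
    """Build the full evaluation report from labels, predictions and scores.

    ``scores`` is an (N, C) array of per-class decision scores (any scale;
    they are min-max normalized per sample before AUC).  A class absent
    from ``y_true`` gets NaN metrics, excluded from the macro mean with a
    warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n_classes = (int(max(y_true.max(), y_pred.max())) + 1
                 if class_names is None else len(class_names))
    if class_names is None:
        class_names = tuple(str(k) for k in range(n_classes))
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes)).astype(int)
    n = y_true.size

    norm_scores = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        lo = scores.min(axis=1, keepdims=True)
        hi = scores.max(axis=1, keepdims=True)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        norm_scores = (scores - lo) / span

    per_class: dict[str, dict[str, float]] = {}
    for k, name in enumerate(class_names):
        tp = float(cm[k, k])
        fn = float(cm[k].sum() - tp)
        fp = float(cm[:, k].sum() - tp)
        tn = float(n - tp - fn - fp)
        if cm[k].sum() == 0:
            warnings.warn(f"class {name!r} absent from test set; metrics undefined",
                          stacklevel=2)
            per_class[name] = {m: float("nan") for m in METRIC_NAMES}
            continue
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn)
        f_score = (2 * precision * recall / (precision + recall)
                   if precision + recall > 0 else 0.0)
        auc = float("nan")
        if norm_scores is not None:
            binary = (y_true == k).astype(int)
            auc = float(roc_auc_score(binary, norm_scores[:, k]))
        per_class[name] = {
            "accuracy": (tp + tn) / n,
            "precision": precision,
            "recall": recall,
            "f_score": f_score,
            "auc": auc,
            "mcc": _binary_mcc(tp, fp, fn, tn),
        }

    average = {}
    for m in METRIC_NAMES:
        values = [per_class[c][m] for c in class_names]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            average[m] = float(np.nanmean(values))
    return EvaluationReport(
        class_names=tuple(class_names),
        per_class=per_class,
        average=average,
        confusion=cm,
        n_test=int(n),
    )
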