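"""Stratified splitting and confusion-matrix-based per-subject metrics.

Per class c (one-vs-rest): TP = cm[c,c], FN = row sum - TP, FP = column sum
- TP, TN = remainder; recall = TP/(TP+FN), precision = TP/(TP+FP),
specificity = TN/(TN+FP), F1 = 2PR/(P+R).  Zero-denominator ratios are
reported as 0 and flagged.  Macro means are unweighted over classes;
accuracy = trace/total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .segmentation import BeatMatrix

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "split_train_test",
    "split_indices",
    "confusion_matrix",
    "per_class_metrics",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InvalidInputError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise InvalidInputError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


@dataclass
class MetricsReport:
    """Per-class specificity/recall/precision/F1, macro means and accuracy."""

    specificity: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    undefined_flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def macro_specificity(self) -> float:
        return float(self.specificity.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def summary(self) -> str:
        return (
            f"accuracy={self.accuracy:.4f} "
            f"macro_specificity={self.macro_specificity:.4f} "
            f"macro_recall={self.macro_recall:.4f} "
            f"macro_precision={self.macro_precision:.4f} "
            f"macro_f1={self.macro_f1:.4f}"
        )


def split_indices(labels, test_frac: float = 0.2, seed: int = 0):
    """Stratified per-class index split: test count = max(floor(n*frac), 1).

    Disjoint, exhaustive and reproducible under ``seed``.
    """
    labels = np.asarray(labels)
    if not 0 < test_frac < 1:
        raise InvalidInputError("test_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise InvalidInputError(
                f"class {cls!r} has {idx.size} beat(s); need >= 2 to split"
            )
        n_test = max(int(idx.size * test_frac), 1)
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def split_train_test(beats: BeatMatrix, test_frac: float = 0.2, seed: int = 0):
    """Split a beat matrix into stratified (train, test) beat matrices."""
    tr, te = split_indices(beats.labels, test_frac, seed)

    def take(idx):
        return BeatMatrix(
            beats=beats.beats[idx],
            labels=beats.labels[idx],
            k=beats.k,
            peak_offset=beats.peak_offset,
            record_ids=None if beats.record_ids is None else beats.record_ids[idx],
        )

    return take(tr), take(te)


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Tally counts[i, j] = number of samples of true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise InvalidInputError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest specificity/recall/precision/F1 per class plus accuracy."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise InvalidInputError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fp - fn

    def ratio(num, den, flag_name, flags):
        den = np.asarray(den, dtype=float)
        out = np.zeros_like(den)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        flags[flag_name] = ~ok
        return out

    flags: dict[str, np.ndarray] = {}
    recall = ratio(tp, tp + fn, "recall", flags)
    precision = ratio(tp, tp + fp, "precision", flags)
    specificity = ratio(tn, tn + fp, "specificity", flags)
    pr = precision + recall
    f1 = np.zeros_like(recall)
    ok = pr > 0
    f1[ok] = 2 * precision[ok] * recall[ok] / pr[ok]
    flags["f1"] = ~ok
    return MetricsReport(
        specificity=specificity,
        recall=recall,
        precision=precision,
        f1=f1,
        support=counts.sum(axis=1),
        accuracy=float(tp.sum() / total),
        undefined_flags=flags,
    )
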