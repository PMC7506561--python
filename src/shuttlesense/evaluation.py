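"""Confusion matrices, per-class and weighted precision/recall/F1, and
class-superset merging.

Per-class rates follow the usual one-vs-rest reading of the confusion
matrix (rows = truth, columns = prediction): tp is the diagonal entry,
fp the rest of the column, fn the rest of the row, with

    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)
    F1        = 2 * precision * recall / (precision + recall)

Rates with a zero denominator are reported as 0 and flagged, so weighted
averages stay defined on sparse synthetic data.  Weighted averages weight
each class by its true support.

Fine stroke classes can be collapsed into supersets (overhand vs
underhand strokes, or clear+smash into one overhead-power category):
merging never decreases accuracy, since correct predictions stay correct
and confusions inside a superset become correct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .signal_io import CLASSES

__all__ = [
    "MetricsReport",
    "ClassMapping",
    "confusion_matrix",
    "precision_recall_f1",
    "evaluate",
    "merge_classes",
    "accuracy",
    "event_segments",
    "event_accuracy",
]

#: Overhand strokes are hit above the shoulder, underhand below; the two
#: non-stroke activities pass through unchanged.
OVERHAND_STROKES = ("clear", "dab", "netdrop", "smash")
UNDERHAND_STROKES = ("drive", "short_serve", "lob")


@dataclass
class ClassMapping:
    """Total map from fine activity classes to superset labels."""

    mapping: dict[str, str]

    def __call__(self, label: str) -> str:
        if label not in self.mapping:
            raise KeyError(f"label {label!r} has no superset mapping")
        return self.mapping[label]

    @property
    def target_vocab(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for v in self.mapping.values():
            seen.setdefault(v)
        return tuple(seen)

    @classmethod
    def identity(cls, vocab: Sequence[str] = CLASSES) -> "ClassMapping":
        return cls({c: c for c in vocab})

    @classmethod
    def overhand_underhand(cls) -> "ClassMapping":
        """Collapse the seven strokes into overhand vs underhand."""
        m = {c: "overhand" for c in OVERHAND_STROKES}
        m.update({c: "underhand" for c in UNDERHAND_STROKES})
        m.update({"displacement": "displacement", "rest": "rest"})
        return cls(m)

    @classmethod
    def clear_smash(cls) -> "ClassMapping":
        """Merge the two fast overhead strokes, which are easily confused."""
        m = {c: c for c in CLASSES}
        m["clear"] = "overhead_power"
        m["smash"] = "overhead_power"
        return cls(m)


@dataclass
class MetricsReport:
    """Confusion matrix plus per-class and support-weighted rates."""

    class_vocab: tuple[str, ...]
    confusion: np.ndarray  # (K, K), rows = truth
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    undefined_classes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "class_vocab": list(self.class_vocab),
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "undefined_classes": list(self.undefined_classes),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        """Plain-text confusion table plus the summary rates."""
        width = max(12, max(len(c) for c in self.class_vocab) + 1)
        lines = ["truth \\ pred".ljust(width) + "".join(c.rjust(width) for c in self.class_vocab)]
        for i, c in enumerate(self.class_vocab):
            lines.append(c.ljust(width) + "".join(str(int(v)).rjust(width) for v in self.confusion[i]))
        lines.append("")
        lines.append(
            f"accuracy {self.accuracy:.4f} | weighted precision {self.weighted_precision:.4f} "
            f"recall {self.weighted_recall:.4f} F1 {self.weighted_f1:.4f}"
        )
        return "\n".join(lines)


def confusion_matrix(truth: Sequence[str], pred: Sequence[str],
                     vocab: Sequence[str] = CLASSES) -> np.ndarray:
    """K×K count matrix; entry (i, j) = positions with truth i, prediction j."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError(
            f"truth length {truth.shape} and prediction length {pred.shape} differ"
        )
    unknown = (set(truth) | set(pred)) - set(vocab)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in vocabulary")
    return _sk_confusion_matrix(truth, pred, labels=list(vocab))


def precision_recall_f1(confusion: np.ndarray,
                        vocab: Sequence[str] = CLASSES) -> MetricsReport:
    """Per-class and support-weighted rates from a confusion matrix."""
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1] or confusion.size == 0:
        raise ValueError(f"confusion matrix must be square and non-empty, got {confusion.shape}")
    vocab = tuple(vocab)
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    support = confusion.sum(axis=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)

    undefined = tuple(
        vocab[i] for i in range(len(vocab)) if (tp[i] + fp[i] == 0) or (tp[i] + fn[i] == 0)
    )
    total = confusion.sum()
    w = support / support.sum() if support.sum() else np.zeros_like(support)
    return MetricsReport(
        class_vocab=vocab,
        confusion=confusion,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support.astype(int),
        accuracy=float(tp.sum() / total) if total else 0.0,
        weighted_precision=float((w * precision).sum()),
        weighted_recall=float((w * recall).sum()),
        weighted_f1=float((w * f1).sum()),
        undefined_classes=undefined,
    )


def evaluate(truth: Sequence[str], pred: Sequence[str],
             vocab: Sequence[str] = CLASSES) -> MetricsReport:
    """Confusion matrix and rates in one step."""
    return precision_recall_f1(confusion_matrix(truth, pred, vocab), vocab)


def merge_classes(seq: Sequence[str], mapping: ClassMapping) -> np.ndarray:
    """Replace every fine label by its superset label."""
    return np.asarray([mapping(label) for label in seq], dtype=object)


def event_segments(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    """Maximal runs of one label: ``(start, stop, label)`` half-open spans."""
    labels = np.asarray(labels, dtype=object)
    out: list[tuple[int, int, str]] = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            out.append((start, t, labels[start]))
            start = t
    return out


def event_accuracy(truth: Sequence[str], pred: Sequence[str],
                   classes: Sequence[str] | None = None) -> float:
    """Stroke-sequence accuracy: each ground-truth activity segment counts
    once, predicted by the modal predicted label inside it.

    This is the per-event reading of a scenario — which activities were
    recognised — as opposed to per-sample accuracy, which also charges
    boundary placement to the classifier.  ``classes`` restricts scoring
    to segments whose true label is in the given set (e.g. just the
    drive/clear pair).
    """
    from .preprocessing import majority_label

    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    n = min(len(truth), len(pred))
    hits = total = 0
    for start, stop, label in event_segments(truth[:n]):
        if classes is not None and label not in classes:
            continue
        total += 1
        hits += majority_label(pred[start:stop]) == label
    if total == 0:
        raise ValueError("no ground-truth segments to score")
    return hits / total


def accuracy(truth: Sequence[str], pred: Sequence[str]) -> float:
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("sequences must have equal length")
    return float(np.mean(truth == pred))
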