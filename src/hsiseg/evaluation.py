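"""Confusion-matrix metrics: per-class precision/recall/F1, overall
accuracy, and first-level group aggregation.

Rows of the confusion matrix are truth, columns are prediction, class
ids 1..C map to indices 0..C-1; unlabeled truth pixels (0) are excluded
before counting. Precision_c = TP/(TP+FP), recall_c = TP/(TP+FN), F1 is
their harmonic mean; zero denominators yield 0 and are flagged. Macro
averages run over the classes actually present in the truth. Grouped
metrics collapse the matrix by summing rows and columns within each
first-level group before recomputing F1 — confusions inside a group
vanish, so collapsing never lowers overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ClassScheme, LabelMap

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "precision_recall_f1",
    "overall_accuracy",
    "group_metrics",
    "evaluate_labels",
]


def _as_labels(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelMap) else np.asarray(x)


def confusion_matrix(truth, predicted, n_classes: int | None = None
                     ) -> np.ndarray:
    """``C x C`` counts with rows = truth class, cols = predicted class."""
    t = _as_labels(truth)
    p = _as_labels(predicted)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if n_classes is None:
        if isinstance(truth, LabelMap):
            n_classes = truth.scheme.n_classes
        else:
            n_classes = int(max(t.max(initial=0), p.max(initial=0)))
    keep = t > 0
    t, p = t[keep], p[keep]
    if p.min(initial=1) < 1 or p.max(initial=1) > n_classes:
        bad = sorted(set(p[(p < 1) | (p > n_classes)]))
        raise ValueError(f"prediction contains ids outside the scheme: {bad}")
    if t.max(initial=1) > n_classes:
        raise ValueError("truth contains ids outside the scheme")
    counts = np.bincount((t - 1) * n_classes + (p - 1),
                         minlength=n_classes * n_classes)
    return counts.reshape(n_classes, n_classes).astype(np.int64)


def precision_recall_f1(confusion: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                   np.ndarray]:
    """Per-class ``(precision, recall, f1, degenerate_flag)``.

    The flag marks classes where a zero denominator forced a 0 rate.
    """
    confusion = np.asarray(confusion, dtype=np.float64)
    tp = np.diag(confusion)
    col = confusion.sum(axis=0)
    row = confusion.sum(axis=1)
    degenerate = (col == 0) | (row == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1),
                      0.0)
    return precision, recall, f1, degenerate


def overall_accuracy(confusion: np.ndarray) -> float:
    """Trace over total; errors on an empty (fully masked) matrix."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix: no labeled pixels")
    return float(np.trace(confusion) / total)


def _collapse(confusion: np.ndarray, scheme: ClassScheme
              ) -> tuple[np.ndarray, list[str]]:
    groups = scheme.group_names
    gidx = {g: i for i, g in enumerate(groups)}
    mapping = np.array([gidx[scheme.groups[i]] for i in scheme.ids])
    g = len(groups)
    collapsed = np.zeros((g, g), dtype=np.int64)
    np.add.at(collapsed, (mapping[:, None], mapping[None, :]), confusion)
    return collapsed, groups


def group_metrics(confusion: np.ndarray, scheme: ClassScheme
                  ) -> dict[str, float]:
    """F1 per first-level group after collapsing the confusion matrix."""
    collapsed, groups = _collapse(confusion, scheme)
    _, _, f1, _ = precision_recall_f1(collapsed)
    return dict(zip(groups, f1.tolist()))


@dataclass
class MetricsReport:
    """All metrics of one prediction, kept as fractions internally."""

    confusion: np.ndarray
    scheme: ClassScheme
    precision: np.ndarray = field(init=False)
    recall: np.ndarray = field(init=False)
    f1: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.precision, self.recall, self.f1, self._degenerate = \
            precision_recall_f1(self.confusion)

    @property
    def present(self) -> np.ndarray:
        return self.confusion.sum(axis=1) > 0

    @property
    def overall_accuracy(self) -> float:
        return overall_accuracy(self.confusion)

    @property
    def macro_precision(self) -> float:
        return float(self.precision[self.present].mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall[self.present].mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1[self.present].mean())

    @property
    def grouped_f1(self) -> dict[str, float]:
        return group_metrics(self.confusion, self.scheme)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Recall per class (the per-category accuracy convention)."""
        return self.recall

    def to_dict(self, percent: bool = True) -> dict:
        """JSON-ready summary; rates as percentages with 2 decimals when
        ``percent`` (the tabular convention), else raw fractions."""
        def fmt(v: float) -> float:
            return round(100.0 * v, 2) if percent else v

        return {
            "overall_accuracy": fmt(self.overall_accuracy),
            "macro_precision": fmt(self.macro_precision),
            "macro_recall": fmt(self.macro_recall),
            "macro_f1": fmt(self.macro_f1),
            "per_class": {
                self.scheme.classes[i + 1]: {
                    "precision": fmt(self.precision[i]),
                    "recall": fmt(self.recall[i]),
                    "f1": fmt(self.f1[i]),
                }
                for i in range(self.scheme.n_classes)
            },
            "grouped_f1": {g: fmt(v) for g, v in self.grouped_f1.items()},
            "confusion": self.confusion.tolist(),
        }


def evaluate_labels(truth: LabelMap, predicted: LabelMap) -> MetricsReport:
    """Convenience wrapper: confusion matrix + full report."""
    cm = confusion_matrix(truth, predicted, n_classes=truth.scheme.n_classes)
    return MetricsReport(cm, truth.scheme)
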