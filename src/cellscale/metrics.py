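"""Confusion matrices and F1 variants for 3-class size prediction.

All model stages report the same quantities: a 3x3 confusion matrix
(rows = truth, columns = prediction, class order S, M, L), per-class
one-vs-rest precision/recall/F1, their macro and class-count-weighted
means, and the model-selection score ``(weighted F1 + macro F1) / 2``.
The headline "F-score" of a model is its weighted F1, which down-weights
no class even under the strong S-heavy imbalance of the cohort.

Zero divisions (a class never predicted, or absent from the truth) are
resolved as 0, matching the convention of treating an undefined
precision/recall as total failure rather than propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class order used everywhere in the package.
CLASSES: tuple[str, str, str] = ("S", "M", "L")

_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


def class_index(label: str) -> int:
    """Map a class label to its canonical index (S=0, M=1, L=2)."""
    try:
        return _CLASS_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")


@dataclass
class PredictionSet:
    """Paired truth/prediction labels for a set of items."""

    item_ids: list[str]
    true_class: list[str]
    predicted_class: list[str]

    def __post_init__(self) -> None:
        if not (len(self.item_ids) == len(self.true_class) == len(self.predicted_class)):
            raise ValueError("item_ids, true_class and predicted_class must have equal length")
        for label in list(self.true_class) + list(self.predicted_class):
            class_index(label)

    def __len__(self) -> int:
        return len(self.item_ids)


@dataclass
class ConfusionMatrix:
    """3x3 count matrix, rows = truth (S, M, L), columns = prediction."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a 3x3 nonnegative integer matrix")

    @classmethod
    def from_predictions(cls, predictions: PredictionSet) -> "ConfusionMatrix":
        counts = np.zeros((3, 3), dtype=int)
        for t, p in zip(predictions.true_class, predictions.predicted_class):
            counts[class_index(t), class_index(p)] += 1
        return cls(counts)

    @property
    def row_normalized(self) -> np.ndarray:
        """Counts normalized per true class; empty rows stay all-zero."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        out = np.zeros((3, 3), dtype=float)
        np.divide(self.counts, row_sums, out=out, where=row_sums > 0)
        return out

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """Per-class and aggregate F1 metrics for one prediction set."""

    confusion: ConfusionMatrix
    precision: dict[str, float] = field(init=False)
    recall: dict[str, float] = field(init=False)
    f1: dict[str, float] = field(init=False)
    macro_f1: float = field(init=False)
    weighted_f1: float = field(init=False)
    validation_score: float = field(init=False)

    def __post_init__(self) -> None:
        counts = self.confusion.counts
        tp = np.diag(counts).astype(float)
        pred_totals = counts.sum(axis=0).astype(float)
        true_totals = counts.sum(axis=1).astype(float)
        precision = _safe_div(tp, pred_totals)
        recall = _safe_div(tp, true_totals)
        f1 = _safe_div(2.0 * precision * recall, precision + recall)
        self.precision = dict(zip(CLASSES, precision.tolist()))
        self.recall = dict(zip(CLASSES, recall.tolist()))
        self.f1 = dict(zip(CLASSES, f1.tolist()))
        self.macro_f1 = float(f1.mean())
        weights = true_totals
        if weights.sum() > 0:
            self.weighted_f1 = float((weights * f1).sum() / weights.sum())
        else:
            self.weighted_f1 = 0.0
        self.validation_score = (self.weighted_f1 + self.macro_f1) / 2.0

    def to_dict(self) -> dict:
        return {
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_row_normalized": self.confusion.row_normalized.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "validation_score": self.validation_score,
        }

    def summary(self) -> str:
        lines = ["class  precision  recall     F1"]
        for c in CLASSES:
            lines.append(
                f"{c:>5}  {self.precision[c]:9.4f}  {self.recall[c]:6.4f}  {self.f1[c]:6.4f}"
            )
        lines.append(f"macro F1     {self.macro_f1:.4f}")
        lines.append(f"weighted F1  {self.weighted_f1:.4f}")
        lines.append(f"validation   {self.validation_score:.4f}")
        return "\n".join(lines)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def evaluate(predictions: PredictionSet) -> EvalReport:
    """Compute the full evaluation report for one prediction set.

    Per-class F1 is one-vs-rest; macro F1 averages the three classes
    equally; weighted F1 weights each class by its true count.
    """
    if len(predictions) == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    return EvalReport(ConfusionMatrix.from_predictions(predictions))


def evaluate_labels(true_class, predicted_class) -> EvalReport:
    """Convenience wrapper for plain label sequences."""
    true_class = list(true_class)
    predicted_class = list(predicted_class)
    ids = [str(i) for i in range(len(true_class))]
    return evaluate(PredictionSet(ids, true_class, predicted_class))
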