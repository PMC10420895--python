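"""Confusion matrices, accuracy formulas, coefficient of variation, labels.

Total accuracy is 100 * (V_A + V_B + V_C) / (N_A + N_B + N_C) where V are
the correctly classified counts per class and N the class sizes; per-class
accuracy is 100 * V_c / N_c.  Freshness classes come from titratable
acidity: fresh A at 13 <= a < 15 degT, sub-fresh B at 15 <= a <= 18 degT,
spoiled C above 18 degT (the spoiled band is written strictly as > 18, so
18 itself falls in B; values below 13 are outside the scheme and raise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import LabelError, Lacto2dError

CLASSES = ("A", "B", "C")


@dataclass
class ConfusionMatrix:
    """True-class x predicted-class counts over an ordered class list."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise Lacto2dError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise Lacto2dError("confusion counts must be nonnegative")

    @property
    def class_sizes(self) -> np.ndarray:
        """N per class (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def correct(self) -> np.ndarray:
        """V per class (diagonal)."""
        return np.diag(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> ConfusionMatrix:
    """Tabulate counts[i][j] = number of samples with true class i predicted j."""
    if len(y_true) != len(y_pred):
        raise Lacto2dError("y_true and y_pred lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise LabelError(f"unknown true label {t!r}; expected one of {tuple(classes)}")
        if p not in index:
            raise LabelError(f"unknown predicted label {p!r}; expected one of {tuple(classes)}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def accuracy_total(cm: ConfusionMatrix) -> float:
    """Overall percent correct: 100 * sum(V) / sum(N)."""
    if cm.total == 0:
        raise Lacto2dError("empty confusion matrix")
    return 100.0 * cm.correct.sum() / cm.total


def accuracy_per_class(cm: ConfusionMatrix) -> dict[str, float]:
    """Percent correct per class, 100 * V_c / N_c; empty classes are omitted."""
    out: dict[str, float] = {}
    for cls, v, n in zip(cm.classes, cm.correct, cm.class_sizes):
        if n > 0:
            out[cls] = 100.0 * v / n
    return out


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise Lacto2dError("coefficient of variation needs >= 2 values")
    mean = x.mean()
    if mean == 0:
        raise Lacto2dError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def label_from_acidity(acidity: float) -> str:
    """Map titratable acidity (degT) to the freshness class A/B/C."""
    if not np.isfinite(acidity) or acidity <= 0:
        raise LabelError(f"acidity must be a positive finite value, got {acidity}")
    if acidity < 13:
        raise LabelError(
            f"acidity {acidity} degT is below the 13 degT floor of the freshness scheme"
        )
    if acidity < 15:
        return "A"
    if acidity <= 18:
        return "B"
    return "C"


@dataclass
class EvaluationReport:
    """Confusion matrix plus the derived accuracies and model metadata."""

    confusion: ConfusionMatrix
    accuracy_total: float
    accuracy_per_class: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # internal consistency: total accuracy is the N-weighted mean of the
        # per-class accuracies
        sizes = self.confusion.class_sizes
        present = sizes > 0
        weighted = float(
            np.sum(
                [self.accuracy_per_class[c] * n
                 for c, n in zip(self.confusion.classes, sizes) if n > 0]
            )
            / sizes[present].sum()
        )
        if abs(weighted - self.accuracy_total) > 1e-9:
            raise Lacto2dError("inconsistent accuracies in report")

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "classes": list(self.confusion.classes),
            "confusion": self.confusion.counts.tolist(),
            "accuracy_total": self.accuracy_total,
            "accuracy_per_class": dict(self.accuracy_per_class),
            "metadata": dict(self.metadata),
        }


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] = CLASSES,
    metadata: dict | None = None,
) -> EvaluationReport:
    """Build a full report from paired true/predicted labels."""
    cm = confusion(y_true, y_pred, classes)
    return EvaluationReport(
        confusion=cm,
        accuracy_total=accuracy_total(cm),
        accuracy_per_class=accuracy_per_class(cm),
        metadata=metadata or {},
    )
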