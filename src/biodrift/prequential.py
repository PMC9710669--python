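"""Progressive (prequential) validation and balanced-accuracy bookkeeping.

Every instance is first scored with the current model, the prediction is
logged against the truth, and only then is the model updated — so the
running accuracy estimates generalization to genuinely unseen samples.
Balanced accuracy (macro-averaged per-class recall) is the headline metric
because tumour-subtype frequencies are heavily imbalanced: a classifier
that always predicts the majority subtype scores its prevalence on raw
accuracy but only 1/K on balanced accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfusionMatrix:
    """Running confusion counts; rows = truth, columns = prediction."""

    def __init__(self, n_classes: int) -> None:
        if n_classes < 2:
            raise ValueError("need at least two classes")
        self.n_classes = n_classes
        self.counts = np.zeros((n_classes, n_classes), dtype=np.int64)

    def update(self, y_true: int, y_pred: int) -> "ConfusionMatrix":
        if not (0 <= y_true < self.n_classes and 0 <= y_pred < self.n_classes):
            raise ValueError(f"label out of range: true={y_true} pred={y_pred}")
        self.counts[y_true, y_pred] += 1
        return self

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def balanced_accuracy(self) -> float:
        """Mean per-class recall over the classes observed so far.

        Classes with no true instances yet are excluded from the mean (the
        macro average would otherwise be undefined early in the stream).
        """
        if self.total == 0:
            raise ValueError("no instances evaluated")
        row_sums = self.counts.sum(axis=1)
        seen = row_sums > 0
        recalls = self.counts.diagonal()[seen] / row_sums[seen]
        return float(recalls.mean())

    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("no instances evaluated")
        return float(self.counts.diagonal().sum() / self.total)


@dataclass
class PrequentialTrace:
    """Cumulative balanced-accuracy trajectory of one test-then-train run."""

    n_classes: int
    confusion: ConfusionMatrix = None
    values: list[float] = field(default_factory=list)
    predictions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.confusion is None:
            self.confusion = ConfusionMatrix(self.n_classes)

    def evaluate_then_update(self, y_true: int, y_pred: int) -> "PrequentialTrace":
        """Record one (truth, prediction) pair and append the new cumulative
        balanced accuracy. The caller must score before training."""
        self.confusion.update(y_true, y_pred)
        self.predictions.append((y_true, y_pred))
        self.values.append(self.confusion.balanced_accuracy())
        return self

    def replay(self) -> list[float]:
        """Recompute the trace from the stored prediction log (audit)."""
        cm = ConfusionMatrix(self.n_classes)
        out = []
        for y_true, y_pred in self.predictions:
            cm.update(y_true, y_pred)
            out.append(cm.balanced_accuracy())
        return out
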