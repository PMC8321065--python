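"""Classification metrics: confusion counts, accuracy, precision, recall, F1.

The positive class is ASD throughout.  Metrics whose denominator is zero
(e.g. precision with no positive predictions) are reported as 0 with a
warning rather than NaN, so automated runs always produce a full report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

from .errors import ValidationError

POSITIVE_CLASS = "ASD"


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion_counts(predicted: list[str], actual: list[str],
                     positive: str = POSITIVE_CLASS) -> ConfusionCounts:
    """Tally a 2-class confusion table against the positive-class convention."""
    if len(predicted) != len(actual):
        raise ValidationError(
            f"length mismatch: {len(predicted)} predictions vs {len(actual)} labels")
    if not predicted:
        raise ValidationError("cannot evaluate an empty prediction set")
    tp = fp = tn = fn = 0
    for p, a in zip(predicted, actual):
        if a == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    if counts.total == 0:
        raise ValidationError("cannot compute metrics over zero subjects")

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} denominator is zero; reporting 0.0",
                          RuntimeWarning, stacklevel=2)
            return 0.0
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    return Metrics(accuracy=accuracy, precision=precision, recall=recall,
                   f1=f1_score(precision, recall))
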