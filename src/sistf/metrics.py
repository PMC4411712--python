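"""Binary confusion counting and the five evaluation measures.

The evaluation is TF-vs-rest: a prediction is *positive* when the query is
called a transcription factor. Unclassifiable queries are counted as negative
predictions by the callers of :func:`confusion`.

Measures: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, precision TP/(TP+FP) and the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

A measure with a zero denominator is reported as undefined (NaN, listed in
``undefined``); MCC with a zero factor under the root is reported as 0.0 with
the ``mcc_zero_denominator`` flag, the common convention for a degenerate
confusion table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import InputError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted: Sequence[bool], truth: Sequence[bool]) -> ConfusionCounts:
    """Tally a 2x2 confusion table from aligned boolean sequences."""
    if len(predicted) != len(truth):
        raise InputError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


@dataclass
class MetricsResult:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    mcc: float
    undefined: tuple[str, ...] = ()
    mcc_zero_denominator: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "mcc": self.mcc,
        }


def compute_metrics(c: ConfusionCounts) -> MetricsResult:
    """Compute the five measures from exact integer counts.

    Raises :class:`InputError` on an all-zero table.
    """
    if c.total == 0:
        raise InputError("cannot compute metrics from an all-zero confusion table")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    acc = (c.tp + c.tn) / c.total
    prec = ratio(c.tp, c.tp + c.fp, "precision")

    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc_flag = denom2 == 0
    if mcc_flag:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)
    return MetricsResult(sens, spec, acc, prec, mcc, tuple(undefined), mcc_flag)
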