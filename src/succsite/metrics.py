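"""Confusion-matrix summary: SN, SP, MCC and the class-ratio-free Q9 index.

MCC is informative but shrinks as the negative class of a test set is
inflated even at fixed sensitivity/specificity.  Q9 summarizes the
normalized false-negative/false-positive error vector and is invariant to
the positive:negative ratio, which makes it the preferred global index for
heavily imbalanced site-prediction benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Sequence, Union

import numpy as np


def _round3(x: float) -> float:
    """Round half away from zero to 3 decimals (table convention)."""
    return math.copysign(math.floor(abs(x) * 1000 + 0.5) / 1000, x)


@dataclass(frozen=True)
class ConfusionSummary:
    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def sn(self) -> float:
        """Sensitivity TP/(TP+FN)."""
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        """Specificity TN/(TN+FP)."""
        return self.tn / (self.tn + self.fp)

    @property
    def mcc(self) -> float:
        """Matthews correlation; 0 when any marginal factor vanishes."""
        num = self.tp * self.tn - self.fn * self.fp
        factors = (
            (self.tp + self.fn),
            (self.tp + self.fp),
            (self.tn + self.fp),
            (self.tn + self.fn),
        )
        if any(f == 0 for f in factors):
            return 0.0
        return num / math.sqrt(math.prod(factors))

    @property
    def q9_raw(self) -> float:
        """The q9 error-vector index (three-branch definition)."""
        p = self.tp + self.fn
        n = self.tn + self.fp
        if p == 0:
            return (self.tn - self.fp) / n
        if n == 0:
            return (self.tp - self.fn) / p
        return 1 - math.sqrt(2) * math.hypot(self.fn / p, self.fp / n)

    @property
    def q9(self) -> float:
        """Global accuracy Q9 = (1 + q9)/2, in [0, 1]."""
        return (1 + self.q9_raw) / 2

    def report_row(self) -> dict[str, float]:
        """Rounded values on the scale the benchmark tables print."""
        return {
            "SN_pct": _round3(self.sn * 100),
            "SP_pct": _round3(self.sp * 100),
            "MCC": _round3(self.mcc),
            "Q9": _round3(self.q9),
        }


def summarize(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionSummary:
    """Tally binary truth/prediction vectors into a confusion summary."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    for v in (labels, predictions):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels and predictions must be binary 0/1")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def write_report(summary: ConfusionSummary, sink: Union[str, IO[str]]) -> None:
    """Tab-separated evaluation report (SN%, SP%, MCC, Q9)."""
    row = summary.report_row()
    text = "\t".join(row) + "\n" + "\t".join(f"{v:.3f}" for v in row.values()) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)
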