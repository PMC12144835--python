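"""Confusion counts and binary-classification metrics (tumor = positive).

The pipeline's headline metric is the Matthews correlation coefficient
(phi coefficient), which uses the full confusion matrix and stays
informative under class imbalance:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Any metric whose denominator is zero is reported as 0 and flagged as
degenerate, which keeps MCC within [-1, 1] and makes empty-model runs
(no combinations selected, everything predicted normal) well defined.

The tumor-ratio threshold rho implicitly controls the classifier's
precision: when the selected combinations' joint-mutation sample sets do
not overlap, precision >= rho, and the specificity is bounded below by
1 - (1-rho) r / ((1-r) rho), with r the tumor fraction of the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "compute_metrics",
    "specificity_lower_bound",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts with tumor as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def tumor_fraction(self) -> float:
        """Tumor share of the data, r = (TP + FN) / n."""
        return (self.tp + self.fn) / self.n if self.n else 0.0


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FN/TN/FP from boolean (or tumor/normal) label arrays."""
    t = np.asarray([v in (1, True, "tumor") for v in np.asarray(y_true).ravel()])
    p = np.asarray([v in (1, True, "tumor") for v in np.asarray(y_pred).ravel()])
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred differ in length")
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
    )


@dataclass(frozen=True)
class MetricReport:
    mcc: float
    sensitivity: float
    specificity: float
    f1: float
    precision: float
    degenerate: frozenset

    def as_dict(self) -> dict:
        return {
            "MCC": self.mcc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "F1": self.f1,
            "precision": self.precision,
            "degenerate": sorted(self.degenerate),
        }


def _ratio(num: float, den: float, name: str, degenerate: set) -> float:
    if den == 0:
        degenerate.add(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """MCC, sensitivity, specificity, F1 and precision from counts.

    Zero-denominator metrics are reported as 0 and named in
    ``report.degenerate``.
    """
    if counts.n < 1:
        raise ValueError("need at least one sample")
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    deg: set = set()
    sens = _ratio(tp, tp + fn, "sensitivity", deg)
    spec = _ratio(tn, tn + fp, "specificity", deg)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1", deg)
    prec = _ratio(tp, tp + fp, "precision", deg)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        deg.add("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return MetricReport(mcc, sens, spec, f1, prec, frozenset(deg))


def specificity_lower_bound(rho: float, r: float) -> float:
    """Lower bound 1 - (1-rho) r / ((1-r) rho) on training specificity.

    Holds when the selected combinations' joint-mutation sample sets are
    pairwise disjoint and every selected combination has tumor ratio at
    least rho; tends to 1 as rho -> 1. ``r`` is the tumor fraction of the
    data.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must be in (0, 1]")
    if not 0.0 <= r < 1.0:
        raise ValueError("r must be in [0, 1)")
    return 1.0 - ((1.0 - rho) * r) / ((1.0 - r) * rho)
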