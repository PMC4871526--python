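"""Pixel-wise evaluation of segmentations against ground truth.

Segmentation is scored as retrieval of object (polyp) pixels: a positive
is an object pixel, giving per-image confusion counts TP/FP/FN/TN and the
derived characteristic values

    AAC       = TP / (TP + FN)          (annotated area covered; = recall)
    DICE      = 2 TP / (2 TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    accuracy  = (TP + TN) / total
    specificity = TN / (TN + FP)
    fallout   = FP / (TN + FP)
    F2        = 5 TP / (5 TP + 4 FN + FP)

Zero-denominator cases are reported as NaN ("undefined") rather than 0 and
excluded from batch means, with the number of exclusions recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "report", "batch_evaluate"]

METRIC_COLUMNS = [
    "aac",
    "dice",
    "precision",
    "recall",
    "accuracy",
    "specificity",
    "fallout",
    "f2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Characteristic values; undefined (0/0) entries are NaN."""

    aac: float
    dice: float
    precision: float
    recall: float
    accuracy: float
    specificity: float
    fallout: float
    f2: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-by-pixel confusion counts (positive = object pixel)."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise InvalidInputError(
            f"prediction shape {p.shape} does not match truth shape {t.shape}"
        )
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def report(counts: ConfusionCounts) -> MetricReport:
    """All characteristic values from one set of confusion counts."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    recall = _ratio(tp, tp + fn)
    return MetricReport(
        aac=recall,
        dice=_ratio(2 * tp, 2 * tp + fp + fn),
        precision=_ratio(tp, tp + fp),
        recall=recall,
        accuracy=_ratio(tp + tn, counts.total),
        specificity=_ratio(tn, tn + fp),
        fallout=_ratio(fp, tn + fp),
        f2=_ratio(5 * tp, 5 * tp + 4 * fn + fp),
    )


def batch_evaluate(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    names: list[str] | None = None,
    pooled: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Evaluate (prediction, truth) pairs; returns a per-image table + means.

    Means are arithmetic over defined (non-NaN) values; the returned table
    also carries the raw counts so a pooled (pixel-level) summary can be
    recomputed.  With ``pooled=True`` the summary row is instead the report
    of the summed confusion counts across all pairs.
    """
    if not pairs:
        raise InvalidInputError("empty evaluation list")
    if names is None:
        names = [str(k) for k in range(len(pairs))]
    records = []
    for name, (pred, truth) in zip(names, pairs):
        try:
            c = confusion(pred, truth)
        except InvalidInputError as exc:
            raise InvalidInputError(f"pair {name!r}: {exc}") from exc
        rec = {"name": name, "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
        rec.update(report(c).as_dict())
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    if pooled:
        total = ConfusionCounts(
            tp=int(table["tp"].sum()),
            fp=int(table["fp"].sum()),
            fn=int(table["fn"].sum()),
            tn=int(table["tn"].sum()),
        )
        summary = pd.Series(report(total).as_dict())
    else:
        summary = table[METRIC_COLUMNS].mean(skipna=True)
    summary["n_undefined"] = int(table[METRIC_COLUMNS].isna().sum().sum())
    return table, summary
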