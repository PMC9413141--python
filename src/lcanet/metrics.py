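"""Confusion-count accumulation and the seven segmentation metrics.

Overlap scores (Dice, pixel accuracy, Jaccard) are reported as percents in
[0, 100]; precision, recall, FPR and FNR as fractions in [0, 1] — the mixed
convention used in segmentation result tables.  A metric whose denominator
is zero (e.g. precision on an all-background prediction) is reported as NaN
and excluded from per-image means rather than raising.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, fields

import numpy as np

METRIC_NAMES = ("dice", "pa", "jaccard", "precision", "recall", "fpr", "fnr")


@dataclass
class ConfusionCounts:
    """Pixelwise TP/FP/FN/TN totals; positive class is the nodule (value 1)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class MetricsReport:
    """The seven metrics; NaN marks an undefined (zero-denominator) entry."""

    dice: float
    pa: float
    jaccard: float
    precision: float
    recall: float
    fpr: float
    fnr: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _validate_mask(m, name):
    a = np.asarray(m)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got ndim={a.ndim}")
    if not np.all((a == 0) | (a == 1)):
        raise ValueError(f"{name} entries must be exactly 0 or 1")
    return a.astype(bool)


def confusion_counts(pred_mask, true_mask) -> ConfusionCounts:
    """Count TP/FP/FN/TN between a predicted and a true binary mask."""
    p = _validate_mask(pred_mask, "pred_mask")
    t = _validate_mask(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs true {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num, den):
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All seven metrics from one set of confusion counts.

    dice    = 100 * 2TP / (2TP + FP + FN)
    pa      = 100 * (TP + TN) / total
    jaccard = 100 * TP / (TP + FP + FN)
    precision = TP / (TP + FP);  recall = TP / (TP + FN)
    fpr = FP / (FP + TN);        fnr = FN / (TP + FN)
    """
    if c.total <= 0:
        raise ValueError("confusion counts must cover at least one pixel")
    return MetricsReport(
        dice=100.0 * _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        pa=100.0 * _ratio(c.tp + c.tn, c.total),
        jaccard=100.0 * _ratio(c.tp, c.tp + c.fp + c.fn),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        fpr=_ratio(c.fp, c.fp + c.tn),
        fnr=_ratio(c.fn, c.tp + c.fn),
    )


def aggregate_metrics(pairs, mode: str = "per-image-mean") -> MetricsReport:
    """Aggregate over (pred_mask, true_mask) pairs.

    ``per-image-mean`` computes a report per pair and averages each metric,
    skipping NaN entries; ``pooled`` sums the confusion counts first and
    computes the metrics once.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one mask pair")
    if mode == "pooled":
        total = None
        for pred, true in pairs:
            c = confusion_counts(pred, true)
            total = c if total is None else total + c
        return compute_metrics(total)
    if mode == "per-image-mean":
        reports = [compute_metrics(confusion_counts(p, t)) for p, t in pairs]
        agg = {}
        for name in METRIC_NAMES:
            vals = [getattr(r, name) for r in reports]
            vals = [v for v in vals if not math.isnan(v)]
            agg[name] = float(np.mean(vals)) if vals else math.nan
        return MetricsReport(**agg)
    raise ValueError(f"unknown aggregation mode {mode!r}")


# ---------------------------------------------------------------------------
# report IO


def write_report_csv(path, rows):
    """Write per-image metric rows: (image_id, MetricsReport) pairs."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("image_id",) + METRIC_NAMES)
        for image_id, report in rows:
            w.writerow([image_id] + [getattr(report, n) for n in METRIC_NAMES])


def write_summary_json(path, summary: MetricsReport, extra: dict = None):
    payload = dict(extra or {})
    payload.update(summary.as_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)
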