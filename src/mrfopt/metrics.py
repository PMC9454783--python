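"""Confusion-matrix construction and the derived metric suite.

All metrics derive from aggregate TP/TN/FP/FN counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    recall      = TP / (TP + FN)            (= sensitivity)
    dice        = 2 TP / (2 TP + FP + FN)
    f1          = 2 P R / (P + R)

Dice and F1 are algebraically identical on hard counts.  For multiclass
problems the counts are aggregated *micro*: the K one-vs-rest 2x2 tables are
summed before any ratio is taken.  Metrics with a zero denominator are
reported as undefined (``None``), never silently as 0.  Percent formatting
rounds half-up to two decimals at presentation time only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_from_predictions",
    "compute_metrics",
    "metric_table",
    "percent",
    "counts_from_csv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("all counts are zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Metric fractions in [0, 1]; ``None`` marks an undefined ratio."""

    accuracy: Optional[float]
    precision: Optional[float]
    specificity: Optional[float]
    recall: Optional[float]
    dice: Optional[float]
    f1: Optional[float]

    @property
    def sensitivity(self) -> Optional[float]:
        return self.recall

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int
) -> ConfusionCounts:
    """Aggregate hard predictions into TP/TN/FP/FN counts.

    Binary problems use the standard 2x2 table with class 1 positive.
    Multiclass problems are micro-aggregated: per-class one-vs-rest counts
    summed over the K classes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    labels = np.arange(n_classes)
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    n = cm.sum()
    if n_classes == 2:
        tn, fp, fn, tp = cm.ravel()
        return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
    diag = np.diag(cm)
    tp = diag.sum()
    fp = (cm.sum(axis=0) - diag).sum()
    fn = (cm.sum(axis=1) - diag).sum()
    tn = n_classes * n - tp - fp - fn  # per-class TN summed over classes
    return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """All six count-based metrics; undefined ratios come back as ``None``."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        specificity=_ratio(c.tn, c.tn + c.fp),
        recall=recall,
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        f1=f1,
    )


def percent(value: Optional[float], digits: int = 2) -> Optional[float]:
    """Fraction -> percentage, rounded half-up (97.715 -> 97.72)."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value * 100)).quantize(q, rounding=ROUND_HALF_UP))


_COLUMNS = ["accuracy", "precision", "specificity", "recall", "dice", "f1"]


def metric_table(counts_by_model: Dict[str, ConfusionCounts]) -> pd.DataFrame:
    """One row per model, metric columns rendered as percentages."""
    if not counts_by_model:
        raise ValueError("empty counts collection")
    rows = {}
    for name, counts in counts_by_model.items():
        rep = compute_metrics(counts)
        rows[name] = {col: percent(getattr(rep, col)) for col in _COLUMNS}
    df = pd.DataFrame.from_dict(rows, orient="index")[_COLUMNS]
    df.index.name = "model"
    return df


def counts_from_csv(path) -> Dict[str, ConfusionCounts]:
    """Read a 4-column counts CSV (model, tp, tn, fp, fn)."""
    df = pd.read_csv(path)
    required = {"model", "tp", "tn", "fp", "fn"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts CSV must have columns {sorted(required)}")
    out = {}
    for i, row in df.iterrows():
        try:
            out[str(row["model"])] = ConfusionCounts(
                tp=int(row["tp"]), tn=int(row["tn"]), fp=int(row["fp"]), fn=int(row["fn"])
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"bad counts row at line {i + 2}: {exc}") from exc
    if not out:
        raise ValueError("counts CSV contains no rows")
    return out


def report_to_json(df: pd.DataFrame) -> str:
    return json.dumps(df.reset_index().to_dict(orient="records"), indent=2)
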