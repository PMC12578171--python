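"""One-vs-rest confusion counts, the five-metric report, and ROC/PR areas.

Per-class metrics follow the one-vs-rest convention throughout: each class
is treated as positive against the union of all others, giving per-class
TP/FP/TN/FN whose sum always equals the evaluation-set size.  From those
counts the report computes

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (recall)
    specificity = TN / (TN + FP)
    F1          = 2 P R / (P + R)

Note that "accuracy" here is the *per-class one-vs-rest* accuracy, not the
overall multiclass accuracy — exactly how the counts in published
per-class tables combine.  Percentages are rounded half-up to two decimals
for display; raw fractions are retained.  A zero denominator yields NaN and
an explicit flag, never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import (multilabel_confusion_matrix,
                             precision_recall_curve, roc_curve)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_pr_summary",
]

_METRIC_COLS = ["ACCU", "PRE", "SENS", "SPEC", "F1"]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/TN/FN (arrays of length K)."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=np.int64) for a in
                (self.tp, self.fp, self.tn, self.fn)]
        self.tp, self.fp, self.tn, self.fn = arrs
        if any(a.min(initial=0) < 0 for a in arrs):
            raise ValueError("confusion counts must be non-negative")
        totals = self.tp + self.fp + self.tn + self.fn
        if len(set(totals.tolist())) > 1:
            raise ValueError(
                "per-class count totals differ; not a one-vs-rest view of "
                "one evaluation set")

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


def confusion(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    """One-vs-rest confusion counts of a multiclass prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, nm in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{nm} labels fall outside [0, {n_classes})")
    mcm = multilabel_confusion_matrix(y_true, y_pred,
                                      labels=np.arange(n_classes))
    return ConfusionCounts(tp=mcm[:, 1, 1], fp=mcm[:, 0, 1],
                           tn=mcm[:, 0, 0], fn=mcm[:, 1, 0])


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def _ratio(num, den):
    """Element-wise num/den with NaN (not 0) where the denominator is 0."""
    num = num.astype(np.float64)
    den = den.astype(np.float64)
    out = np.full_like(num, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


@dataclass
class MetricsReport:
    """Raw fractions, display percentages, and macro averages."""

    raw: dict[str, np.ndarray]          # metric -> per-class fraction in [0,1]
    percent: dict[str, list[float]]     # metric -> 2-decimal percentages
    macro: dict[str, float]             # metric -> macro-average percentage
    undefined: dict[str, np.ndarray]    # metric -> bool mask of NaN cells
    counts: ConfusionCounts

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the published per-class layout."""
        c = self.counts
        df = pd.DataFrame({
            "Class": np.arange(c.n_classes),
            "FP": c.fp, "TP": c.tp, "TN": c.tn, "FN": c.fn,
        })
        for col in _METRIC_COLS:
            df[col] = self.percent[col]
        df["Data Size"] = c.tp + c.fn
        return df


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute the five-metric report from one-vs-rest counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = (tp + fp + tn + fn).astype(np.float64)
    raw = {
        "ACCU": _ratio(tp + tn, total),
        "PRE": _ratio(tp, tp + fp),
        "SENS": _ratio(tp, tp + fn),
        "SPEC": _ratio(tn, tn + fp),
    }
    p, r = raw["PRE"], raw["SENS"]
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where((p + r) > 0, 2 * p * r / (p + r), np.nan)
    f1 = np.where(np.isnan(p) | np.isnan(r), np.nan, f1)
    raw["F1"] = f1
    percent, macro, undefined = {}, {}, {}
    for k, vals in raw.items():
        undefined[k] = np.isnan(vals)
        percent[k] = [np.nan if np.isnan(v) else _round2(100.0 * v)
                      for v in vals]
        defined = vals[~np.isnan(vals)]
        macro[k] = _round2(100.0 * float(defined.mean())) if defined.size \
            else float("nan")
    # displayed F1 is the harmonic mean of the *displayed* (2-decimal)
    # precision and sensitivity — the convention per-class tables in this
    # field follow; the raw F1 above stays exact
    disp_f1 = []
    for pp, rr in zip(percent["PRE"], percent["SENS"]):
        if np.isnan(pp) or np.isnan(rr) or pp + rr == 0:
            disp_f1.append(np.nan)
        else:
            disp_f1.append(_round2(2.0 * pp * rr / (pp + rr)))
    percent["F1"] = disp_f1
    return MetricsReport(raw=raw, percent=percent, macro=macro,
                         undefined=undefined, counts=counts)


def roc_pr_summary(scores: np.ndarray, labels: np.ndarray
                   ) -> tuple[float, float]:
    """Macro-averaged one-vs-rest ROC and PR areas (trapezoidal).

    ``scores`` is (n, K) in [0, 1]; ``labels`` are integer classes.  A class
    absent from ``labels`` (or covering all of them) makes its curve — and
    the summary — undefined, which raises.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim != 2 or len(scores) != len(labels):
        raise ValueError("scores must be (n_samples, n_classes)")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    k = scores.shape[1]
    roc_areas, pr_areas = [], []
    for c in range(k):
        pos = (labels == c).astype(int)
        if pos.min() == pos.max():
            raise ValueError(
                f"class {c} is absent from (or covers all of) the labels; "
                "its ROC/PR curve is undefined")
        fpr, tpr, _ = roc_curve(pos, scores[:, c])
        roc_areas.append(np.trapezoid(tpr, fpr))
        prec, rec, _ = precision_recall_curve(pos, scores[:, c])
        # integrate along the threshold path (recall is monotone along it;
        # re-sorting would scramble ties at equal recall)
        pr_areas.append(abs(np.trapezoid(prec, rec)))
    return float(np.mean(roc_areas)), float(np.mean(pr_areas))
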