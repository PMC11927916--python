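"""Screening evaluation metrics and their per-class / averaged aggregation.

Percentages are kept at full precision internally and rounded half-up to
two decimals only at presentation.  Metrics with a zero denominator are
reported as ``None`` with an explicit flag, never silently as 0.

Definitions (all in percent except AUC):

    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100
    sensitivity = TP / (TP + FN) * 100              (recall, TPR)
    specificity = TN / (TN + FP) * 100
    precision   = TP / (TP + FP) * 100
    F1          = 2 * precision * recall / (precision + recall)
    AUC         = area under the ROC curve (TPR vs FPR, trapezoidal)

For single-label multiclass evaluation each class is binarised
one-vs-rest; the micro-averaged F1 then equals the pooled accuracy
(fraction of exactly-correct predictions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


def round2(value: Optional[float]) -> Optional[float]:
    """Round half-up to 2 decimals (presentation only)."""
    if value is None:
        return None
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    positive_class: str = ""

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(
    predictions: Sequence, truth: Sequence, positive_class
) -> ConfusionCounts:
    """One-vs-rest binarisation then counting."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape or pred.size < 1:
        raise ValueError("predictions and truth must be non-empty and equal length")
    pp = pred == positive_class
    tp_ = true == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pp & tp_)),
        TN=int(np.sum(~pp & ~tp_)),
        FP=int(np.sum(pp & ~tp_)),
        FN=int(np.sum(~pp & tp_)),
        positive_class=str(positive_class),
    )


def _ratio_pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def basic_metrics(c: ConfusionCounts) -> Dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, precision, F1 in percent.

    Returns full-precision values; a metric whose denominator is zero is
    ``None`` and listed under the ``"undefined"`` key.
    """
    acc = _ratio_pct(c.TP + c.TN, c.n)
    sen = _ratio_pct(c.TP, c.TP + c.FN)
    spec = _ratio_pct(c.TN, c.TN + c.FP)
    prec = _ratio_pct(c.TP, c.TP + c.FP)
    f1_den = 2 * c.TP + c.FP + c.FN
    f1 = None if f1_den == 0 else 100.0 * 2 * c.TP / f1_den
    out = {"accuracy": acc, "sensitivity": sen, "specificity": spec,
           "precision": prec, "f1": f1}
    out["undefined"] = tuple(k for k, v in out.items() if v is None)
    return out


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> Optional[float]:
    """Harmonic mean of precision and recall, both in percent."""
    if precision_pct + recall_pct == 0:
        return None
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def averaged_f1(
    per_class_f1: Mapping[str, float],
    supports: Optional[Mapping[str, int]] = None,
    mode: str = "macro",
    pooled_counts: Optional[Mapping[str, float]] = None,
) -> float:
    """Aggregate per-class F1 scores (percent).

    macro: unweighted mean.  weighted: support-weighted mean.  micro: F1
    on pooled TP/FP/FN counts -- pass ``pooled_counts`` with keys
    TP/FP/FN, or (for single-label one-vs-rest, where micro F1 equals
    pooled accuracy) pass per-class recalls as ``pooled_counts=
    {"recalls": {...}}`` together with ``supports``.
    """
    if not per_class_f1 and mode != "micro":
        raise ValueError("per_class_f1 must be non-empty")
    if mode == "macro":
        return float(np.mean(list(per_class_f1.values())))
    if mode == "weighted":
        if supports is None:
            raise ValueError("weighted averaging requires supports")
        keys = list(per_class_f1)
        w = np.array([supports[k] for k in keys], dtype=float)
        f = np.array([per_class_f1[k] for k in keys], dtype=float)
        return float((w * f).sum() / w.sum())
    if mode == "micro":
        if pooled_counts is None:
            raise ValueError("micro averaging requires pooled counts or recalls")
        if "recalls" in pooled_counts:
            if supports is None:
                raise ValueError("micro from recalls requires supports")
            recalls = pooled_counts["recalls"]
            keys = list(recalls)
            w = np.array([supports[k] for k in keys], dtype=float)
            r = np.array([recalls[k] for k in keys], dtype=float)
            return float((w * r).sum() / w.sum())  # pooled accuracy
        tp, fp, fn = (float(pooled_counts[k]) for k in ("TP", "FP", "FN"))
        return 100.0 * 2 * tp / (2 * tp + fp + fn)
    raise ValueError(f"unknown mode {mode!r}")


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Area under the ROC curve by trapezoidal integration over thresholds.

    Tied scores contribute a single ROC vertex, which credits correctly
    half of each tied positive/negative pair.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth).astype(int)
    if s.shape != y.shape or s.size < 1:
        raise ValueError("scores and truth must be non-empty and equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # vertex at each distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], y.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


@dataclass
class MetricsReport:
    """Per-class metrics plus micro/macro/weighted F1 and per-class AUC."""

    per_class: Dict[str, Dict[str, Optional[float]]]
    supports: Dict[str, int]
    micro_f1: float
    macro_f1: float
    weighted_f1: float
    auc: Dict[str, Optional[float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the per-class + averages layout, 2-decimal."""
        rows = []
        for cls, mets in self.per_class.items():
            rows.append({
                "class": cls,
                "support": self.supports.get(cls),
                "accuracy": round2(mets["accuracy"]),
                "sensitivity": round2(mets["sensitivity"]),
                "specificity": round2(mets["specificity"]),
                "precision": round2(mets["precision"]),
                "f1": round2(mets["f1"]),
                "auc": round2(None if self.auc.get(cls) is None else 100 * self.auc[cls]),
            })
        df = pd.DataFrame(rows)
        df.attrs["micro_f1"] = round2(self.micro_f1)
        df.attrs["macro_f1"] = round2(self.macro_f1)
        df.attrs["weighted_f1"] = round2(self.weighted_f1)
        return df

    def to_json(self) -> str:
        payload = {
            "per_class": {
                cls: {k: (round2(v) if isinstance(v, float) else v)
                      for k, v in mets.items() if k != "undefined"}
                for cls, mets in self.per_class.items()
            },
            "supports": self.supports,
            "micro_f1": round2(self.micro_f1),
            "macro_f1": round2(self.macro_f1),
            "weighted_f1": round2(self.weighted_f1),
            "auc": {k: (None if v is None else round(v, 4)) for k, v in self.auc.items()},
        }
        return json.dumps(payload, indent=2)


def metrics_report(
    predictions: Sequence,
    scores: Optional[Mapping[str, Sequence[float]]],
    truth: Sequence,
    classes: Optional[Sequence[str]] = None,
) -> MetricsReport:
    """Assemble the full evaluation report for single-label predictions.

    ``scores`` optionally maps each class to per-sample one-vs-rest
    scores for AUC; classes absent from it get no AUC.
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if classes is None:
        classes = sorted(set(true.tolist()))
    per_class: Dict[str, Dict[str, Optional[float]]] = {}
    supports: Dict[str, int] = {}
    pooled = {"TP": 0, "FP": 0, "FN": 0}
    f1s: Dict[str, float] = {}
    aucs: Dict[str, Optional[float]] = {}
    for cls in classes:
        c = confusion_counts(pred, true, cls)
        m = basic_metrics(c)
        per_class[cls] = m
        supports[cls] = c.TP + c.FN
        pooled["TP"] += c.TP
        pooled["FP"] += c.FP
        pooled["FN"] += c.FN
        if m["f1"] is not None:
            f1s[cls] = m["f1"]
        if scores is not None and cls in scores:
            try:
                aucs[cls] = roc_auc(scores[cls], (true == cls).astype(int))
            except ValueError:
                aucs[cls] = None
    micro = averaged_f1(f1s, supports, "micro", pooled_counts=pooled)
    macro = averaged_f1(f1s, supports, "macro")
    weighted = averaged_f1(f1s, {k: supports[k] for k in f1s}, "weighted")
    return MetricsReport(per_class, supports, micro, macro, weighted, aucs)
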