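"""Confusion-matrix construction and the per-class metric suite.

All metrics derive from one-vs-rest TP/FP/TN/FN counts:

    Pre = TP/(TP+FP)   Sen = TP/(TP+FN)   Spe = TN/(FP+TN)
    F1  = 2*Pre*Sen/(Pre+Sen)             Acc = (TP+TN)/(TP+FN+FP+TN)

reported as percentages.  Per-class "Acc" is the one-vs-rest accuracy;
the overall row aggregates per-class Pre/Sen/Spe/F1 by support weighting
and reports plain multi-class accuracy.  Zero-denominator cases carry an
explicit ``None`` marker rather than NaN arithmetic.  Report rounding is
half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import InvalidParameterError
from .synth import RhythmClass

__all__ = [
    "ConfusionMatrix", "EvalReport", "confusion", "per_class_metrics",
    "f1_from_pre_sen", "roc_pr", "evaluate_predictions", "round2",
]

N_CLASSES = 4


def round2(x: float | None) -> float | None:
    """Half-up rounding to two decimals, as printed in report tables."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # [4, 4]; rows = true class, cols = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise InvalidParameterError(
                f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
        if np.any(self.counts < 0):
            raise InvalidParameterError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self, cls: int) -> dict[str, int]:
        """One-vs-rest TP/FP/TN/FN for one class."""
        tp = int(self.counts[cls, cls])
        fp = int(self.counts[:, cls].sum() - tp)
        fn = int(self.counts[cls, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


@dataclass
class EvalReport:
    cm: ConfusionMatrix
    per_class: dict[RhythmClass, dict]
    overall: dict
    roc_auc: dict[RhythmClass, float | None] = field(default_factory=dict)
    micro_auc: float | None = None
    micro_ap: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cls, m in self.per_class.items():
            rows.append({"class": RhythmClass(cls).short_name,
                         **{k: round2(m[k]) if k in
                            ("Pre", "Sen", "Spe", "F1", "Acc") else m[k]
                            for k in m}})
        rows.append({"class": "Overall",
                     **{k: round2(v) for k, v in self.overall.items()}})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.cm.counts.tolist(),
            "per_class": {RhythmClass(c).short_name: m
                          for c, m in self.per_class.items()},
            "overall": self.overall,
            "roc_auc": {RhythmClass(c).short_name: v
                        for c, v in self.roc_auc.items()},
            "micro_auc": self.micro_auc,
            "micro_ap": self.micro_ap,
        }


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """counts[i, j] = number of windows with true class i predicted j."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise InvalidParameterError("y_true and y_pred lengths differ")
    if t.size and (t.min() < 0 or t.max() >= N_CLASSES
                   or p.min() < 0 or p.max() >= N_CLASSES):
        raise InvalidParameterError(
            f"labels must be integers in [0, {N_CLASSES})")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def f1_from_pre_sen(pre: float | None, sen: float | None) -> float | None:
    """Harmonic mean of precision and sensitivity (percent in, percent out)."""
    if pre is None or sen is None or pre + sen == 0:
        return None
    return 2.0 * pre * sen / (pre + sen)


def per_class_metrics(cm: ConfusionMatrix) -> EvalReport:
    """One-vs-rest Pre/Sen/Spe/F1/Acc per class plus the overall row
    (support-weighted averages; plain multi-class accuracy)."""
    if cm.total == 0:
        raise InvalidParameterError("empty confusion matrix")
    per_class: dict[RhythmClass, dict] = {}
    supports = cm.counts.sum(axis=1)
    for cls in range(N_CLASSES):
        c = cm.ovr_counts(cls)
        pre = _ratio(c["TP"], c["TP"] + c["FP"])
        sen = _ratio(c["TP"], c["TP"] + c["FN"])
        spe = _ratio(c["TN"], c["FP"] + c["TN"])
        acc = _ratio(c["TP"] + c["TN"], cm.total)
        per_class[RhythmClass(cls)] = {
            **c, "Pre": pre, "Sen": sen, "Spe": spe,
            "F1": f1_from_pre_sen(pre, sen), "Acc": acc,
        }

    def weighted(key: str) -> float | None:
        num = den = 0.0
        for cls in range(N_CLASSES):
            v = per_class[RhythmClass(cls)][key]
            if v is not None and supports[cls] > 0:
                num += v * supports[cls]
                den += supports[cls]
        return None if den == 0 else num / den

    overall = {k: weighted(k) for k in ("Pre", "Sen", "Spe", "F1")}
    overall["Acc"] = 100.0 * np.trace(cm.counts) / cm.total
    return EvalReport(cm=cm, per_class=per_class, overall=overall)


def roc_pr(y_true, scores) -> tuple[dict[RhythmClass, float | None],
                                    float | None, float | None]:
    """One-vs-rest ROC AUC per class plus micro-average AUC and
    micro-average precision, pooling all (class, window) decisions.

    A class absent from ``y_true`` gets a ``None`` marker.
    """
    y = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 2 or s.shape[1] != N_CLASSES or len(y) != len(s):
        raise InvalidParameterError(
            f"scores must be [n, {N_CLASSES}] aligned with y_true")
    onehot = np.zeros_like(s)
    onehot[np.arange(len(y)), y] = 1.0
    per_class: dict[RhythmClass, float | None] = {}
    for cls in range(N_CLASSES):
        pos = onehot[:, cls]
        if pos.min() == pos.max():
            per_class[RhythmClass(cls)] = None
        else:
            per_class[RhythmClass(cls)] = float(
                roc_auc_score(pos, s[:, cls]))
    flat_t, flat_s = onehot.ravel(), s.ravel()
    if flat_t.min() == flat_t.max():
        return per_class, None, None
    micro_auc = float(roc_auc_score(flat_t, flat_s))
    micro_ap = float(average_precision_score(flat_t, flat_s))
    return per_class, micro_auc, micro_ap


def evaluate_predictions(y_true, scores) -> EvalReport:
    """Full report from true labels and predicted probability rows."""
    y_pred = np.asarray(scores).argmax(axis=1)
    report = per_class_metrics(confusion(y_true, y_pred))
    report.roc_auc, report.micro_auc, report.micro_ap = roc_pr(y_true, scores)
    return report
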