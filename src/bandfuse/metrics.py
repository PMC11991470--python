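"""Classification metrics from one-vs-rest confusion counts.

Per class: precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2TP/(2TP+FP+FN); overall accuracy = correct/total.  Macro averages
(unweighted class means) summarize multi-class runs.  A metric whose
denominator is zero is reported as 0 with a warning — deterministic and
conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "metrics"]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/TN/FN (each an ``n_classes`` vector)."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        totals = self.tp + self.fp + self.tn + self.fn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-class counts must sum to the same total")

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


def confusion(preds, labels, n_classes: int) -> ConfusionCounts:
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.shape != labels.shape:
        raise ValueError(f"{len(preds)} predictions for {len(labels)} labels")
    joint = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(joint, (labels, preds), 1)
    tp = np.diag(joint).copy()
    fp = joint.sum(axis=0) - tp
    fn = joint.sum(axis=1) - tp
    tn = len(preds) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    out = np.zeros(len(num), dtype=np.float64)
    ok = den > 0
    if not ok.all():
        warnings.warn(f"{name}: zero denominator for class(es) "
                      f"{np.nonzero(~ok)[0].tolist()}; reporting 0")
    out[ok] = num[ok] / den[ok]
    return out


def metrics(cc: ConfusionCounts) -> dict:
    """Per-class and macro precision/recall/F1 plus overall accuracy."""
    precision = _safe_div(cc.tp, cc.tp + cc.fp, "precision")
    recall = _safe_div(cc.tp, cc.tp + cc.fn, "recall")
    f1 = _safe_div(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn, "f1")
    accuracy = float(cc.tp.sum()) / cc.total if cc.total else 0.0
    return {
        "per_class": {
            "precision": precision.tolist(),
            "recall": recall.tolist(),
            "f1": f1.tolist(),
        },
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "accuracy": accuracy,
    }
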