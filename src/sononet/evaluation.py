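"""Detection and localisation metrics.

Detection is scored one-vs-rest per class with precision, recall and F1;
macro averages are *unweighted* over classes (otherwise the huge background
class would dominate) and by default exclude the background class, which is
how the standard views are averaged.  Ratios with zero denominator are
reported as absent (``None``) and omitted from macro averages with a
warning — never silently as zero.  Localisation is scored by IOU against
ground-truth boxes, counting a box as correct at IOU >= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .localisation import BoundingBox, iou

__all__ = [
    "ClassMetrics",
    "detection_metrics",
    "confusion",
    "localisation_accuracy",
    "retrieval_accuracy",
]


@dataclass
class ClassMetrics:
    """One-vs-rest counts and derived scores for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den else None


def detection_metrics(truth, predicted, K: int,
                      background_index: int | None = None,
                      include_background_in_macro: bool = False
                      ) -> tuple[list[ClassMetrics], dict]:
    """Per-class one-vs-rest metrics plus unweighted macro averages.

    ``background_index`` (default: the last class) is excluded from the
    macro averages unless ``include_background_in_macro`` is set; both
    variants of the macro F1 are returned in the summary dict.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction sequences differ in length")
    if background_index is None:
        background_index = K - 1
    per_class: list[ClassMetrics] = []
    for k in range(K):
        tp = int(np.sum((truth == k) & (predicted == k)))
        fp = int(np.sum((truth != k) & (predicted == k)))
        fn = int(np.sum((truth == k) & (predicted != k)))
        tn = int(np.sum((truth != k) & (predicted != k)))
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f1 = None
        if p is not None and r is not None:
            f1 = 2 * p * r / (p + r) if (p + r) else None
        per_class.append(ClassMetrics(tp, fp, fn, tn, p, r, f1))

    def macro(metric: str, with_bg: bool) -> float | None:
        vals = []
        for k, m in enumerate(per_class):
            if k == background_index and not with_bg:
                continue
            v = getattr(m, metric)
            if v is None:
                warnings.warn(
                    f"class {k}: {metric} undefined, omitted from macro")
            else:
                vals.append(v)
        return float(np.mean(vals)) if vals else None

    with_bg = include_background_in_macro
    summary = {
        "macro_precision": macro("precision", with_bg),
        "macro_recall": macro("recall", with_bg),
        "macro_f1": macro("f1", with_bg),
        "macro_f1_with_background": macro("f1", True),
        "macro_f1_foreground_only": macro("f1", False),
    }
    return per_class, summary


def confusion(truth, predicted, K: int) -> np.ndarray:
    """K x K confusion matrix; rows are truth, columns predictions."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction sequences differ in length")
    for name, arr in (("truth", truth), ("prediction", predicted)):
        if arr.size and (arr.min() < 0 or arr.max() >= K):
            raise ValueError(f"{name} labels outside [0, {K})")
    mat = np.zeros((K, K), dtype=int)
    np.add.at(mat, (truth, predicted), 1)
    return mat


def localisation_accuracy(pred_boxes, gt_boxes, labels=None,
                          threshold: float = 0.5) -> dict:
    """Score predicted against ground-truth boxes.

    ``pred_boxes`` entries may be ``None`` for localisation failures, which
    count as incorrect (and as IOU 0 in the mean).  With ``labels`` given,
    per-class means and accuracies are reported as well.
    """
    if len(pred_boxes) != len(gt_boxes):
        raise ValueError("unpaired boxes: prediction/truth lengths differ")
    if labels is not None and len(labels) != len(gt_boxes):
        raise ValueError("unpaired labels")
    ious = np.array([iou(p, g) if p is not None else 0.0
                     for p, g in zip(pred_boxes, gt_boxes)])
    correct = ious >= threshold
    out = {
        "mean_iou": float(ious.mean()) if len(ious) else None,
        "accuracy": float(correct.mean()) if len(ious) else None,
        "n": len(ious),
    }
    if labels is not None:
        labels = np.asarray(labels)
        per_class = {}
        for k in np.unique(labels):
            sel = labels == k
            per_class[int(k)] = {
                "mean_iou": float(ious[sel].mean()),
                "accuracy": float(correct[sel].mean()),
                "n": int(sel.sum()),
            }
        out["per_class"] = per_class
    return out


def retrieval_accuracy(correct_flags) -> float:
    """Proportion of retrievals validated as correct (TP / (P + N))."""
    flags = np.asarray(correct_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("no retrieval flags given")
    return float(flags.mean())
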