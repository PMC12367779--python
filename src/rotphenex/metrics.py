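"""Rotated-detection evaluation and trait-agreement statistics.

Detection quality follows the VOC protocol with a rotated-IoU matching
criterion (default threshold 0.5): predictions are matched greedily in
descending confidence, each ground truth at most once; precision, recall and
F1 come from the TP/FP/FN counts, AP is the area under the monotone envelope
of the precision-recall curve, and mAP averages AP over classes.

Trait agreement between extracted and measured values is summarized by the
coefficient of determination R^2 of the least-squares line of extracted vs
measured, the statistic used to report per-trait accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError
from .rotgeom import RotatedBox, rotated_iou

__all__ = [
    "EvalResult",
    "match_detections",
    "precision_recall_f1",
    "f1_score",
    "average_precision",
    "mean_ap",
    "r_squared",
    "evaluate_detections",
]


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap: float
    map: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "ap": self.ap, "map": self.map,
        }


def match_detections(
    preds: Sequence[tuple],
    gts: Sequence[RotatedBox],
    iou_threshold: float = 0.5,
) -> tuple[np.ndarray, int]:
    """Greedy one-to-one matching of scored predictions to ground truths.

    ``preds`` is a sequence of ``(RotatedBox, score)``.  Returns
    ``(tp_flags, fn_count)`` where ``tp_flags[i]`` tells whether the i-th
    prediction *in descending score order* matched an unused ground truth at
    rotated IoU >= threshold.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    used = np.zeros(len(gts), dtype=bool)
    tp_flags = np.zeros(len(preds), dtype=bool)
    for rank, i in enumerate(order):
        box = preds[i][0]
        best_j, best_iou = -1, iou_threshold
        for j, gt in enumerate(gts):
            if used[j]:
                continue
            iou = rotated_iou(box, gt)
            if iou >= best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            used[best_j] = True
            tp_flags[rank] = True
    return tp_flags, int((~used).sum())


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean from raw counts."""
    if min(tp, fp, fn) < 0:
        raise UndefinedMetricError("counts must be non-negative")
    if tp + fp == 0:
        warnings.warn("no predictions; precision reported as 0", stacklevel=2)
    if tp + fn == 0:
        warnings.warn("no ground truth; recall reported as 0", stacklevel=2)
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision < 0 or recall < 0:
        raise UndefinedMetricError("precision/recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def average_precision(
    confidences: Sequence[float], tp_flags: Sequence[bool], n_gt: int
) -> float:
    """All-points interpolated AP: area under the monotone precision envelope."""
    if n_gt <= 0:
        raise UndefinedMetricError("AP undefined without ground truth")
    conf = np.asarray(confidences, dtype=float)
    flags = np.asarray(tp_flags, dtype=bool)
    if conf.size == 0 or not flags.any():
        return 0.0
    order = np.argsort(-conf, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone (right-to-left running max) envelope, integrated over recall
    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([0.0], precision, [0.0]))
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def mean_ap(per_class_ap: Mapping[str, float]) -> float:
    """Arithmetic mean of per-class AP values."""
    if not per_class_ap:
        raise UndefinedMetricError("no classes")
    return float(np.mean(list(per_class_ap.values())))


def r_squared(estimates: Sequence[float], truths: Sequence[float]) -> float:
    """R^2 of the least-squares line of estimates against truths."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise UndefinedMetricError("estimates and truths must have equal length")
    if est.size < 2:
        raise UndefinedMetricError("need at least two points")
    if np.allclose(tru, tru[0]):
        raise UndefinedMetricError("truths are constant; R^2 undefined")
    if np.allclose(est, est[0]):
        return 0.0
    res = stats.linregress(tru, est)
    return float(res.rvalue ** 2)


def evaluate_detections(
    preds_by_image: Mapping[str, Sequence[tuple]],
    gts_by_image: Mapping[str, Sequence[RotatedBox]],
    iou_threshold: float = 0.5,
) -> EvalResult:
    """Aggregate VOC-style evaluation over a set of images (single class)."""
    all_conf: list[float] = []
    all_flags: list[bool] = []
    n_gt = 0
    fn_total = 0
    for key in gts_by_image:
        gts = list(gts_by_image[key])
        preds = list(preds_by_image.get(key, []))
        n_gt += len(gts)
        flags, fn = match_detections(preds, gts, iou_threshold)
        order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
        all_conf.extend(preds[i][1] for i in order)
        all_flags.extend(flags.tolist())
        fn_total += fn
    tp = int(np.sum(all_flags))
    fp = len(all_flags) - tp
    p, r, f1 = precision_recall_f1(tp, fp, fn_total)
    ap = average_precision(all_conf, all_flags, n_gt) if n_gt > 0 else 0.0
    return EvalResult(tp, fp, fn_total, p, r, f1, ap, mean_ap({"leaf": ap}))
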