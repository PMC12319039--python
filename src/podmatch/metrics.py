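"""Detection and counting evaluation metrics.

Detection side: pixel-set IoU, TP/FP/FN assignment at IoU >= 0.5,
precision / recall / F1, average precision as the rectangular sum
``AP = sum_k Precision(k) * dRecall(k)`` over the confidence-ranked list
(no interpolation by default), and mAP as the plain mean over classes.

Counting side: MAE, RMSE, and the coefficient-of-determination form
``R = 1 - sum (t_i - c_i)^2 / sum (t_i - tbar)^2`` (which can be negative);
the per-category count accuracy ``Acc = 1 - |truth - predict| / truth`` and
its mean over the four pod classes plus the total (five categories).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detections import BoundingBox, PodSet, VALID_CLASSES

COUNT_CATEGORIES = ("one", "two", "three", "four", "total")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def assign_tp_fp(dets: PodSet | list, truths: PodSet | list,
                 iou_min: float = 0.5) -> list[bool]:
    """Label each detection TP/FP against one class's ground truth.

    Detections are visited in confidence-descending order (ties by index);
    each claims the unclaimed truth of highest IoU and is a TP iff that IoU
    reaches ``iou_min``.  Each truth is claimed at most once, so duplicate
    detections of one pod are FPs.  Returned labels follow the original
    detection order; FN count = n_truth - TP count.  Caller stratifies by
    class first.
    """
    det_list = list(dets)
    truth_boxes = [t.box for t in truths]
    order = sorted(range(len(det_list)), key=lambda i: (-det_list[i].confidence, i))
    claimed = [False] * len(truth_boxes)
    labels = [False] * len(det_list)
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, tb in enumerate(truth_boxes):
            if claimed[j]:
                continue
            v = iou(det_list[i].box, tb)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_min:
            labels[i] = True
            claimed[best_j] = True
    return labels


def pr_ap(labels: list[bool], n_truth: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision/recall curve and AP from a confidence-ranked TP/FP list.

    AP is the raw rectangular sum over rank positions k of
    ``Precision(k) * (Recall(k) - Recall(k-1))``; 0 when there is no truth.
    """
    if n_truth < 0:
        raise ValueError("n_truth must be nonnegative")
    lab = np.asarray(labels, dtype=bool)
    if lab.size == 0 or n_truth == 0:
        return np.zeros(0), np.zeros(0), 0.0
    tp = np.cumsum(lab)
    k = np.arange(1, lab.size + 1)
    precision = tp / k
    recall = tp / n_truth
    drecall = np.diff(np.concatenate([[0.0], recall]))
    return precision, recall, float(np.sum(precision * drecall))


def interpolated_ap(labels: list[bool], n_truth: int) -> float:
    """VOC-style all-point interpolated AP (precision envelope); optional alternative."""
    precision, recall, _ = pr_ap(labels, n_truth)
    if precision.size == 0:
        return 0.0
    env = np.maximum.accumulate(precision[::-1])[::-1]
    drecall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(env * drecall))


def mean_ap(aps: dict[int, float] | list[float]) -> float:
    vals = list(aps.values()) if isinstance(aps, dict) else list(aps)
    if not vals:
        raise ValueError("mean_ap needs at least one class AP")
    return float(np.mean(vals))


@dataclass
class DetectionEvalReport:
    per_class: dict[int, dict] = field(default_factory=dict)
    map: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in sorted(self.per_class):
            m = self.per_class[cls]
            rows.append({"class": cls, **{k: m[k] for k in
                        ("tp", "fp", "fn", "precision", "recall", "f1", "ap")}})
        df = pd.DataFrame(rows)
        df["map"] = self.map
        return df


def evaluate_detections(dets: PodSet, truths: PodSet,
                        iou_min: float = 0.5) -> DetectionEvalReport:
    """Class-stratified detection evaluation on one image (or a pooled set)."""
    report = DetectionEvalReport()
    aps = {}
    for cls in sorted(VALID_CLASSES):
        d_cls = [d for d in dets if d.pod_class == cls]
        t_cls = [t for t in truths if t.pod_class == cls]
        order = sorted(range(len(d_cls)), key=lambda i: (-d_cls[i].confidence, i))
        labels_orig = assign_tp_fp(d_cls, t_cls, iou_min=iou_min)
        ranked = [labels_orig[i] for i in order]
        tp = sum(ranked)
        fp = len(ranked) - tp
        fn = len(t_cls) - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
        _, _, ap = pr_ap(ranked, len(t_cls))
        report.per_class[cls] = {"tp": tp, "fp": fp, "fn": fn, "precision": precision,
                                 "recall": recall, "f1": f1, "ap": ap}
        aps[cls] = ap
    report.map = mean_ap(aps)
    return report


def count_metrics(t, c) -> tuple[float, float, float]:
    """(MAE, RMSE, R) between truth and predicted counts.

    R is the coefficient-of-determination form, undefined for constant truth.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.shape != c.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("t and c must be equal-length 1-D vectors")
    mae = float(np.mean(np.abs(t - c)))
    rmse = float(np.sqrt(np.mean((t - c) ** 2)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R undefined: truth vector is constant")
    r = 1.0 - float(np.sum((t - c) ** 2)) / ss_tot
    return mae, rmse, r


def pearson_r(t, c) -> float:
    """Ordinary Pearson correlation, as an alternative to the R of count_metrics."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    return float(np.corrcoef(t, c)[0, 1])


def acc(truth: float, predict: float) -> float:
    """Count accuracy ``1 - |truth - predict| / truth``; unclamped, so it goes
    negative once the prediction exceeds twice the truth."""
    if truth <= 0:
        raise ValueError("acc undefined for truth <= 0")
    return 1.0 - abs(truth - predict) / truth


def acc_mean(accs) -> float:
    """Mean of exactly five category accuracies (four pod classes + total)."""
    vals = list(accs)
    if len(vals) != 5:
        raise ValueError(f"acc_mean takes exactly 5 category accuracies, got {len(vals)}")
    return float(np.mean(vals))


@dataclass
class CountEvalReport:
    per_category: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": cat, **self.per_category[cat]} for cat in COUNT_CATEGORIES
                if cat in self.per_category]
        return pd.DataFrame(rows)


def evaluate_counts(truth_table: pd.DataFrame, pred_table: pd.DataFrame) -> CountEvalReport:
    """Count metrics per category over a table of plants.

    Both tables need columns ``plant_id, one, two, three, four, total`` and
    are aligned on plant_id.  R is NaN for a constant truth column.
    """
    merged = truth_table.merge(pred_table, on="plant_id", suffixes=("_t", "_c"))
    if len(merged) != len(truth_table) or len(merged) != len(pred_table):
        raise ValueError("plant_id mismatch between truth and prediction tables")
    report = CountEvalReport()
    for cat in COUNT_CATEGORIES:
        t = merged[f"{cat}_t"].to_numpy(dtype=float)
        c = merged[f"{cat}_c"].to_numpy(dtype=float)
        try:
            mae, rmse, r = count_metrics(t, c)
        except ValueError:
            mae = float(np.mean(np.abs(t - c)))
            rmse = float(np.sqrt(np.mean((t - c) ** 2)))
            r = float("nan")
        report.per_category[cat] = {"r": r, "mae": mae, "rmse": rmse}
    return report
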