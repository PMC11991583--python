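"""Detection metrics (precision, recall, mAP50, mAP50-95, confusion matrix)
and counting metrics (RMSE, MAE, MSE, R^2).

AP uses all-point interpolation (area under the monotone precision envelope).
mAP50-95 supports two threshold protocols: the conventional ten thresholds
0.50:0.05:0.95 (``standard10``, the default) and a fine 91-threshold grid
0.500:0.005:0.950 (``paper91``).  Reported P and R are taken at IoU 0.5 and
the confidence that maximizes F1.  The counting R^2 is the squared Pearson
correlation between true and predicted counts (insensitive to constant bias),
not the regression coefficient of determination.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .blocks import CLASS_NAMES
from .loss_assign import iou_matrix

__all__ = [
    "match_detections", "average_precision", "map_suite",
    "confusion_matrix", "counting_metrics",
]


def match_detections(det_boxes, det_scores, gt_boxes, iou_threshold: float = 0.5):
    """Greedy one-image single-class matching in descending confidence.

    Returns (tp_flags aligned with confidence-sorted detections, sorted scores,
    number of unmatched ground truths)."""
    det_boxes = np.asarray(det_boxes, dtype=float).reshape(-1, 4)
    det_scores = np.asarray(det_scores, dtype=float)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    order = np.argsort(-det_scores, kind="stable")
    tp = np.zeros(len(order), dtype=bool)
    used = np.zeros(len(gt_boxes), dtype=bool)
    if len(gt_boxes) and len(order):
        ious = iou_matrix(det_boxes[order], gt_boxes)
        for i in range(len(order)):
            cand = np.where(~used & (ious[i] >= iou_threshold))[0]
            if len(cand):
                j = cand[np.argmax(ious[i, cand])]
                used[j] = True
                tp[i] = True
    return tp, det_scores[order], int((~used).sum())


def average_precision(tp_sorted: np.ndarray, n_gt: int) -> float:
    """Area under the monotone-envelope PR curve, all-point interpolation.

    ``tp_sorted`` must be ordered by descending confidence across the dataset."""
    if n_gt == 0:
        return float("nan")
    tp_sorted = np.asarray(tp_sorted, dtype=bool)
    if len(tp_sorted) == 0:
        return 0.0
    tps = np.cumsum(tp_sorted)
    fps = np.cumsum(~tp_sorted)
    recall = tps / n_gt
    precision = tps / (tps + fps)
    # envelope
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def _per_class_curves(dets, gts, iou_threshold: float, num_classes: int):
    """dets/gts: lists per image of (boxes, scores, classes) / (boxes, classes).
    Returns per class (scores, tp flags, n_gt)."""
    out = []
    for k in range(num_classes):
        scores_all, tp_all, n_gt = [], [], 0
        for (db, ds, dc), (gb, gc) in zip(dets, gts):
            db = np.asarray(db, dtype=float).reshape(-1, 4)
            ds, dc = np.asarray(ds, dtype=float), np.asarray(dc, dtype=int)
            gb = np.asarray(gb, dtype=float).reshape(-1, 4)
            gc = np.asarray(gc, dtype=int)
            dm, gm = dc == k, gc == k
            n_gt += int(gm.sum())
            tp, sc, _ = match_detections(db[dm], ds[dm], gb[gm], iou_threshold)
            scores_all.append(sc)
            tp_all.append(tp)
        scores = np.concatenate(scores_all) if scores_all else np.zeros(0)
        tp = np.concatenate(tp_all) if tp_all else np.zeros(0, dtype=bool)
        order = np.argsort(-scores, kind="stable")
        out.append((scores[order], tp[order], n_gt))
    return out


def _pr_at_best_f1(curves):
    """Operating-point P and R: the confidence maximizing overall F1 at IoU .5."""
    scores = np.concatenate([c[0] for c in curves])
    tps = np.concatenate([c[1] for c in curves])
    n_gt = sum(c[2] for c in curves)
    if len(scores) == 0 or n_gt == 0:
        return 0.0, 0.0
    order = np.argsort(-scores, kind="stable")
    tp_c = np.cumsum(tps[order])
    fp_c = np.cumsum(~tps[order])
    prec = tp_c / (tp_c + fp_c)
    rec = tp_c / n_gt
    f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
    i = int(np.argmax(f1))
    return float(prec[i]), float(rec[i])


def map_suite(dets, gts, mode: str = "standard10", num_classes: int = len(CLASS_NAMES)):
    """Full detection metric suite.

    dets: per image (boxes (D,4), scores (D,), classes (D,));
    gts: per image (boxes (G,4), classes (G,)).
    Returns dict with precision, recall, map50, map50_95, per_class_ap50.
    Classes with zero ground truth are excluded from the means."""
    if mode == "standard10":
        thresholds = np.arange(0.50, 0.96, 0.05)
    elif mode == "paper91":
        thresholds = 0.5 + 0.005 * np.arange(91)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ap_by_thr = []
    for t in thresholds:
        curves = _per_class_curves(dets, gts, float(t), num_classes)
        ap_by_thr.append([average_precision(tp, n) for _, tp, n in curves])
    ap = np.array(ap_by_thr)  # (T, K)
    valid = ~np.isnan(ap[0])
    ap50 = ap[0]
    map50 = float(np.nanmean(ap50)) if valid.any() else 0.0
    map5095 = float(np.nanmean(ap[:, valid].mean(axis=0))) if valid.any() else 0.0
    curves50 = _per_class_curves(dets, gts, 0.5, num_classes)
    p, r = _pr_at_best_f1(curves50)
    return {
        "precision": p, "recall": r, "map50": map50, "map50_95": map5095,
        "per_class_ap50": {CLASS_NAMES[k] if k < len(CLASS_NAMES) else str(k):
                           (None if np.isnan(ap50[k]) else float(ap50[k]))
                           for k in range(num_classes)},
        "mode": mode,
    }


def confusion_matrix(dets, gts, num_classes: int = len(CLASS_NAMES),
                     iou_threshold: float = 0.5, conf_threshold: float = 0.25):
    """Row-normalized (K+1)x(K+1) matrix; last index is background.

    Rows are predictions, columns ground truth: an unmatched GT adds to
    (background, its class); an unmatched detection to (its class, background)."""
    m = np.zeros((num_classes + 1, num_classes + 1))
    for (db, ds, dc), (gb, gc) in zip(dets, gts):
        db = np.asarray(db, dtype=float).reshape(-1, 4)
        ds, dc = np.asarray(ds, dtype=float), np.asarray(dc, dtype=int)
        gb = np.asarray(gb, dtype=float).reshape(-1, 4)
        gc = np.asarray(gc, dtype=int)
        keep = ds >= conf_threshold
        db, ds, dc = db[keep], ds[keep], dc[keep]
        used_gt = np.zeros(len(gb), dtype=bool)
        order = np.argsort(-ds, kind="stable")
        if len(gb) and len(order):
            ious = iou_matrix(db[order], gb)
            for i in range(len(order)):
                cand = np.where(~used_gt & (ious[i] >= iou_threshold))[0]
                if len(cand):
                    j = cand[np.argmax(ious[i, cand])]
                    used_gt[j] = True
                    m[dc[order[i]], gc[j]] += 1
                else:
                    m[dc[order[i]], num_classes] += 1
        else:
            for c in dc:
                m[c, num_classes] += 1
        for j in np.where(~used_gt)[0]:
            m[num_classes, gc[j]] += 1
    rows = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        mn = np.where(rows > 0, m / rows, 0.0)
    return mn


@dataclass
class CountingMetrics:
    rmse: float
    mae: float
    mse: float
    r2: float


def counting_metrics(true_counts, pred_counts) -> CountingMetrics:
    """RMSE / MAE / MSE and squared-Pearson R^2 of per-image spike counts."""
    t = np.asarray(true_counts, dtype=float)
    p = np.asarray(pred_counts, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted counts must be 1-D and aligned")
    d = t - p
    mse = float(np.mean(d * d))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(d)))
    st, sp = t.std(), p.std()
    if st == 0 or sp == 0 or len(t) < 2:
        warnings.warn("zero variance in counts; R^2 reported as 0")
        r2 = 0.0
    else:
        r = float(np.corrcoef(t, p)[0, 1])
        r2 = r * r
    return CountingMetrics(rmse, mae, mse, r2)
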