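"""Box geometry (IoU / CIoU), the composite detection loss, and task-aligned
training-time target assignment.

The localization loss is 1 - CIoU, where CIoU = IoU - rho^2/c^2 - alpha*v:
rho^2 is the squared distance between box centers, c^2 the squared diagonal of
the smallest enclosing box, v = (4/pi^2)(arctan(w_gt/h_gt) - arctan(w/h))^2 the
aspect-ratio penalty and alpha = v / ((1 - IoU) + v) its balance weight
(treated as a constant during backpropagation, as is conventional).
Classification uses binary cross-entropy on all cells; box regression adds a
distribution-focal term on the two integer bins bracketing each target
distance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import engine as E
from .engine import Tensor
from .network import HeadConfig, dfl_expectation, make_anchors

__all__ = [
    "iou", "ciou", "ciou_terms", "CIOUTerms", "ciou_tensor", "ciou_loss",
    "TaskAlignedAssigner", "assign_targets", "detection_loss",
]

_EPS = 1e-9


# ---------------------------------------------------------------------------
# geometry (numpy; broadcasting over leading dims)
# ---------------------------------------------------------------------------

def iou(a, b) -> np.ndarray | float:
    """Intersection over union of axis-aligned boxes (x1, y1, x2, y2)."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    ix = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
    iy = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = ix * iy
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    out = inter / np.maximum(area_a + area_b - inter, _EPS)
    return float(out) if out.ndim == 0 else out


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU: a (M,4) x b (N,4) -> (M,N)."""
    return iou(np.asarray(a)[:, None, :], np.asarray(b)[None, :, :])


@dataclass
class CIOUTerms:
    iou: float
    rho2: float
    c2: float
    v: float
    alpha: float


def ciou_terms(a, b) -> CIOUTerms:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    i = iou(a, b)
    wa, ha = max(a[2] - a[0], _EPS), max(a[3] - a[1], _EPS)
    wb, hb = max(b[2] - b[0], _EPS), max(b[3] - b[1], _EPS)
    rho2 = (((a[0] + a[2]) - (b[0] + b[2])) ** 2 + ((a[1] + a[3]) - (b[1] + b[3])) ** 2) / 4.0
    cw = max(a[2], b[2]) - min(a[0], b[0])
    ch = max(a[3], b[3]) - min(a[1], b[1])
    c2 = cw * cw + ch * ch
    v = (4.0 / math.pi ** 2) * (math.atan(wb / hb) - math.atan(wa / ha)) ** 2
    alpha = v / ((1.0 - i) + v) if v > 0 else 0.0
    return CIOUTerms(float(i), float(rho2), float(c2), float(v), float(alpha))


def ciou(a, b) -> float:
    """Complete IoU of two boxes; the corresponding loss is 1 - ciou."""
    t = ciou_terms(a, b)
    return t.iou - t.rho2 / max(t.c2, _EPS) - t.alpha * t.v


def ciou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise CIoU: a (M,4) x b (N,4) -> (M,N), vectorized."""
    a = np.asarray(a, dtype=np.float64)[:, None, :]
    b = np.asarray(b, dtype=np.float64)[None, :, :]
    i = iou(a, b)
    wa = np.maximum(a[..., 2] - a[..., 0], _EPS)
    ha = np.maximum(a[..., 3] - a[..., 1], _EPS)
    wb = np.maximum(b[..., 2] - b[..., 0], _EPS)
    hb = np.maximum(b[..., 3] - b[..., 1], _EPS)
    rho2 = (((a[..., 0] + a[..., 2]) - (b[..., 0] + b[..., 2])) ** 2
            + ((a[..., 1] + a[..., 3]) - (b[..., 1] + b[..., 3])) ** 2) / 4.0
    cw = np.maximum(a[..., 2], b[..., 2]) - np.minimum(a[..., 0], b[..., 0])
    ch = np.maximum(a[..., 3], b[..., 3]) - np.minimum(a[..., 1], b[..., 1])
    c2 = np.maximum(cw * cw + ch * ch, _EPS)
    v = (4.0 / math.pi ** 2) * (np.arctan(wb / hb) - np.arctan(wa / ha)) ** 2
    alpha = v / ((1.0 - i) + v + _EPS)
    return i - rho2 / c2 - alpha * v


def ciou_tensor(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Differentiable elementwise CIoU between pred (M,4) Tensor rows and gt (M,4)."""
    gt = np.asarray(gt, dtype=np.float32)
    x1, y1 = _col(pred, 0), _col(pred, 1)
    x2, y2 = _col(pred, 2), _col(pred, 3)
    gx1, gy1, gx2, gy2 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    w = E.clip_min(x2 - x1, _EPS)
    h = E.clip_min(y2 - y1, _EPS)
    gw, gh = np.maximum(gx2 - gx1, _EPS), np.maximum(gy2 - gy1, _EPS)
    ix = E.clip_min(E.minimum(x2, Tensor(gx2)) - E.maximum(x1, Tensor(gx1)), 0.0)
    iy = E.clip_min(E.minimum(y2, Tensor(gy2)) - E.maximum(y1, Tensor(gy1)), 0.0)
    inter = ix * iy
    union = w * h + Tensor(gw * gh) - inter
    i = inter / E.clip_min(union, _EPS)
    rho2 = (((x1 + x2) - Tensor(gx1 + gx2)) ** 2 + ((y1 + y2) - Tensor(gy1 + gy2)) ** 2) * 0.25
    cw = E.maximum(x2, Tensor(gx2)) - E.minimum(x1, Tensor(gx1))
    ch = E.maximum(y2, Tensor(gy2)) - E.minimum(y1, Tensor(gy1))
    c2 = E.clip_min(cw * cw + ch * ch, _EPS)
    v = (E.arctan(Tensor(gw / gh)) - E.arctan(w / h)) ** 2 * (4.0 / math.pi ** 2)
    alpha = (v.data / ((1.0 - i.data) + v.data + _EPS))  # constant wrt gradient
    return i - rho2 / c2 - Tensor(alpha) * v


def _col(t: Tensor, j: int) -> Tensor:
    m = np.zeros((t.shape[1],), dtype=np.float32)
    m[j] = 1.0
    return (t * Tensor(m)).sum(axis=1)


def ciou_loss(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Mean 1 - CIoU over matched pred/gt box rows."""
    return (1.0 - ciou_tensor(pred, gt)).mean()


# ---------------------------------------------------------------------------
# task-aligned assignment
# ---------------------------------------------------------------------------

class TaskAlignedAssigner:
    """Assign at most one ground-truth box to each cell.

    Alignment metric = score^alpha * max(CIoU, 0)^beta over cells whose anchor
    center lies inside the GT box; the top-k cells per GT become positives;
    conflicts resolve to the highest metric.
    """

    def __init__(self, topk: int = 10, alpha: float = 0.5, beta: float = 6.0):
        self.topk, self.alpha, self.beta = topk, alpha, beta

    def __call__(self, scores: np.ndarray, boxes: np.ndarray, anchors: np.ndarray,
                 gt_boxes: np.ndarray, gt_labels: np.ndarray):
        """scores (A, nc) post-sigmoid; boxes (A,4); anchors (A,2); gt (G,4)/(G,).

        Returns (fg_mask (A,), gt_index (A,), target_scores (A, nc))."""
        a = len(anchors)
        fg = np.zeros(a, dtype=bool)
        gidx = np.full(a, -1, dtype=int)
        tscores = np.zeros_like(scores)
        g = len(gt_boxes)
        if g == 0:
            return fg, gidx, tscores
        inside = ((anchors[:, 0:1] > gt_boxes[None, :, 0]) &
                  (anchors[:, 0:1] < gt_boxes[None, :, 2]) &
                  (anchors[:, 1:2] > gt_boxes[None, :, 1]) &
                  (anchors[:, 1:2] < gt_boxes[None, :, 3]))  # (A, G)
        overlap = np.clip(ciou_matrix(boxes, gt_boxes), 0.0, None)  # (A, G)
        cls_score = scores[:, gt_labels]  # (A, G)
        metric = (cls_score ** self.alpha) * (overlap ** self.beta)
        metric = np.where(inside, metric, 0.0)

        best_metric = np.zeros(a)
        for j in range(g):
            mj = metric[:, j]
            cand = np.argsort(-mj, kind="stable")[: self.topk]
            cand = cand[mj[cand] > 0]
            for c in cand:
                if mj[c] > best_metric[c]:
                    best_metric[c] = mj[c]
                    gidx[c] = j
                    fg[c] = True
        # normalized target scores per GT (aligned-metric convention)
        for j in range(g):
            cells = np.where(fg & (gidx == j))[0]
            if len(cells) == 0:
                continue
            mmax = metric[cells, j].max()
            omax = overlap[cells, j].max()
            t = metric[cells, j] / max(mmax, _EPS) * omax
            tscores[cells, gt_labels[j]] = t
        return fg, gidx, tscores


def assign_targets(gt_boxes, gt_labels, anchors_per_level, scores, boxes,
                   topk: int = 10, alpha: float = 0.5, beta: float = 6.0):
    """Pool anchor points across levels and run task-aligned assignment."""
    anchors = np.concatenate(anchors_per_level, axis=0)
    return TaskAlignedAssigner(topk, alpha, beta)(
        np.asarray(scores), np.asarray(boxes), anchors,
        np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4),
        np.asarray(gt_labels, dtype=int))


# ---------------------------------------------------------------------------
# composite loss
# ---------------------------------------------------------------------------

def _flatten_levels(raw, cfg: HeadConfig, image_index: int):
    """Per-level (reg, cls) -> flat graph tensors (A, 4*reg_max), (A, nc) plus
    anchors (A,2) and per-cell strides (A,)."""
    regs, clss, strides = [], [], []
    level_hw = []
    for (reg, cls), s in zip(raw, cfg.strides):
        n, cr, h, w = reg.shape
        level_hw.append((h, w))
        r = E.reshape(E.transpose(reg, (0, 2, 3, 1)), (n, h * w, cr))
        c = E.reshape(E.transpose(cls, (0, 2, 3, 1)), (n, h * w, cfg.num_classes))
        regs.append(E.take(r, np.array([image_index])))
        clss.append(E.take(c, np.array([image_index])))
        strides.append(np.full(h * w, s, dtype=np.float32))
    reg_flat = E.reshape(E.concat(regs, axis=1), (-1, 4 * cfg.reg_max))
    cls_flat = E.reshape(E.concat(clss, axis=1), (-1, cfg.num_classes))
    anchors = make_anchors(level_hw, cfg.strides)
    return reg_flat, cls_flat, anchors, np.concatenate(strides)


def _decode_boxes_np(reg_flat: np.ndarray, anchors: np.ndarray,
                     strides: np.ndarray, reg_max: int) -> np.ndarray:
    a = reg_flat.shape[0]
    dist = dfl_expectation(reg_flat.T.reshape(1, -1, a, 1), reg_max)
    dist = dist[0, :, :, 0].T * strides[:, None]
    return np.stack([anchors[:, 0] - dist[:, 0], anchors[:, 1] - dist[:, 1],
                     anchors[:, 0] + dist[:, 2], anchors[:, 1] + dist[:, 3]], axis=1)


def detection_loss(raw, targets, cfg: HeadConfig | None = None,
                   weights: tuple[float, float, float] = (7.5, 0.5, 1.5),
                   assigner: TaskAlignedAssigner | None = None):
    """Composite detection loss over a batch.

    raw: per-level (reg, cls) graph tensors from the model forward.
    targets: list (one per image) of (boxes (G,4) in pixels, labels (G,)).
    Returns (total: Tensor, components: dict of floats).
    """
    cfg = cfg or HeadConfig()
    assigner = assigner or TaskAlignedAssigner()
    lam_box, lam_cls, lam_dfl = weights
    box_terms, dfl_terms, cls_terms = [], [], []
    n_pos_total = 0
    for b, (gt_boxes, gt_labels) in enumerate(targets):
        reg_flat, cls_flat, anchors_lv, strides = _flatten_levels(raw, cfg, b)
        anchors = np.concatenate(anchors_lv, axis=0)
        gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
        gt_labels = np.asarray(gt_labels, dtype=int)
        with np.errstate(over="ignore"):
            scores_np = 1.0 / (1.0 + np.exp(-cls_flat.data))
        boxes_np = _decode_boxes_np(reg_flat.data, anchors, strides, cfg.reg_max)
        fg, gidx, tscores = assigner(scores_np, boxes_np, anchors, gt_boxes, gt_labels)
        pos = np.where(fg)[0]
        n_pos_total += len(pos)
        # normalization follows the base detector: losses are summed and
        # divided by the total assigned target score, clamped below at 1 to
        # keep early steps (tiny overlaps) stable; an image without positives
        # falls back to the plain mean (-log 0.5 per cell per class at zero
        # logits)
        tau = max(float(tscores.sum()), 1.0)
        if len(pos) > 0:
            cls_terms.append(E.bce_with_logits(cls_flat, tscores).sum() * (1.0 / tau))
        else:
            cls_terms.append(E.bce_with_logits(cls_flat, tscores).mean())
        if len(pos) == 0:
            continue
        w_pos = tscores[pos, gt_labels[gidx[pos]]].astype(np.float32)
        # differentiable decode of positive cells only
        reg_pos = E.take(reg_flat, pos)                      # (M, 4*reg_max)
        m = len(pos)
        p = E.softmax(E.reshape(reg_pos, (m, 4, cfg.reg_max)), axis=2)
        bins = np.arange(cfg.reg_max, dtype=np.float32).reshape(1, 1, -1)
        dist = (p * Tensor(bins)).sum(axis=2) * Tensor(strides[pos, None])  # (M,4)
        ax, ay = anchors[pos, 0], anchors[pos, 1]
        sign = Tensor(np.array([-1, -1, 1, 1], dtype=np.float32))
        anc = Tensor(np.stack([ax, ay, ax, ay], axis=1).astype(np.float32))
        pred_boxes = anc + dist * sign
        tgt = gt_boxes[gidx[pos]]
        one_minus_ciou = 1.0 - ciou_tensor(pred_boxes, tgt.astype(np.float32))
        box_terms.append((one_minus_ciou * Tensor(w_pos)).sum() * (1.0 / tau))
        # DFL on the two bins bracketing the normalized target distances
        td = np.stack([(ax - tgt[:, 0]), (ay - tgt[:, 1]),
                       (tgt[:, 2] - ax), (tgt[:, 3] - ay)], axis=1) / strides[pos, None]
        td = np.clip(td, 0.0, cfg.reg_max - 1 - 1e-3)
        lo = np.floor(td).astype(int)
        wl, wu = (lo + 1 - td), (td - lo)
        wmat = np.zeros((m, 4, cfg.reg_max), dtype=np.float32)
        rows = np.arange(m)[:, None]
        cols = np.arange(4)[None, :]
        wmat[rows, cols, lo] = wl
        wmat[rows, cols, np.minimum(lo + 1, cfg.reg_max - 1)] += wu
        wmat *= w_pos[:, None, None] / 4.0
        logp = E.log(E.clip_min(p, 1e-9))
        dfl_terms.append(-(Tensor(wmat) * logp).sum() * (1.0 / tau))

    cls_loss = _mean_terms(cls_terms)
    box_loss = _mean_terms(box_terms) if box_terms else Tensor(0.0)
    dfl_loss = _mean_terms(dfl_terms) if dfl_terms else Tensor(0.0)
    total = lam_box * box_loss + lam_cls * cls_loss + lam_dfl * dfl_loss
    comps = {"box": float(box_loss.data), "cls": float(cls_loss.data),
             "dfl": float(dfl_loss.data), "total": float(total.data),
             "n_pos": n_pos_total}
    return total, comps


def _mean_terms(terms):
    acc = terms[0]
    for t in terms[1:]:
        acc = acc + t
    return acc * (1.0 / len(terms))
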