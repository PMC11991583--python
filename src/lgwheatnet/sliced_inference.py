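"""Sliced hyper-inference for large images: tile into overlapping windows,
detect per window, remap to source coordinates, merge with class-wise NMS,
and aggregate per-region counts.

Defaults follow the field protocol for drone mosaics: 256x256 windows with a
0.1 overlap ratio along both axes, so the step is floor(256 * 0.9) = 230 px;
the last window on each axis is clamped to the image border.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .network import Detection, nms

__all__ = ["SliceGrid", "compute_slices", "slice_predict", "count_regions"]


@dataclass
class SliceGrid:
    windows: list[tuple[int, int, int, int]]  # (x0, y0, w, h) source pixels
    slice_size: int
    overlap_ratio: float


def _axis_starts(dim: int, s: int, step: int) -> list[int]:
    if dim <= s:
        return [0]
    out: list[int] = []
    st = 0
    while True:
        if st + s > dim:  # would overrun: single clamped final window
            st = max(0, dim - s)
            if st not in out:
                out.append(st)
            break
        out.append(st)
        if st + s == dim:
            break
        st += step
    return out


def compute_slices(width: int, height: int, slice_size: int = 256,
                   overlap_ratio: float = 0.1) -> SliceGrid:
    """Overlapping window grid covering every source pixel.

    Starts advance by floor(S*(1-r)); a start that would overrun the border is
    replaced by the single clamped start max(0, dim - S)."""
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be positive")
    step = int(np.floor(slice_size * (1.0 - overlap_ratio)))
    step = max(step, 1)
    xs = _axis_starts(width, slice_size, step)
    ys = _axis_starts(height, slice_size, step)
    windows = [(x, y, min(slice_size, width - x), min(slice_size, height - y))
               for y in ys for x in xs]
    return SliceGrid(windows, slice_size, overlap_ratio)


def slice_predict(image: np.ndarray, detector, grid: SliceGrid | None = None,
                  merge_iou: float = 0.5, conf: float = 0.25,
                  border_margin: float = 1e-3) -> list[Detection]:
    """Detect on each window, shift into source coordinates, merge duplicates.

    ``detector`` is either a model exposing ``predict(window, conf, iou)`` or a
    plain callable ``window -> list[Detection]`` in window coordinates.
    Windows smaller than the slice size (clamped at borders of small images)
    are zero-padded before detection.  A detection touching an interior window
    border (within ``border_margin`` px) is a truncated view of an object the
    overlapping neighbour window sees whole, so it is discarded before
    merging; borders that coincide with the image edge are kept."""
    h, w = image.shape[:2]
    if grid is None:
        grid = compute_slices(w, h)
    s = grid.slice_size
    fn: Callable = detector.predict if hasattr(detector, "predict") else detector
    pooled: list[Detection] = []
    for (x0, y0, ww, wh) in grid.windows:
        win = image[y0:y0 + wh, x0:x0 + ww]
        if ww < s or wh < s:
            pad = np.zeros((s, s) + image.shape[2:], dtype=image.dtype)
            pad[:wh, :ww] = win
            win = pad
        dets = (fn(win, conf) if hasattr(detector, "predict")
                else fn(win))
        for d in dets:
            x1, y1, x2, y2 = d.box
            if ((x1 <= border_margin and x0 > 0)
                    or (y1 <= border_margin and y0 > 0)
                    or (x2 >= ww - border_margin and x0 + ww < w)
                    or (y2 >= wh - border_margin and y0 + wh < h)):
                continue
            pooled.append(Detection(d.class_id, d.score,
                                    (x1 + x0, y1 + y0, x2 + x0, y2 + y0)))
    if not pooled:
        return []
    out: list[Detection] = []
    classes = sorted({d.class_id for d in pooled})
    for k in classes:
        dk = [d for d in pooled if d.class_id == k]
        boxes = np.array([d.box for d in dk])
        scores = np.array([d.score for d in dk])
        for i in nms(boxes, scores, merge_iou):
            x1, y1, x2, y2 = boxes[i]
            x1, x2 = float(np.clip(x1, 0, w)), float(np.clip(x2, 0, w))
            y1, y2 = float(np.clip(y1, 0, h)), float(np.clip(y2, 0, h))
            if x2 > x1 and y2 > y1:
                out.append(Detection(k, float(scores[i]), (x1, y1, x2, y2)))
    out.sort(key=lambda d: -d.score)
    return out


def count_regions(detections: Sequence[Detection],
                  regions: Sequence[tuple[float, float, float, float]] | None = None,
                  image_hw: tuple[int, int] | None = None) -> dict:
    """Count detections per rectangular region by box-center membership.

    Membership is half-open: left/top edges inclusive, right/bottom exclusive,
    so a center sitting exactly on a shared internal boundary belongs to the
    region on its right/bottom side only.  Overlapping regions are allowed and
    a detection may then count in several.  With no regions, the whole image
    is one region."""
    if regions is None:
        if image_hw is None:
            raise ValueError("need image_hw when no regions are given")
        h, w = image_hw
        regions = [(0.0, 0.0, float(w), float(h))]
    for (x1, y1, x2, y2) in regions:
        if x2 <= x1 or y2 <= y1:
            raise ValueError("degenerate region")
    counts = {i: 0 for i in range(len(regions))}
    for d in detections:
        cx = (d.box[0] + d.box[2]) / 2.0
        cy = (d.box[1] + d.box[3]) / 2.0
        for i, (x1, y1, x2, y2) in enumerate(regions):
            if x1 <= cx < x2 and y1 <= cy < y2:
                counts[i] += 1
    return {"per_region": counts, "total": len(detections)}
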