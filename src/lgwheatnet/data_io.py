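"""Dataset handling: PASCAL VOC XML read/write, 8:1:1 splitting, the offline
augmentation suite (noise, brightness, occlusion, rotation, crop, translation,
mirror), and a synthetic wheat-canopy scene generator.

Coordinate conventions
----------------------
Internally boxes are 0-based half-open ``[x1, x2) x [y1, y2)`` floats, which
makes area arithmetic unambiguous.  On disk the VOC dialect is 1-based
inclusive integers, so reading maps ``xmin -> xmin - 1`` (and symmetrically on
write).

The synthetic generator emulates the salient structure of field imagery —
cluttered green canopy background, several elongated textured spikes per image
in three growth-stage classes (green-yellow flowering, yellow grain-filling,
gold ripe) with awn strokes — with exact mask-derived bounding boxes.  It is a
stand-in for real field photographs: it reproduces geometry, clutter and class
appearance separation, not real occlusion statistics or lighting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from lxml import etree
from skimage.transform import rotate as _sk_rotate

from .blocks import CLASS_NAMES

__all__ = [
    "AnnotatedImage", "AugmentationSpec", "SyntheticSceneConfig",
    "read_voc", "write_voc", "split_dataset", "augment",
    "generate_synthetic_dataset", "CLASS_NAMES",
]


@dataclass
class AnnotatedImage:
    image: np.ndarray                      # H x W x 3 uint8 RGB
    boxes: np.ndarray                      # (N, 4) float, 0-based half-open
    labels: list[str]                      # class names
    name: str = "scene"

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        h, w = self.image.shape[:2]
        if len(self.boxes) and (
                (self.boxes[:, 0] < 0).any() or (self.boxes[:, 1] < 0).any()
                or (self.boxes[:, 2] > w).any() or (self.boxes[:, 3] > h).any()):
            raise ValueError("box outside image bounds")
        for lb in self.labels:
            if lb not in CLASS_NAMES:
                raise ValueError(f"unknown class {lb!r}")

    @property
    def class_ids(self) -> np.ndarray:
        return np.array([CLASS_NAMES.index(l) for l in self.labels], dtype=int)


# ---------------------------------------------------------------------------
# VOC XML
# ---------------------------------------------------------------------------

def read_voc(xml_path, image_path=None) -> AnnotatedImage:
    """Parse a VOC annotation (and its image, if given) into AnnotatedImage."""
    tree = etree.parse(str(xml_path))
    root = tree.getroot()
    if image_path is not None:
        image = np.asarray(Image.open(image_path).convert("RGB"))
        h, w = image.shape[:2]
    else:
        size = root.find("size")
        w = int(size.findtext("width"))
        h = int(size.findtext("height"))
        image = np.zeros((h, w, 3), dtype=np.uint8)
    boxes, labels = [], []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name not in CLASS_NAMES:
            raise ValueError(f"unknown class {name!r} in {xml_path}")
        bb = obj.find("bndbox")
        x1 = float(bb.findtext("xmin")) - 1.0
        y1 = float(bb.findtext("ymin")) - 1.0
        x2 = float(bb.findtext("xmax"))
        y2 = float(bb.findtext("ymax"))
        cx1, cy1 = max(x1, 0.0), max(y1, 0.0)
        cx2, cy2 = min(x2, float(w)), min(y2, float(h))
        if (cx1, cy1, cx2, cy2) != (x1, y1, x2, y2):
            warnings.warn(f"box {(x1, y1, x2, y2)} outside {w}x{h} image; clipped")
        boxes.append((cx1, cy1, cx2, cy2))
        labels.append(name)
    return AnnotatedImage(image, np.array(boxes).reshape(-1, 4), labels,
                          name=Path(xml_path).stem)


def write_voc(ann: AnnotatedImage, xml_path, image_path=None) -> None:
    """Write VOC XML (1-based inclusive) and optionally the image file."""
    h, w = ann.image.shape[:2]
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = (
        Path(image_path).name if image_path else ann.name + ".png")
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(w)
    etree.SubElement(size, "height").text = str(h)
    etree.SubElement(size, "depth").text = "3"
    for (x1, y1, x2, y2), lb in zip(ann.boxes, ann.labels):
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = lb
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(round(x1)) + 1)
        etree.SubElement(bb, "ymin").text = str(int(round(y1)) + 1)
        etree.SubElement(bb, "xmax").text = str(int(round(x2)))
        etree.SubElement(bb, "ymax").text = str(int(round(y2)))
    etree.ElementTree(root).write(str(xml_path), pretty_print=True)
    if image_path is not None:
        Image.fromarray(ann.image).save(image_path)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(items: list, ratios=(8, 1, 1), seed: int = 0):
    """Disjoint, exhaustive random split with largest-remainder sizes."""
    if len(items) < len(ratios):
        raise ValueError("need at least one item per part")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    total = float(sum(ratios))
    quotas = [len(items) * r / total for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    rem = len(items) - sum(sizes)
    frac_order = np.argsort([-(q - np.floor(q)) for q in quotas], kind="stable")
    for i in range(rem):
        sizes[frac_order[i]] += 1
    out, pos = [], 0
    for s in sizes:
        out.append([items[i] for i in order[pos:pos + s]])
        pos += s
    return tuple(out)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationSpec:
    gaussian_sigma: float = 0.0            # additive noise std (8-bit units)
    salt_pepper_fraction: float = 0.0
    brightness_range: tuple[float, float] = (1.0, 1.0)
    occlusion_count: int = 0
    occlusion_size: tuple[int, int] = (10, 40)
    rotation_degrees: float = 0.0          # sampled uniformly in +-degrees
    crop_fraction: float = 0.0             # max fraction removed per side
    translation_fraction: float = 0.0
    mirror_probability: float = 0.0
    min_box_survival: float = 0.25         # drop boxes keeping < this area share
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.brightness_range
        if lo > hi:
            raise ValueError("brightness range must be ordered")
        if not 0 <= self.mirror_probability <= 1:
            raise ValueError("mirror probability must be in [0,1]")


def _clip_boxes(boxes, areas0, w, h, min_survival):
    if len(boxes) == 0:
        return boxes, np.zeros(0, dtype=bool)
    b = boxes.copy()
    b[:, 0::2] = np.clip(b[:, 0::2], 0, w)
    b[:, 1::2] = np.clip(b[:, 1::2], 0, h)
    area = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    keep = area >= min_survival * np.maximum(areas0, 1e-9)
    return b, keep


def augment(ann: AnnotatedImage, spec: AugmentationSpec) -> AnnotatedImage:
    """Apply the configured geometric + photometric transforms; box coordinates
    follow (rotation takes the axis-aligned hull; crops/shifts clip; boxes with
    less than ``min_box_survival`` of their area left are dropped); occlusion
    patches leave ground truth untouched (simulated leaf cover)."""
    rng = np.random.default_rng(spec.seed)
    img = ann.image.astype(np.float64)
    boxes = ann.boxes.copy()
    labels = list(ann.labels)
    h, w = img.shape[:2]
    areas0 = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]) if len(boxes) else np.zeros(0)

    # rotation about the image center, frame size preserved
    if spec.rotation_degrees:
        ang = rng.uniform(-spec.rotation_degrees, spec.rotation_degrees)
        img = _sk_rotate(img, ang, resize=False, preserve_range=True, mode="edge")
        if len(boxes):
            t = np.deg2rad(ang)
            # image rotates by +ang (CCW display); points rotate accordingly
            c, s = np.cos(t), np.sin(t)
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            corners = np.stack([boxes[:, [0, 2, 0, 2]].ravel(),
                                boxes[:, [1, 1, 3, 3]].ravel()], axis=1)
            x = corners[:, 0] - cx
            y = corners[:, 1] - cy
            xr = c * x + s * y + cx
            yr = -s * x + c * y + cy
            xr = xr.reshape(-1, 4)
            yr = yr.reshape(-1, 4)
            boxes = np.stack([xr.min(1), yr.min(1), xr.max(1), yr.max(1)], axis=1)

    # crop (then resize back is NOT applied; frame shrinks)
    if spec.crop_fraction:
        l = int(rng.uniform(0, spec.crop_fraction) * w)
        r = int(rng.uniform(0, spec.crop_fraction) * w)
        t = int(rng.uniform(0, spec.crop_fraction) * h)
        b = int(rng.uniform(0, spec.crop_fraction) * h)
        img = img[t:h - b, l:w - r]
        h, w = img.shape[:2]
        if len(boxes):
            boxes[:, 0::2] -= l
            boxes[:, 1::2] -= t

    # translation with edge fill
    if spec.translation_fraction:
        dx = int(rng.uniform(-spec.translation_fraction, spec.translation_fraction) * w)
        dy = int(rng.uniform(-spec.translation_fraction, spec.translation_fraction) * h)
        out = np.zeros_like(img)
        sx1, sx2 = max(0, -dx), min(w, w - dx)
        sy1, sy2 = max(0, -dy), min(h, h - dy)
        out[sy1 + dy:sy2 + dy, sx1 + dx:sx2 + dx] = img[sy1:sy2, sx1:sx2]
        img = out
        if len(boxes):
            boxes[:, 0::2] += dx
            boxes[:, 1::2] += dy

    # horizontal mirror
    if spec.mirror_probability and rng.random() < spec.mirror_probability:
        img = img[:, ::-1]
        if len(boxes):
            boxes = np.stack([w - boxes[:, 2], boxes[:, 1],
                              w - boxes[:, 0], boxes[:, 3]], axis=1)

    # photometric
    lo, hi = spec.brightness_range
    if (lo, hi) != (1.0, 1.0):
        img = img * rng.uniform(lo, hi)
    if spec.gaussian_sigma:
        img = img + rng.normal(0, spec.gaussian_sigma, img.shape)
    if spec.salt_pepper_fraction:
        m = rng.random(img.shape[:2])
        img[m < spec.salt_pepper_fraction / 2] = 0
        img[m > 1 - spec.salt_pepper_fraction / 2] = 255

    # occlusion patches (ground truth unchanged)
    for _ in range(spec.occlusion_count):
        sz = rng.integers(spec.occlusion_size[0], spec.occlusion_size[1] + 1)
        x0 = int(rng.integers(0, max(1, w - sz)))
        y0 = int(rng.integers(0, max(1, h - sz)))
        img[y0:y0 + sz, x0:x0 + sz] = rng.uniform(30, 90, 3)

    boxes, keep = _clip_boxes(boxes, areas0, w, h, spec.min_box_survival)
    boxes = boxes[keep]
    labels = [lb for lb, k in zip(labels, keep) if k]
    img = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedImage(img, boxes, labels, name=ann.name + "_aug")


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSceneConfig:
    image_size: int = 256
    spikes_per_image: tuple[int, int] = (3, 8)   # inclusive range
    spike_length_frac: tuple[float, float] = (0.14, 0.22)  # of image size
    spike_aspect: tuple[float, float] = (2.8, 4.2)         # length / width
    clutter: float = 0.5                          # background texture strength
    awn_count: int = 12
    classes: tuple[str, ...] = CLASS_NAMES
    seed: int = 0

    def __post_init__(self):
        if self.spikes_per_image[0] < 0:
            raise ValueError("spike count must be >= 0")


# per-class base colors (RGB): flowering green-yellow, filling yellow, ripe gold
_STAGE_COLOR = {
    "flowerwheat": (150, 175, 80),
    "fillingwheat": (200, 185, 85),
    "ripewheat": (210, 165, 55),
}


def _background(size: int, clutter: float, rng) -> np.ndarray:
    """Cluttered green canopy: multi-scale value noise tinted green."""
    img = np.zeros((size, size, 3))
    base = np.array([60.0, 95.0, 45.0])
    img += base
    for cell in (8, 16, 32):
        g = rng.normal(0, 1, (size // cell + 2, size // cell + 2))
        gi = np.kron(g, np.ones((cell, cell)))[:size, :size]
        img += clutter * 22.0 * gi[..., None] * np.array([0.5, 1.0, 0.4])
    img += rng.normal(0, 6 * clutter, (size, size, 3))
    # leaf-like streaks
    for _ in range(int(10 * clutter) + 2):
        x0, y0 = rng.integers(0, size, 2)
        ang = rng.uniform(0, np.pi)
        ln = rng.integers(size // 6, size // 2)
        ts = np.arange(ln)
        xs = np.clip(x0 + ts * np.cos(ang), 0, size - 1).astype(int)
        ys = np.clip(y0 + ts * np.sin(ang), 0, size - 1).astype(int)
        img[ys, xs] = img[ys, xs] * 0.6 + np.array([40, 120, 50]) * 0.4
    return img


def _render_spike(length: float, width: float, angle: float, color, awn_count,
                  rng) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one spike into a local patch; returns (patch RGB, alpha mask)."""
    a, b = length / 2.0, width / 2.0
    pad = int(np.ceil(a * 1.45)) + 2
    s = 2 * pad + 1
    yy, xx = np.mgrid[0:s, 0:s]
    x = xx - pad
    y = yy - pad
    c, sn = np.cos(angle), np.sin(angle)
    u = c * x + sn * y       # along spike axis
    v = -sn * x + c * y      # across
    ell = (u / a) ** 2 + (v / b) ** 2
    mask = ell <= 1.0
    patch = np.zeros((s, s, 3))
    col = np.array(color, dtype=float) * rng.uniform(0.85, 1.15)
    # spikelet texture: periodic brightness along the axis, shading across
    tex = 1.0 + 0.22 * np.cos(u * (2 * np.pi / max(width * 0.9, 3.0)))
    shade = 1.0 - 0.35 * (np.abs(v) / max(b, 1e-6)) ** 2
    patch[mask] = np.clip(col * (tex * shade)[mask, None], 0, 255)
    alpha = mask.astype(float)
    # awns: thin bright strokes fanning out from the spike tip
    tip = np.array([pad + a * c, pad + a * sn])
    for _ in range(awn_count):
        da = angle + rng.uniform(-0.5, 0.5)
        ln = rng.uniform(0.15, 0.4) * length
        ts = np.linspace(0, ln, int(ln * 2) + 2)
        xs = np.clip(tip[0] + ts * np.cos(da), 0, s - 1).astype(int)
        ys = np.clip(tip[1] + ts * np.sin(da), 0, s - 1).astype(int)
        patch[ys, xs] = np.clip(col * 1.1, 0, 255)
        alpha[ys, xs] = 1.0
    return patch, alpha


def generate_synthetic_scene(cfg: SyntheticSceneConfig, seed: int,
                             name: str = "scene") -> AnnotatedImage:
    """One deterministic synthetic canopy image with exact box ground truth."""
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    img = _background(size, cfg.clutter, rng)
    k = int(rng.integers(cfg.spikes_per_image[0], cfg.spikes_per_image[1] + 1))
    stage = cfg.classes[rng.integers(0, len(cfg.classes))]
    boxes, labels = [], []
    for _ in range(k):
        length = rng.uniform(*cfg.spike_length_frac) * size
        width = length / rng.uniform(*cfg.spike_aspect)
        angle = rng.uniform(0, np.pi)
        patch, alpha = _render_spike(length, width, angle,
                                     _STAGE_COLOR[stage], cfg.awn_count, rng)
        s = patch.shape[0]
        # place fully inside the frame; overlap with other spikes is allowed
        x0 = int(rng.integers(0, max(1, size - s)))
        y0 = int(rng.integers(0, max(1, size - s)))
        region = img[y0:y0 + s, x0:x0 + s]
        am = alpha[..., None]
        img[y0:y0 + s, x0:x0 + s] = region * (1 - am) + patch * am
        ys, xs = np.nonzero(alpha)
        boxes.append((x0 + xs.min(), y0 + ys.min(),
                      x0 + xs.max() + 1, y0 + ys.max() + 1))
        labels.append(stage)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedImage(img, np.array(boxes).reshape(-1, 4), labels, name=name)


def generate_synthetic_dataset(cfg: SyntheticSceneConfig, n_images: int,
                               out_dir=None) -> list[AnnotatedImage]:
    """n deterministic scenes (seed = cfg.seed + index); optionally write
    PNG + VOC XML pairs plus a manifest listing into ``out_dir``."""
    scenes = [generate_synthetic_scene(cfg, cfg.seed + i, name=f"scene_{i:04d}")
              for i in range(n_images)]
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.txt", "w") as mf:
            for sc in scenes:
                ip = out / "images" / f"{sc.name}.png"
                xp = out / "annotations" / f"{sc.name}.xml"
                write_voc(sc, xp, ip)
                mf.write(f"{ip.name}\t{xp.name}\n")
        with open(out / "classes.txt", "w") as cf:
            cf.write("\n".join(CLASS_NAMES) + "\n")
    return scenes
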