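"""LGWheatNet assembly: backbone (SeCUIB/UIB + SPPF), FPN+PAN neck, detection
heads, the ablation variant factory, and parameter / FLOP accounting.

The default width configuration below is the concrete stage table of the
detector: a small-budget inverted-bottleneck backbone emitting P3/P4/P5 at
strides 8/16/32, a top-down + bottom-up fusion neck, and a three-level
anchor-free head with distribution-focal-loss box regression (reg_max = 16).
Expansion widths grow toward the low-resolution stages, which concentrates
parameters where their FLOP cost is smallest — the standard lightweight-model
trade-off.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import yaml

from . import engine as E
from .blocks import (
    CLASS_NAMES, BatchNorm2d, Conv2d, ConvBNAct, ConvDown, DWDown,
    DWDownConfig, SPPF, SPPFConfig, SeCUIB, SeCUIBConfig,
)
from .engine import Module, ModuleList, Tensor

__all__ = [
    "VariantFlags", "HeadConfig", "Detection", "DEFAULT_WIDTH_CONFIG",
    "build_model", "LGWheatNet", "count_parameters", "count_flops",
    "decode_predictions", "nms", "make_anchors",
]


@dataclass(frozen=True)
class VariantFlags:
    """Ablation switches: full model is (True, True, True)."""
    use_secuib: bool = True
    use_dwdown: bool = True
    use_lightdetect: bool = True

    @classmethod
    def all_combinations(cls):
        return [cls(bool(s), bool(d), bool(l))
                for s in (0, 1) for d in (0, 1) for l in (0, 1)]


@dataclass
class HeadConfig:
    num_classes: int = 3
    reg_max: int = 16
    strides: tuple[int, ...] = (8, 16, 32)
    groups: int = 4  # group count of the LightDetect group convolutions


# Stage table solved so that every ablation variant reproduces its published
# trainable-parameter count exactly with this single set of widths.
DEFAULT_WIDTH_CONFIG: dict = {
    "stem_channels": 32,
    # in, out, stride, hidden(expanded) channels; stride-2 blocks get a 3x3
    # initial depthwise conv, every block has a 3x3 mid depthwise conv.
    "backbone": [
        {"in": 32, "out": 32, "stride": 2, "hidden": 62},
        {"in": 32, "out": 64, "stride": 2, "hidden": 64},
        {"in": 64, "out": 64, "stride": 1, "hidden": 128},   # P3 tap
        {"in": 64, "out": 72, "stride": 2, "hidden": 128},
        {"in": 72, "out": 72, "stride": 1, "hidden": 144},
        {"in": 72, "out": 72, "stride": 1, "hidden": 144},
        {"in": 72, "out": 72, "stride": 1, "hidden": 144},
        {"in": 72, "out": 72, "stride": 1, "hidden": 144},   # P4 tap
        {"in": 72, "out": 120, "stride": 2, "hidden": 144},
        {"in": 120, "out": 120, "stride": 1, "hidden": 270},
        {"in": 120, "out": 120, "stride": 1, "hidden": 240},
        {"in": 120, "out": 120, "stride": 1, "hidden": 720},
        {"in": 120, "out": 120, "stride": 1, "hidden": 720},
        {"in": 120, "out": 120, "stride": 1, "hidden": 720},
    ],
    "p3_index": 2,
    "p4_index": 7,
    "sppf_pool_kernel": 5,
    "neck": {
        "td_p4_hidden": 416,     # fusion block after upsample(P5) ++ P4
        "td_p3_hidden": 272,     # fusion block after upsample(N4) ++ P3
        "down_p4_channels": 75,  # P3out -> stride 16 downsampler width
        "down_p5_channels": 37,  # P4out -> stride 32 downsampler width
        "bu_p4_hidden": 298,
        "bu_p5_hidden": 940,
    },
    "head": {
        "standard_reg_hidden": 86,
        "standard_cls_hidden": 48,
        "light_hidden": [124, 88, 96],
    },
    "shuffle_groups": 2,
    "se_ratio": 0.25,
}


def load_width_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_width_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclass
class Detection:
    """One predicted box in image pixels."""
    class_id: int
    score: float
    box: tuple[float, float, float, float]  # x1, y1, x2, y2


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------

class _HeadBranchLight(Module):
    def __init__(self, ci, hidden, out, groups, rng):
        super().__init__()
        if ci % groups or hidden % groups:
            raise ValueError(
                f"head branch channels {ci}->{hidden} not divisible by groups={groups}")
        self.gconv = ConvBNAct(ci, hidden, 3, groups=groups, act="silu", rng=rng)
        self.dw = ConvBNAct(hidden, hidden, 3, groups=hidden, act="silu", rng=rng)
        self.pw = ConvBNAct(hidden, hidden, 1, act="silu", rng=rng)
        self.out = Conv2d(hidden, out, 1, bias=True, rng=rng)

    def forward(self, x):
        return self.out(self.pw(self.dw(self.gconv(x))))


def _init_head_priors(reg_branches, cls_branches):
    # rare-object prior: initial class probability ~0.01; small positive
    # regression bias keeps early decoded boxes off-degenerate
    for b in cls_branches:
        b.out.bias.data[...] = -4.6
    for b in reg_branches:
        b.out.bias.data[...] = 1.0


class LightDetect(Module):
    """Lightweight decoupled head: group conv -> depthwise-separable conv ->
    1x1 prediction, per level and per branch (box regression / classification)."""

    def __init__(self, in_channels, cfg: HeadConfig, hiddens, rng):
        super().__init__()
        self.cfg = cfg
        self.reg = ModuleList([
            _HeadBranchLight(ci, h, 4 * cfg.reg_max, cfg.groups, rng)
            for ci, h in zip(in_channels, hiddens)])
        self.cls = ModuleList([
            _HeadBranchLight(ci, h, cfg.num_classes, cfg.groups, rng)
            for ci, h in zip(in_channels, hiddens)])
        _init_head_priors(self.reg, self.cls)

    def forward(self, feats):
        return [(r(f), c(f)) for f, r, c in zip(feats, self.reg, self.cls)]


class _HeadBranchStd(Module):
    def __init__(self, ci, hidden, out, rng):
        super().__init__()
        self.c1 = ConvBNAct(ci, hidden, 3, act="silu", rng=rng)
        self.c2 = ConvBNAct(hidden, hidden, 3, act="silu", rng=rng)
        self.out = Conv2d(hidden, out, 1, bias=True, rng=rng)

    def forward(self, x):
        return self.out(self.c2(self.c1(x)))


class StandardDetect(Module):
    """Baseline decoupled head with full dense 3x3 convolutions."""

    def __init__(self, in_channels, cfg: HeadConfig, reg_hidden, cls_hidden, rng):
        super().__init__()
        self.cfg = cfg
        self.reg = ModuleList([
            _HeadBranchStd(ci, reg_hidden, 4 * cfg.reg_max, rng) for ci in in_channels])
        self.cls = ModuleList([
            _HeadBranchStd(ci, cls_hidden, cfg.num_classes, rng) for ci in in_channels])
        _init_head_priors(self.reg, self.cls)

    def forward(self, feats):
        return [(r(f), c(f)) for f, r, c in zip(feats, self.reg, self.cls)]


def lightdetect_forward(feats, cfg: HeadConfig, module: LightDetect):
    return module([f if isinstance(f, Tensor) else Tensor(f) for f in feats])


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class LGWheatNet(Module):
    def __init__(self, flags: VariantFlags = VariantFlags(),
                 head_cfg: HeadConfig | None = None,
                 width_config: dict | None = None, seed: int = 0):
        super().__init__()
        self.flags = flags
        self.head_cfg = head_cfg or HeadConfig()
        wc = copy.deepcopy(width_config or DEFAULT_WIDTH_CONFIG)
        self.width_config = wc
        rng = np.random.default_rng(seed)
        sg, ser = wc.get("shuffle_groups", 2), wc.get("se_ratio", 0.25)

        def block(ci, co, stride, hidden):
            cfg = SeCUIBConfig(ci, co, expand_ratio=hidden / ci,
                               start_dw_kernel=3 if stride == 2 else 0,
                               mid_dw_kernel=3, stride=stride,
                               shuffle_groups=sg, se_ratio=ser,
                               hidden_channels=hidden)
            return SeCUIB(cfg, use_se=flags.use_secuib,
                          use_shuffle=flags.use_secuib, rng=rng)

        c0 = wc["stem_channels"]
        self.stem = ConvBNAct(3, c0, 3, 2, act="silu", rng=rng)
        self.backbone = ModuleList([
            block(b["in"], b["out"], b["stride"], b["hidden"]) for b in wc["backbone"]])
        self.p3_index, self.p4_index = wc["p3_index"], wc["p4_index"]
        c3 = wc["backbone"][self.p3_index]["out"]
        c4 = wc["backbone"][self.p4_index]["out"]
        c5 = wc["backbone"][-1]["out"]
        self.channels = (c3, c4, c5)
        self.sppf = SPPF(SPPFConfig(c5, c5, wc["sppf_pool_kernel"]), rng=rng)

        nk = wc["neck"]
        self.td_p4 = block(c5 + c4, c4, 1, nk["td_p4_hidden"])
        self.td_p3 = block(c4 + c3, c3, 1, nk["td_p3_hidden"])
        d4, d5 = nk["down_p4_channels"], nk["down_p5_channels"]
        if flags.use_dwdown:
            self.down_p4 = DWDown(DWDownConfig(c3, d4), rng=rng)
            self.down_p5 = DWDown(DWDownConfig(c4, d5), rng=rng)
        else:
            self.down_p4 = ConvDown(c3, d4, rng=rng)
            self.down_p5 = ConvDown(c4, d5, rng=rng)
        self.bu_p4 = block(d4 + c4, c4, 1, nk["bu_p4_hidden"])
        self.bu_p5 = block(d5 + c5, c5, 1, nk["bu_p5_hidden"])

        hd = wc["head"]
        if flags.use_lightdetect:
            self.head = LightDetect(self.channels, self.head_cfg,
                                    hd["light_hidden"], rng)
        else:
            self.head = StandardDetect(self.channels, self.head_cfg,
                                       hd["standard_reg_hidden"],
                                       hd["standard_cls_hidden"], rng)

    # -- forward --------------------------------------------------------
    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input spatial dims {h}x{w} must be divisible by 32")
        y = self.stem(x)
        p3 = p4 = None
        for i, blk in enumerate(self.backbone):
            y = blk(y)
            if i == self.p3_index:
                p3 = y
            elif i == self.p4_index:
                p4 = y
        p5 = self.sppf(y)

        n4 = self.td_p4(E.concat([E.upsample2(p5), p4], axis=1))
        n3 = self.td_p3(E.concat([E.upsample2(n4), p3], axis=1))
        n4b = self.bu_p4(E.concat([self.down_p4(n3), n4], axis=1))
        n5b = self.bu_p5(E.concat([self.down_p5(n4b), p5], axis=1))
        return self.head([n3, n4b, n5b])

    def predict(self, image: np.ndarray, conf_threshold: float = 0.25,
                iou_threshold: float = 0.5) -> list[Detection]:
        """Run eval-mode detection on one HxWx3 uint8/float image."""
        self.eval()
        x = preprocess(image)
        with E.no_grad():
            raw = self.forward(x)
        return decode_predictions(raw, self.head_cfg, conf_threshold,
                                  iou_threshold, image.shape[:2])


def preprocess(image: np.ndarray) -> np.ndarray:
    """HxWx3 image -> normalized [1,3,H,W] float32, padded to /32."""
    img = np.asarray(image, dtype=np.float32) / 255.0
    h, w = img.shape[:2]
    ph, pw = (-h) % 32, (-w) % 32
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)))
    return img.transpose(2, 0, 1)[None]


def build_model(flags: VariantFlags = VariantFlags(),
                head_cfg: HeadConfig | None = None,
                width_config: dict | None = None, seed: int = 0) -> LGWheatNet:
    return LGWheatNet(flags, head_cfg, width_config, seed)


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_parameters(model: Module) -> int:
    """Total number of trainable scalars (conv/linear weights+biases, BN affine)."""
    return model.num_parameters()


def count_flops(model: LGWheatNet, input_hw: tuple[int, int] = (640, 640)) -> float:
    """GFLOPs (2 x multiply-accumulates over conv/linear layers) at input_hw."""
    h, w = input_hw
    if h % 32 or w % 32:
        raise ValueError("input dims must be divisible by 32")
    was_training = model.training
    model.eval()
    x = np.zeros((1, 3, h, w), dtype=np.float32)
    with E.no_grad(), E.count_macs() as macs:
        model.forward(x)
    model.train(was_training)
    return 2.0 * macs[0] / 1e9


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def make_anchors(level_hw: list[tuple[int, int]], strides) -> list[np.ndarray]:
    """Cell-center anchor points (x, y) in image pixels, one array per level."""
    out = []
    for (h, w), s in zip(level_hw, strides):
        xs = (np.arange(w) + 0.5) * s
        ys = (np.arange(h) + 0.5) * s
        gx, gy = np.meshgrid(xs, ys)
        out.append(np.stack([gx.ravel(), gy.ravel()], axis=1).astype(np.float32))
    return out


def dfl_expectation(reg: np.ndarray, reg_max: int) -> np.ndarray:
    """(N, 4*reg_max, H, W) logits -> (N, 4, H, W) expected bin distances."""
    n, _, h, w = reg.shape
    r = reg.reshape(n, 4, reg_max, h, w)
    r = r - r.max(axis=2, keepdims=True)
    e = np.exp(r)
    p = e / e.sum(axis=2, keepdims=True)
    bins = np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1, 1)
    return (p * bins).sum(axis=2)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    boxes = boxes[order]
    x1, y1, x2, y2 = boxes.T
    areas = (x2 - x1) * (y2 - y1)
    alive = np.ones(len(order), dtype=bool)
    for i in range(len(order)):
        if not alive[i]:
            continue
        keep.append(order[i])
        xx1 = np.maximum(x1[i], x1)
        yy1 = np.maximum(y1[i], y1)
        xx2 = np.minimum(x2[i], x2)
        yy2 = np.minimum(y2[i], y2)
        inter = np.clip(xx2 - xx1, 0, None) * np.clip(yy2 - yy1, 0, None)
        iou = inter / np.maximum(areas[i] + areas - inter, 1e-9)
        alive &= iou <= iou_threshold
        alive[i] = False
    return np.asarray(keep, dtype=int)


def decode_predictions(raw, cfg: HeadConfig, conf_threshold: float = 0.25,
                       iou_threshold: float = 0.5,
                       image_hw: tuple[int, int] | None = None) -> list[Detection]:
    """DFL-decode raw per-level (reg, cls) outputs of a single image, filter by
    confidence, and apply class-wise greedy NMS."""
    level_hw = [r.shape[2:] for r, _ in raw]
    anchors = make_anchors(level_hw, cfg.strides)
    all_boxes, all_scores, all_cls = [], [], []
    for (reg, cls), anc, stride in zip(raw, anchors, cfg.strides):
        reg = reg.data if isinstance(reg, Tensor) else np.asarray(reg)
        cls = cls.data if isinstance(cls, Tensor) else np.asarray(cls)
        dist = dfl_expectation(reg[:1], cfg.reg_max)[0].reshape(4, -1).T * stride
        with np.errstate(over="ignore"):
            scores = 1.0 / (1.0 + np.exp(-cls[0].reshape(cfg.num_classes, -1).T))
        boxes = np.stack([anc[:, 0] - dist[:, 0], anc[:, 1] - dist[:, 1],
                          anc[:, 0] + dist[:, 2], anc[:, 1] + dist[:, 3]], axis=1)
        all_boxes.append(boxes)
        all_scores.append(scores)
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    dets: list[Detection] = []
    for k in range(cfg.num_classes):
        sk = scores[:, k]
        m = sk > conf_threshold
        if not m.any():
            continue
        bk, sk = boxes[m], sk[m]
        for i in nms(bk, sk, iou_threshold):
            x1, y1, x2, y2 = bk[i]
            if image_hw is not None:
                h, w = image_hw
                x1, x2 = np.clip([x1, x2], 0, w)
                y1, y2 = np.clip([y1, y2], 0, h)
            if x2 > x1 and y2 > y1:
                dets.append(Detection(k, float(sk[i]), (float(x1), float(y1),
                                                        float(x2), float(y2))))
    dets.sort(key=lambda d: -d.score)
    return dets
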