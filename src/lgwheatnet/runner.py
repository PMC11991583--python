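"""Training loop (SGD + momentum, linear decay with warmup), evaluation
driver, and the ablation harness.

Hyperparameter defaults are the detector's training recipe: 300 epochs,
lr0 = 0.01 decaying linearly to lr0 * lrf with lrf = 0.01, momentum 0.937,
weight decay 5e-4 (applied to convolution weights only), 3 warmup epochs with
momentum 0.8 and bias learning rate warming from 0.1.  Only the offline
augmentation suite is used — no train-time mosaic.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import engine as E
from .data_io import AnnotatedImage
from .loss_assign import detection_loss
from .metrics import counting_metrics, map_suite
from .network import (VariantFlags, build_model, count_flops,
                      count_parameters, decode_predictions)

__all__ = ["TrainConfig", "lr_schedule", "train", "evaluate", "run_ablation"]


@dataclass
class TrainConfig:
    epochs: int = 300
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: int = 3
    warmup_momentum: float = 0.8
    warmup_bias_lr: float = 0.1
    batch_size: int = 16
    input_size: int = 640
    loss_weights: tuple[float, float, float] = (7.5, 0.5, 1.5)
    val_interval: int = 1          # epochs between val metric evaluations
    seed: int = 0

    def __post_init__(self):
        if self.lrf > 1:
            raise ValueError("lrf must be <= 1")
        if min(self.epochs, self.lr0, self.batch_size, self.input_size) <= 0:
            raise ValueError("config values must be positive")


def lr_schedule(epoch: int, step: int, steps_per_epoch: int, cfg: TrainConfig):
    """Learning rates per parameter group and momentum at a training step.

    Returns dict with ``lr_weights``, ``lr_other``, ``lr_bias``, ``momentum``.
    During warmup each lr ramps linearly from 0 (biases from warmup_bias_lr)
    to the scheduled value; afterwards lr decays linearly from lr0 to lr0*lrf
    at the final epoch."""
    denom = max(cfg.epochs - 1, 1)
    lin = cfg.lr0 * (1.0 - (min(epoch, denom) / denom) * (1.0 - cfg.lrf))
    s = epoch * steps_per_epoch + step
    nw = cfg.warmup_epochs * steps_per_epoch
    if s < nw:
        lr_w = float(np.interp(s, [0, nw], [0.0, lin]))
        lr_b = float(np.interp(s, [0, nw], [cfg.warmup_bias_lr, lin]))
        mom = float(np.interp(s, [0, nw], [cfg.warmup_momentum, cfg.momentum]))
    else:
        lr_w, lr_b, mom = lin, lin, cfg.momentum
    return {"lr_weights": lr_w, "lr_other": lr_w, "lr_bias": lr_b, "momentum": mom}


def _param_groups(model, cfg: TrainConfig):
    decay, other, bias = [], [], []
    for name, p in model.named_parameters():
        leaf = name.rsplit(".", 1)[-1]
        if leaf == "bias":
            bias.append(p)
        elif leaf == "weight" and p.data.ndim >= 2:
            decay.append(p)
        else:
            other.append(p)  # BN gamma/beta
    return [
        {"params": decay, "lr": cfg.lr0, "momentum": cfg.momentum,
         "weight_decay": cfg.weight_decay},
        {"params": other, "lr": cfg.lr0, "momentum": cfg.momentum, "weight_decay": 0.0},
        {"params": bias, "lr": cfg.lr0, "momentum": cfg.momentum, "weight_decay": 0.0},
    ]


def prepare_sample(ann: AnnotatedImage, size: int):
    """Scale the long side to ``size``, pad bottom/right; returns (chw float32
    array in [0,1], boxes scaled to network pixels, class ids)."""
    img = ann.image
    h, w = img.shape[:2]
    scale = size / max(h, w)
    boxes = ann.boxes * scale
    if (h, w) != (size, size):
        nh, nw = round(h * scale), round(w * scale)
        img = _sk_resize(img, (nh, nw), order=1, preserve_range=True,
                         anti_aliasing=True)
        out = np.zeros((size, size, 3), dtype=np.float32)
        out[:nh, :nw] = img
        img = out
    x = np.asarray(img, dtype=np.float32) / 255.0
    return x.transpose(2, 0, 1), boxes.astype(np.float64), ann.class_ids


def train(model, train_images: list[AnnotatedImage],
          val_images: list[AnnotatedImage] | None = None,
          cfg: TrainConfig | None = None, out_dir=None, verbose: bool = False):
    """SGD training; returns history dict and leaves the best-mAP50 weights
    (falling back to final weights when validation is off) loaded in the model."""
    cfg = cfg or TrainConfig()
    if not train_images:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    groups = _param_groups(model, cfg)
    opt = E.SGD(groups)
    n = len(train_images)
    steps_per_epoch = max(1, (n + cfg.batch_size - 1) // cfg.batch_size)
    prepared = [prepare_sample(a, cfg.input_size) for a in train_images]
    history = {"epoch_loss": [], "val_map50": [], "components": []}
    best = {"map50": -1.0, "state": None}
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses, comps_acc = [], []
        for step in range(steps_per_epoch):
            idx = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            if len(idx) == 0:
                continue
            xb = np.stack([prepared[i][0] for i in idx])
            targets = [(prepared[i][1], prepared[i][2]) for i in idx]
            sched = lr_schedule(epoch, step, steps_per_epoch, cfg)
            for g, key in zip(groups, ("lr_weights", "lr_other", "lr_bias")):
                g["lr"] = sched[key]
                g["momentum"] = sched["momentum"]
            raw = model.forward(xb)
            loss, comps = detection_loss(raw, targets, model.head_cfg,
                                         cfg.loss_weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} step {step}: {comps}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            comps_acc.append(comps)
        history["epoch_loss"].append(float(np.mean(losses)))
        history["components"].append(
            {k: float(np.mean([c[k] for c in comps_acc])) for k in ("box", "cls", "dfl")})
        if val_images and cfg.val_interval and (
                epoch % cfg.val_interval == 0 or epoch == cfg.epochs - 1):
            stats = evaluate(model, val_images, input_size=cfg.input_size)
            history["val_map50"].append((epoch, stats["map50"]))
            if stats["map50"] > best["map50"]:
                best = {"map50": stats["map50"], "state": model.state_dict()}
        if verbose:
            print(f"epoch {epoch}: loss {history['epoch_loss'][-1]:.4f}")
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        model.save(Path(out_dir) / "best.npz")
    history["best_map50"] = best["map50"]
    return history


def evaluate(model, images: list[AnnotatedImage], conf: float = 0.01,
             nms_iou: float = 0.5, count_conf: float = 0.25,
             input_size: int | None = None, mode: str = "standard10"):
    """Detection metric suite plus per-image counting metrics.

    The per-image predicted count is the number of post-NMS detections with
    confidence above ``count_conf``."""
    model.eval()
    dets, gts, t_counts, p_counts = [], [], [], []
    for ann in images:
        if input_size is not None:
            x, boxes, cls = prepare_sample(ann, input_size)
        else:
            size = int(np.ceil(max(ann.image.shape[:2]) / 32) * 32)
            x, boxes, cls = prepare_sample(ann, size)
        with E.no_grad():
            raw = model.forward(x[None])
        size_hw = (x.shape[1], x.shape[2])
        d = decode_predictions(raw, model.head_cfg, conf, nms_iou, size_hw)
        dets.append((np.array([dd.box for dd in d]).reshape(-1, 4),
                     np.array([dd.score for dd in d]),
                     np.array([dd.class_id for dd in d], dtype=int)))
        gts.append((boxes, cls))
        t_counts.append(len(boxes))
        p_counts.append(sum(1 for dd in d if dd.score >= count_conf))
    stats = map_suite(dets, gts, mode=mode)
    cm = counting_metrics(t_counts, p_counts)
    stats.update({"count_rmse": cm.rmse, "count_mae": cm.mae,
                  "count_mse": cm.mse, "count_r2": cm.r2})
    return stats


def run_ablation(width_config=None, input_hw=(640, 640), with_flops: bool = True):
    """Machine-checkable ablation table: parameters (and GFLOPs) per variant."""
    rows = []
    for flags in VariantFlags.all_combinations():
        model = build_model(flags, width_config=width_config)
        row = {"use_secuib": flags.use_secuib, "use_dwdown": flags.use_dwdown,
               "use_lightdetect": flags.use_lightdetect,
               "parameters": count_parameters(model)}
        if with_flops:
            row["gflops"] = round(count_flops(model, input_hw), 1)
        rows.append(row)
    return rows
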