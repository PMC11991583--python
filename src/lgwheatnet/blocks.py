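"""Bespoke building blocks of the wheat-spike detector.

SeCUIB — a squeeze-excitation + channel-shuffle universal inverted bottleneck
(optional initial depthwise conv, 1x1 expansion, optional mid depthwise conv
carrying the stride, channel shuffle, linear 1x1 projection, SE gate, residual).
DWDown — pointwise channel adjustment, stride-2 depthwise feature extraction,
batch normalization.  SPPF — halve channels, three chained stride-1 max pools,
concat, fuse.  Plus the primitive operators (SiLU, channel shuffle, SE, batch
norm) exposed functionally.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine as E
from .engine import Module, Parameter, Tensor

CLASS_NAMES = ("flowerwheat", "fillingwheat", "ripewheat")


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def silu(x):
    """SiLU activation f(x) = x / (1 + exp(-x)), elementwise."""
    if isinstance(x, Tensor):
        return E.silu(x)
    x = np.asarray(x, dtype=np.float64)
    return x / (1.0 + np.exp(-x))


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Index permutation pi with out[i] = in[pi[i]] for channel shuffle."""
    if channels % groups:
        raise ValueError(f"channels={channels} not divisible by groups={groups}")
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


def channel_shuffle(x, groups: int):
    """Reshape-(groups, C/groups)-transpose-flatten channel permutation."""
    c = x.shape[1]
    if c % groups:
        raise ValueError(f"channels={c} not divisible by groups={groups}")
    n, _, h, w = x.shape
    if isinstance(x, Tensor):
        y = E.reshape(x, (n, groups, c // groups, h, w))
        y = E.transpose(y, (0, 2, 1, 3, 4))
        return E.reshape(y, (n, c, h, w))
    return x.reshape(n, groups, c // groups, h, w).transpose(0, 2, 1, 3, 4).reshape(x.shape)


def channel_shuffle_inverse(x, groups: int):
    """Inverse of ``channel_shuffle`` (shuffle with C//groups groups)."""
    return channel_shuffle(x, x.shape[1] // groups)


@dataclass
class BNParams:
    """Per-channel batch-normalization statistics and affine parameters."""
    mean: np.ndarray
    var: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5

    def __post_init__(self):
        if np.any(np.asarray(self.var) < 0):
            raise ValueError("variance must be non-negative")
        if self.eps <= 0:
            raise ValueError("epsilon must be positive")


def batch_norm(x: np.ndarray, p: BNParams) -> np.ndarray:
    """Normalize x per channel: (x - mu)/sqrt(var + eps) * gamma + beta."""
    x = np.asarray(x, dtype=np.float64)
    sh = (1, -1) + (1,) * (x.ndim - 2)
    mu = np.asarray(p.mean, dtype=np.float64).reshape(sh)
    var = np.asarray(p.var, dtype=np.float64).reshape(sh)
    g = np.asarray(p.gamma, dtype=np.float64).reshape(sh)
    b = np.asarray(p.beta, dtype=np.float64).reshape(sh)
    return (x - mu) / np.sqrt(var + p.eps) * g + b


# ---------------------------------------------------------------------------
# layer modules
# ---------------------------------------------------------------------------

def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, ci: int, co: int, k: int = 1, stride: int = 1,
                 groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.groups, self.k = stride, groups, k
        self.weight = Parameter(_kaiming(rng, (co, ci // groups, k, k),
                                         ci // groups * k * k))
        self.bias = Parameter(np.zeros(co, dtype=np.float32)) if bias else None

    def forward(self, x):
        return E.conv2d(x, self.weight, self.bias, self.stride, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x):
        if self.training:
            return E.batch_norm_train(x, self.gamma, self.beta, self.running_mean,
                                      self.running_var, self.momentum, self.eps)
        return E.batch_norm_eval(x, self.gamma, self.beta, self.running_mean,
                                 self.running_var, self.eps)


_ACTS = {"silu": E.silu, "relu": E.relu, None: lambda t: t, "none": lambda t: t}


class ConvBNAct(Module):
    """Bias-free convolution + batch norm + activation."""

    def __init__(self, ci, co, k=1, stride=1, groups=1, act="silu", rng=None):
        super().__init__()
        self.conv = Conv2d(ci, co, k, stride, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(co)
        self.act = act

    def forward(self, x):
        return _ACTS[self.act](self.bn(self.conv(x)))


class SqueezeExcite(Module):
    """Two-layer channel-gating bottleneck: GAP -> reduce -> ReLU -> expand -> sigmoid."""

    def __init__(self, c: int, se_ratio: float = 0.25, rng=None):
        super().__init__()
        if not 0 < se_ratio <= 1:
            raise ValueError("se_ratio must lie in (0, 1]")
        r = max(1, round(c * se_ratio))
        self.reduce = Conv2d(c, r, 1, bias=True, rng=rng)
        self.expand = Conv2d(r, c, 1, bias=True, rng=rng)

    def forward(self, x):
        g = E.global_avg_pool(x)
        g = E.sigmoid(self.expand(E.relu(self.reduce(g))))
        return x * g


def squeeze_excite(x, se_ratio: float, module: SqueezeExcite | None = None):
    """Functional SE: gate ``x`` with a (given or fresh) SE module."""
    m = module or SqueezeExcite(x.shape[1], se_ratio)
    return m(x if isinstance(x, Tensor) else Tensor(x))


# ---------------------------------------------------------------------------
# SeCUIB / UIB
# ---------------------------------------------------------------------------

@dataclass
class SeCUIBConfig:
    in_channels: int
    out_channels: int
    expand_ratio: float = 2.0
    start_dw_kernel: int = 0
    mid_dw_kernel: int = 3
    stride: int = 1
    shuffle_groups: int = 2
    se_ratio: float = 0.25
    hidden_channels: int | None = None  # overrides round(in * expand_ratio)

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.stride == 2 and not (self.start_dw_kernel or self.mid_dw_kernel):
            raise ValueError("stride 2 requires at least one depthwise stage")

    @property
    def hidden(self) -> int:
        h = self.hidden_channels
        if h is None:
            h = round(self.in_channels * self.expand_ratio)
        if h % self.shuffle_groups:
            raise ValueError(
                f"expanded channels {h} not divisible by shuffle_groups={self.shuffle_groups}")
        return h

    @property
    def has_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


class SeCUIB(Module):
    """Universal inverted bottleneck with SE attention and channel shuffle.

    With ``use_se=False`` and ``use_shuffle=False`` this is the plain UIB
    baseline block (ReLU-family activation by default in that mode).
    """

    def __init__(self, cfg: SeCUIBConfig, use_se: bool = True,
                 use_shuffle: bool = True, act: str | None = None, rng=None):
        super().__init__()
        self.cfg = cfg
        self.use_se, self.use_shuffle = use_se, use_shuffle
        self.act = act if act is not None else ("silu" if use_se or use_shuffle else "relu")
        ci, co, h = cfg.in_channels, cfg.out_channels, cfg.hidden
        # stride lives on the mid depthwise conv when present, else on the start conv
        s_start = cfg.stride if (cfg.start_dw_kernel and not cfg.mid_dw_kernel) else 1
        s_mid = cfg.stride if cfg.mid_dw_kernel else 1
        if cfg.start_dw_kernel:
            self.start_dw = Conv2d(ci, ci, cfg.start_dw_kernel, s_start, groups=ci, rng=rng)
            self.start_bn = BatchNorm2d(ci)
        else:
            self.start_dw = None
        self.expand = Conv2d(ci, h, 1, rng=rng)
        self.expand_bn = BatchNorm2d(h)
        if cfg.mid_dw_kernel:
            self.mid_dw = Conv2d(h, h, cfg.mid_dw_kernel, s_mid, groups=h, rng=rng)
            self.mid_bn = BatchNorm2d(h)
        else:
            self.mid_dw = None
        self.project = Conv2d(h, co, 1, rng=rng)
        self.project_bn = BatchNorm2d(co)
        self.se = SqueezeExcite(co, cfg.se_ratio, rng=rng) if use_se else None

    def forward(self, x):
        act = _ACTS[self.act]
        y = x
        if self.start_dw is not None:
            y = self.start_bn(self.start_dw(y))
        y = act(self.expand_bn(self.expand(y)))
        if self.mid_dw is not None:
            y = act(self.mid_bn(self.mid_dw(y)))
            if self.use_shuffle:
                y = channel_shuffle(y, self.cfg.shuffle_groups)
        y = self.project_bn(self.project(y))  # linear projection, no activation
        if self.se is not None:
            y = self.se(y)
        if self.cfg.has_residual:
            y = y + x
        return y


def secuib_forward(x, cfg: SeCUIBConfig, module: SeCUIB | None = None):
    m = module or SeCUIB(cfg)
    return m(x if isinstance(x, Tensor) else Tensor(x))


# ---------------------------------------------------------------------------
# DWDown / plain downsampler
# ---------------------------------------------------------------------------

@dataclass
class DWDownConfig:
    in_channels: int
    out_channels: int
    dw_kernel: int = 3
    stride: int = 2

    def __post_init__(self):
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.stride != 2:
            raise ValueError("DWDown is a downsampling block; stride is fixed at 2")


class DWDown(Module):
    """Pointwise channel adjustment -> stride-2 depthwise conv -> batch norm."""

    def __init__(self, cfg: DWDownConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        self.pw = Conv2d(cfg.in_channels, cfg.out_channels, 1, rng=rng)
        self.dw = Conv2d(cfg.out_channels, cfg.out_channels, cfg.dw_kernel,
                         cfg.stride, groups=cfg.out_channels, rng=rng)
        self.bn = BatchNorm2d(cfg.out_channels)

    def forward(self, x):
        return self.bn(self.dw(self.pw(x)))


def dwdown_forward(x, cfg: DWDownConfig, module: DWDown | None = None):
    m = module or DWDown(cfg)
    return m(x if isinstance(x, Tensor) else Tensor(x))


class ConvDown(Module):
    """Plain dense 3x3 stride-2 downsampler (baseline substitute for DWDown)."""

    def __init__(self, ci: int, co: int, rng=None):
        super().__init__()
        self.conv = ConvBNAct(ci, co, 3, 2, act="silu", rng=rng)

    def forward(self, x):
        return self.conv(x)


# ---------------------------------------------------------------------------
# SPPF
# ---------------------------------------------------------------------------

@dataclass
class SPPFConfig:
    in_channels: int
    out_channels: int
    pool_kernel: int = 5

    def __post_init__(self):
        if self.in_channels // 2 < 1:
            raise ValueError("SPPF needs in_channels >= 2")


class SPPF(Module):
    """Spatial pyramid pooling (fast): halve channels, chain three stride-1
    max pools, concatenate the four maps, fuse with a 1x1 conv."""

    def __init__(self, cfg: SPPFConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        h = cfg.in_channels // 2
        self.cv1 = ConvBNAct(cfg.in_channels, h, 1, act="silu", rng=rng)
        self.cv2 = ConvBNAct(4 * h, cfg.out_channels, 1, act="silu", rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        p1 = E.max_pool2d(y, self.cfg.pool_kernel)
        p2 = E.max_pool2d(p1, self.cfg.pool_kernel)
        p3 = E.max_pool2d(p2, self.cfg.pool_kernel)
        return self.cv2(E.concat([y, p1, p2, p3], axis=1))


def sppf_forward(x, cfg: SPPFConfig, module: SPPF | None = None):
    m = module or SPPF(cfg)
    return m(x if isinstance(x, Tensor) else Tensor(x))
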