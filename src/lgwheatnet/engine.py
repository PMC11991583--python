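"""Minimal reverse-mode autodiff engine on numpy arrays.

Implements exactly the operator set the wheat-spike detector needs: grouped /
depthwise 2-D convolution, batch normalization, stride-1 max pooling, nearest
upsampling, elementwise math, reductions, indexing, and an SGD optimizer with
momentum, weight decay and parameter groups.  Tensors carry ``float32`` data
and build a dynamic graph; ``backward()`` runs a topological sweep.

A global MAC counter can be armed around a forward pass to measure the
multiply-accumulate cost of convolution/linear work (see ``count_macs``).
"""
from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "SGD", "no_grad", "count_macs",
]

_grad_enabled = True
_mac_counter: list[float] | None = None


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextlib.contextmanager
def count_macs():
    """Context manager yielding a one-element list accumulating conv/linear MACs."""
    global _mac_counter
    prev = _mac_counter
    _mac_counter = [0.0]
    try:
        yield _mac_counter
    finally:
        _mac_counter = prev


def _as_array(x) -> np.ndarray:
    """float64 arrays are preserved (for high-precision gradient checks);
    everything else becomes float32."""
    if isinstance(x, np.ndarray) and x.dtype == np.float64:
        return x
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures
        # graph edges no longer needed
        for node in topo:
            node._parents = ()

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += g

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, k):
        return power(self, k)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even under no_grad


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient g down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise binary ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bw)


def sub(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data - b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), bw)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bw)


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data / b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(data, (a, b), bw)


def maximum(a, b):
    a, b = _wrap(a), _wrap(b)
    data = np.maximum(a.data, b.data)

    def bw(g):
        m = (a.data >= b.data)
        if a.requires_grad:
            a._accum(_unbroadcast(g * m, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~m), b.data.shape))

    return _make(data, (a, b), bw)


def minimum(a, b):
    a, b = _wrap(a), _wrap(b)
    data = np.minimum(a.data, b.data)

    def bw(g):
        m = (a.data <= b.data)
        if a.requires_grad:
            a._accum(_unbroadcast(g * m, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~m), b.data.shape))

    return _make(data, (a, b), bw)


# ---------------------------------------------------------------------------
# elementwise unary ops
# ---------------------------------------------------------------------------

def power(a, k: float):
    a = _wrap(a)
    data = a.data ** k

    def bw(g):
        a._accum(g * k * a.data ** (k - 1))

    return _make(data, (a,), bw)


def sqrt(a):
    a = _wrap(a)
    data = np.sqrt(a.data)

    def bw(g):
        a._accum(g * 0.5 / np.maximum(data, 1e-12))

    return _make(data, (a,), bw)


def exp(a):
    a = _wrap(a)
    data = np.exp(a.data)

    def bw(g):
        a._accum(g * data)

    return _make(data, (a,), bw)


def log(a):
    a = _wrap(a)
    data = np.log(a.data)

    def bw(g):
        a._accum(g / a.data)

    return _make(data, (a,), bw)


def arctan(a):
    a = _wrap(a)
    data = np.arctan(a.data)

    def bw(g):
        a._accum(g / (1.0 + a.data * a.data))

    return _make(data, (a,), bw)


def sigmoid(a):
    a = _wrap(a)
    with np.errstate(over="ignore"):
        data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accum(g * data * (1.0 - data))

    return _make(data, (a,), bw)


def silu(a):
    """x * sigmoid(x) — the swish activation."""
    a = _wrap(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    data = a.data * s

    def bw(g):
        a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(data, (a,), bw)


def relu(a):
    a = _wrap(a)
    data = np.maximum(a.data, 0.0)

    def bw(g):
        a._accum(g * (a.data > 0))

    return _make(data, (a,), bw)


def clip_min(a, lo: float):
    a = _wrap(a)
    data = np.maximum(a.data, lo)

    def bw(g):
        a._accum(g * (a.data > lo))

    return _make(data, (a,), bw)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = _wrap(a)
    old = a.data.shape
    data = a.data.reshape(shape)

    def bw(g):
        a._accum(g.reshape(old))

    return _make(data, (a,), bw)


def transpose(a, axes):
    a = _wrap(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(g):
        a._accum(g.transpose(inv))

    return _make(data, (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1):
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, o, s in zip(tensors, offsets, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o, o + s)
                t._accum(g[tuple(sl)])

    return _make(data, tuple(tensors), bw)


def take(a, idx: np.ndarray, axis: int = 0):
    """Gather rows along ``axis`` with an integer index array."""
    a = _wrap(a)
    data = np.take(a.data, idx, axis=axis)

    def bw(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, (slice(None),) * axis + (idx,), g)
        a._accum(ga)

    return _make(data, (a,), bw)


def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def softmax(a, axis: int = -1):
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accum(data * (g - dot))

    return _make(data, (a,), bw)


# ---------------------------------------------------------------------------
# neural-net ops
# ---------------------------------------------------------------------------

def _patches(xp: np.ndarray, k: int, stride: int):
    """(N,C,Hp,Wp) -> strided view (N,C,OH,OW,k,k)."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def conv2d(x, w, b=None, stride: int = 1, groups: int = 1):
    """Grouped 2-D convolution with symmetric same-padding k//2.

    x: (N, C, H, W); w: (Cout, C/groups, k, k); b: (Cout,) or None.
    Output spatial size is ceil(H/stride) for odd kernels.
    """
    x, w = _wrap(x), _wrap(w)
    cout, cg, k, _ = w.data.shape
    n, c, h, wd = x.data.shape
    if c % groups or cout % groups:
        raise ValueError(f"channels {c}->{cout} not divisible by groups={groups}")
    if c // groups != cg:
        raise ValueError("weight shape inconsistent with input channels/groups")
    pad = k // 2
    if groups == c and cout == c and k > 1:
        return _conv2d_depthwise(x, w, b, stride, pad)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    pt = _patches(xp, k, stride)  # (N,C,OH,OW,k,k)
    oh, ow = pt.shape[2], pt.shape[3]
    ptg = pt.reshape(n, groups, cg, oh, ow, k, k)
    wg = w.data.reshape(groups, cout // groups, cg, k, k)
    out = np.einsum("ngcxykl,gdckl->ngdxy", ptg, wg, optimize=True)
    out = out.reshape(n, cout, oh, ow)
    if _mac_counter is not None:
        _mac_counter[0] += float(n) * oh * ow * k * k * cg * cout
    bias = _wrap(b) if b is not None else None
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, w) + ((bias,) if bias is not None else ())

    def bw(g):
        gg = g.reshape(n, groups, cout // groups, oh, ow)
        if w.requires_grad:
            dw = np.einsum("ngcxykl,ngdxy->gdckl", ptg, gg, optimize=True)
            w._accum(dw.reshape(cout, cg, k, k))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dpt = np.einsum("gdckl,ngdxy->ngcxykl", wg, gg, optimize=True)
            dpt = dpt.reshape(n, c, oh, ow, k, k)
            dxp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad), dtype=np.float32)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + stride * oh:stride,
                        kj:kj + stride * ow:stride] += dpt[:, :, :, :, ki, kj]
            x._accum(dxp[:, :, pad:pad + h, pad:pad + wd] if pad else dxp)

    return _make(out, parents, bw)


def _conv2d_depthwise(x, w, b, stride: int, pad: int):
    """Fast path: per-channel spatial conv as k*k shifted multiply-adds."""
    n, c, h, wd = x.data.shape
    k = w.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    oh = (h + 2 * pad - k) // stride + 1
    ow = (wd + 2 * pad - k) // stride + 1
    out = np.zeros((n, c, oh, ow), dtype=np.float32)
    for ki in range(k):
        for kj in range(k):
            out += xp[:, :, ki:ki + stride * oh:stride,
                      kj:kj + stride * ow:stride] * w.data[:, 0, ki, kj].reshape(1, c, 1, 1)
    if _mac_counter is not None:
        _mac_counter[0] += float(n) * oh * ow * k * k * c
    bias = _wrap(b) if b is not None else None
    if bias is not None:
        out += bias.data.reshape(1, c, 1, 1)
    parents = (x, w) + ((bias,) if bias is not None else ())

    def bw(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for ki in range(k):
                for kj in range(k):
                    dw[:, 0, ki, kj] = (g * xp[:, :, ki:ki + stride * oh:stride,
                                               kj:kj + stride * ow:stride]).sum(axis=(0, 2, 3))
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad), dtype=np.float32)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + stride * oh:stride,
                        kj:kj + stride * ow:stride] += g * w.data[:, 0, ki, kj].reshape(1, c, 1, 1)
            x._accum(dxp[:, :, pad:pad + h, pad:pad + wd] if pad else dxp)

    return _make(out, parents, bw)


def max_pool2d(x, k: int, stride: int = 1):
    """Same-padded max pooling (used by SPPF with k=5, stride 1)."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    pt = _patches(xp, k, stride)
    oh, ow = pt.shape[2], pt.shape[3]
    flat = pt.reshape(n, c, oh, ow, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        ki, kj = np.divmod(arg, k)
        ii = np.arange(oh)[None, None, :, None] * stride + ki
        jj = np.arange(ow)[None, None, None, :] * stride + kj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, ii, jj), g)
        x._accum(dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp)

    return _make(out, (x,), bw)


def upsample2(x):
    """Nearest-neighbour 2x spatial upsampling."""
    x = _wrap(x)
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def bw(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(data, (x,), bw)


def global_avg_pool(x):
    x = _wrap(x)
    n, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3), keepdims=True)

    def bw(g):
        x._accum(np.broadcast_to(g / (h * w), x.data.shape).astype(np.float32))

    return _make(data, (x,), bw)


def batch_norm_train(x, gamma, beta, running_mean, running_var,
                     momentum: float = 0.03, eps: float = 1e-5):
    """Batch normalization using mini-batch statistics; updates running stats."""
    x = _wrap(x)
    axes = (0, 2, 3)
    m = x.data.mean(axis=axes)
    v = x.data.var(axis=axes)
    nel = x.data.size // x.data.shape[1]
    running_mean *= (1 - momentum)
    running_mean += momentum * m
    running_var *= (1 - momentum)
    running_var += momentum * (v * nel / max(nel - 1, 1))
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    data = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gy = g * gamma.data.reshape(1, -1, 1, 1)
            mean_gy = gy.mean(axis=axes, keepdims=True)
            mean_gy_xhat = (gy * xhat).mean(axis=axes, keepdims=True)
            dx = (gy - mean_gy - xhat * mean_gy_xhat) * inv.reshape(1, -1, 1, 1)
            x._accum(dx.astype(np.float32))

    return _make(data, (x, gamma, beta), bw)


def batch_norm_eval(x, gamma, beta, running_mean, running_var, eps: float = 1e-5):
    x = _wrap(x)
    inv = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * inv).reshape(1, -1, 1, 1)
    shift = (beta.data - gamma.data * running_mean * inv).reshape(1, -1, 1, 1)
    data = x.data * scale + shift

    def bw(g):
        if gamma.requires_grad:
            xhat = (x.data - running_mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(g * scale)

    return _make(data, (x, gamma, beta), bw)


def bce_with_logits(logits, targets):
    """Elementwise binary cross-entropy on raw logits (numerically stable)."""
    logits = _wrap(logits)
    z, y = logits.data, np.asarray(targets, dtype=np.float32)
    data = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accum(g * (s - y))

    return _make(data, (logits,), bw)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, ModuleList):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        for n, p in self.named_parameters():
            p.data[...] = d[n]
        for n, b in self.named_buffers():
            b[...] = d[n]

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as z:
            self.load_state_dict({k: z[k] for k in z.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods: Sequence[Module] = ()):  # noqa: D107
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class SGD:
    """SGD with momentum and decoupled parameter groups.

    groups: list of dicts with keys ``params`` (list of Parameter), ``lr``,
    ``momentum``, ``weight_decay``.  Learning rate / momentum can be updated
    in-place between steps by the scheduler.
    """

    def __init__(self, groups: list[dict]):
        self.groups = groups
        self._vel = [[np.zeros_like(p.data) for p in g["params"]] for g in groups]

    def step(self):
        for g, vels in zip(self.groups, self._vel):
            lr = g["lr"]
            mom = g.get("momentum", 0.0)
            wd = g.get("weight_decay", 0.0)
            for p, v in zip(g["params"], vels):
                if p.grad is None:
                    continue
                d = p.grad
                if wd:
                    d = d + wd * p.data
                v *= mom
                v += d
                p.data -= lr * v

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None
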