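"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Just enough machinery for a two-scale convolutional detector: convolution via
im2col, batch normalization, max-pooling, nearest upsampling, attention
gates, and the pointwise functions the YOLO loss needs.  Written for clarity
and testability (every op is finite-difference checked in the suite), not
for large-scale throughput; desk-scale networks train in seconds.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Float dtype of every tensor; float32 for speed, switchable to float64 for
#: finite-difference gradient checks.
DTYPE = np.float32


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor, seed grad 1."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        if not self.requires_grad:
            return
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> np.ndarray:
        return self.data.copy()

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return _wire(out, bw)

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        return _wire(out, lambda g: _accum(self, -g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return _wire(out, bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g / other.data, self.data.shape))
            _accum(
                other,
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return _wire(out, bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))
        return _wire(
            out, lambda g: _accum(self, g * exponent * self.data ** (exponent - 1))
        )

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            _accum(self, g @ other.data.swapaxes(-1, -2))
            _accum(other, self.data.swapaxes(-1, -2) @ g)

        return _wire(out, bw)

    # -- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        return _wire(out, lambda g: _accum(self, g.reshape(self.data.shape)))

    def transpose(self, *axes):
        out = _node(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)
        return _wire(out, lambda g: _accum(self, g.transpose(*inv)))

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bw(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                _accum_raw(self, buf)

        return _wire(out, bw)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.data.shape))

        return _wire(out, bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == data
        mask = mask / mask.sum(axis=axis, keepdims=True)
        out = _node(data if keepdims else np.squeeze(data, axis=axis), (self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, g * mask)

        return _wire(out, bw)


def _node(data, parents) -> Tensor:
    return Tensor(
        data,
        requires_grad=any(p.requires_grad for p in parents),
        parents=tuple(p for p in parents if p.requires_grad),
    )


def _wire(out: Tensor, bw) -> Tensor:
    if out.requires_grad:
        out._backward = bw
    return out


def _accum(t: Tensor, g) -> None:
    if t.requires_grad:
        _accum_raw(t, g)


def _accum_raw(t: Tensor, g) -> None:
    t.grad = g.astype(DTYPE) if t.grad is None else t.grad + g.astype(DTYPE)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Pointwise functions
# ---------------------------------------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(s, (x,))
    return _wire(out, lambda g: _accum(x, g * s * (1.0 - s)))


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = _node(e, (x,))
    return _wire(out, lambda g: _accum(x, g * e))


def log(x: Tensor) -> Tensor:
    out = _node(np.log(x.data), (x,))
    return _wire(out, lambda g: _accum(x, g / x.data))


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)
    out = _node(r, (x,))
    return _wire(out, lambda g: _accum(x, g * 0.5 / np.maximum(r, 1e-12)))


def atan(x: Tensor) -> Tensor:
    out = _node(np.arctan(x.data), (x,))
    return _wire(out, lambda g: _accum(x, g / (1.0 + x.data**2)))


def softplus(x: Tensor) -> Tensor:
    """log(1+exp(x)), computed stably; gradient is sigmoid(x)."""
    d = np.logaddexp(0.0, x.data)
    out = _node(d, (x,))
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _wire(out, lambda g: _accum(x, g * s))


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    factor = np.where(x.data > 0, 1.0, slope).astype(np.float32)
    out = _node(x.data * factor, (x,))
    return _wire(out, lambda g: _accum(x, g * factor))


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float32)
    out = _node(x.data * mask, (x,))
    return _wire(out, lambda g: _accum(x, g * mask))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only where the value was inside the range."""
    mask = ((x.data >= lo) & (x.data <= hi)).astype(np.float32)
    out = _node(np.clip(x.data, lo, hi), (x,))
    return _wire(out, lambda g: _accum(x, g * mask))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            _accum(t, g[tuple(sl)])

    return _wire(out, bw)


# ---------------------------------------------------------------------------
# Spatial ops (NCHW)
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation with im2col; padding is zero-padding."""
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, width = xd.shape
    o, _, k, _ = w.data.shape
    ho = (h - k) // stride + 1
    wo = (width - k) // stride + 1
    win = sliding_window_view(xd, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    out_mat = cols @ w.data.reshape(o, -1).T
    out_data = out_mat.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())
    out = _node(out_data, parents)

    def bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        if w.requires_grad:
            _accum_raw(w, (g2.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum_raw(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (g2 @ w.data.reshape(o, -1)).reshape(n, ho, wo, c, k, k)
            dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # n,c,ho,wo,k,k
            dx = np.zeros_like(xd)
            for i in range(k):
                for j in range(k):
                    dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += dcols[
                        :, :, :, :, i, j
                    ]
            if pad:
                dx = dx[:, :, pad:-pad, pad:-pad]
            _accum_raw(x, dx)

    return _wire(out, bw)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (even spatial dims required)."""
    n, c, h, w = x.data.shape
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = r.max(axis=(3, 5))
    mask = r == out_data[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    out = _node(out_data, (x,))

    def bw(g):
        _accum(x, (mask * g[:, :, :, None, :, None]).reshape(n, c, h, w))

    return _wire(out, bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = _node(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), (x,))
    n, c, h, w = x.data.shape

    def bw(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _wire(out, bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy: softplus(x) - t*x (any t in [0,1])."""
    return softplus(logits) - logits * np.asarray(targets, dtype=np.float32)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Minimal parameter container with train/eval modes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            if hasattr(m, "training"):
                m.training = flag

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        """Flat name -> array mapping, including batch-norm running stats."""
        out = {}

        def walk(mod: Module, prefix: str) -> None:
            for name, value in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor):
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict) -> None:
        def walk(mod: Module, prefix: str) -> None:
            for name, value in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and key in state:
                    value.data = np.asarray(state[key], dtype=np.float32)
                elif isinstance(value, np.ndarray) and key in state:
                    setattr(mod, name, np.asarray(state[key], dtype=value.dtype))
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean
                + (1 - self.momentum) * mu.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var
                + (1 - self.momentum) * var.data.ravel()
            )
            xhat = centered * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xhat = (x - mu) * (1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, scale, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Adam:
    """Adam with decoupled schedule: the learning rate is set per step."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        if lr is not None:
            self.lr = lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
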