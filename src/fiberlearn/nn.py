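"""A compact reverse-mode autodiff engine and neural-network layers on numpy.

Supports exactly what the multi-task fiber models need: dense and strided
convolutional layers (2D for slice representations, 3D for volumes), ReLU,
global average pooling, concatenation of a tabular prior branch, masked
uncertainty-weighted losses with learnable log-variances, and SGD/Adam with
global-norm gradient clipping. Everything is float64 and fully deterministic
for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A numpy array with reverse-mode gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # --- operator plumbing -------------------------------------------------

    def __add__(self, other):
        return _binop(self, _wrap(other), lambda a, b: a + b,
                      lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, _wrap(other), lambda a, b: a - b,
                      lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _wrap(other).__sub__(self)

    def __mul__(self, other):
        return _binop(self, _wrap(other), lambda a, b: a * b,
                      lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(self, _wrap(other), lambda a, b: a / b,
                      lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return _wrap(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad)
        out._parents = (self,)

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._parents = (self,)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        out._parents = (self,)

        def bwd(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self):
        return _unop(self, lambda a: np.maximum(a, 0.0), lambda g, a: g * (a > 0))

    def exp(self):
        out_val = np.exp(self.data)
        return _unop(self, lambda a: out_val, lambda g, a: g * out_val)

    def log(self):
        return _unop(self, np.log, lambda g, a: g / a)

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return _unop(self, lambda a: val, lambda g, a: g * val * (1 - val))

    def softplus(self):
        """log(1 + exp(x)), numerically stable."""
        a = self.data
        val = np.maximum(a, 0) + np.log1p(np.exp(-np.abs(a)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500)))
        return _unop(self, lambda _: val, lambda g, _: g * sig)

    def __pow__(self, p: float):
        return _unop(self, lambda a: a ** p, lambda g, a: g * p * a ** (p - 1))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape it was broadcast from."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _unop(x: Tensor, fwd, bwd) -> Tensor:
    out = Tensor(fwd(x.data), x.requires_grad)
    out._parents = (x,)

    def backward(g):
        if x.requires_grad:
            x._accumulate(bwd(g, x.data))

    out._backward = backward
    return out


def _binop(a: Tensor, b: Tensor, fwd, bwd_a, bwd_b) -> Tensor:
    out = Tensor(fwd(a.data, b.data), a.requires_grad or b.requires_grad)
    out._parents = (a, b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(bwd_a(g, a.data, b.data))
        if b.requires_grad:
            b._accumulate(bwd_b(g, a.data, b.data))

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


# --------------------------------------------------------------------------
# convolution (nD via im2col on sliding windows)
# --------------------------------------------------------------------------


def _convnd(x: Tensor, w: Tensor, b: Tensor | None, stride: int, pad: int,
            nd: int) -> Tensor:
    """Strided nD cross-correlation. x: (N, C, *spatial), w: (F, C, *k)."""
    ksize = w.data.shape[2:]
    xp = np.pad(x.data, [(0, 0), (0, 0)] + [(pad, pad)] * nd)
    win = sliding_window_view(xp, ksize, axis=tuple(range(2, 2 + nd)))
    slicer = (slice(None), slice(None)) + (slice(None, None, stride),) * nd
    win = win[slicer]  # (N, C, *out_spatial, *k)
    n_spatial = win.ndim - 2 - nd
    # flatten: (N, out..., C*prod(k)) @ (C*prod(k), F)
    win_m = np.moveaxis(win, 1, 1 + n_spatial)  # (N, *out, C, *k)
    lead = win_m.shape[: 1 + n_spatial]
    win_flat = win_m.reshape(*lead, -1)
    w_flat = w.data.reshape(w.data.shape[0], -1)
    out_val = win_flat @ w_flat.T  # (N, *out, F)
    out_val = np.moveaxis(out_val, -1, 1)  # (N, F, *out)
    if b is not None:
        out_val = out_val + b.data.reshape((1, -1) + (1,) * nd)

    out = Tensor(out_val, x.requires_grad or w.requires_grad
                 or (b is not None and b.requires_grad))
    out._parents = tuple(t for t in (x, w, b) if t is not None)

    def bwd(g):
        g_m = np.moveaxis(g, 1, -1)  # (N, *out, F)
        if w.requires_grad:
            gw = np.tensordot(g_m.reshape(-1, g_m.shape[-1]).T,
                              win_flat.reshape(-1, win_flat.shape[-1]), axes=1)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        if x.requires_grad:
            gx_pad = np.zeros_like(xp)
            out_spatial = g.shape[2:]
            # scatter per kernel offset (kernel volumes are small)
            for off in np.ndindex(*ksize):
                # contribution to x at position stride*o + off
                contrib = np.einsum("f c, n f ... -> n c ...",
                                    w.data[(slice(None), slice(None)) + off], g)
                sl = tuple(slice(o, o + stride * s, stride)
                           for o, s in zip(off, out_spatial))
                gx_pad[(slice(None), slice(None)) + sl] += contrib
            if pad:
                sl = (slice(None), slice(None)) + (slice(pad, -pad),) * nd
                x._accumulate(gx_pad[sl])
            else:
                x._accumulate(gx_pad)

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 1) -> Tensor:
    return _convnd(x, w, b, stride, pad, nd=2)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 1) -> Tensor:
    return _convnd(x, w, b, stride, pad, nd=3)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, *spatial) -> (N, C)."""
    axes = tuple(range(2, x.data.ndim))
    out = Tensor(x.data.mean(axis=axes), x.requires_grad)
    out._parents = (x,)
    n = float(np.prod([x.data.shape[a] for a in axes]))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(
                g.reshape(g.shape + (1,) * len(axes)), x.data.shape) / n)

    out._backward = bwd
    return out


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class ConvBlock(Module):
    """Conv (stride 2 downsampling) + ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 nd: int = 2, kernel: int = 3, stride: int = 2):
        fan_in = c_in * kernel ** nd
        scale = math.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0, scale, (c_out, c_in) + (kernel,) * nd),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.nd = nd

    def __call__(self, x: Tensor) -> Tensor:
        return _convnd(x, self.w, self.b, self.stride, pad=1, nd=self.nd).relu()


class Optimizer:
    def __init__(self, params: list[Tensor]):
        self.params = params

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def clip_global_norm(self, max_norm: float) -> float:
        total = math.sqrt(sum(float((p.grad ** 2).sum())
                              for p in self.params if p.grad is not None))
        if total > max_norm > 0:
            scale = max_norm / (total + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return total

    def step(self) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.9):
        super().__init__(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
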