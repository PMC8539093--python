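"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical engine behind the registration and similarity
networks.  It implements exactly the operator set those models need — dense
and 3x3 convolutional layers, 2x2 max-pooling and nearest-neighbour
upsampling, element-wise nonlinearities, reductions, and a differentiable
bilinear sampler — together with SGD and Adam optimisers.  All arithmetic is
float32; gradients are checked against finite differences in the test suite.

Conventions: image tensors are (N, C, H, W); the bilinear sampler takes
absolute (row, col) sample positions and reads zero outside the frame.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "dense",
    "maxpool2",
    "upsample2",
    "bilinear_sample",
    "SGD",
    "Adam",
    "he_init",
    "glorot_init",
]


def _as_f32(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- shape / info ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data**p

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(out_data, (a,), backward)

    # -- element-wise functions -------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), backward)

    def abs(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))

        return Tensor._make(np.abs(a.data), (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def leaky_relu(self, alpha: float = 0.2):
        a = self
        factor = np.where(a.data > 0, np.float32(1.0), np.float32(alpha))

        def backward(g):
            if a.requires_grad:
                a._accum(g * factor)

        return Tensor._make(a.data * factor, (a,), backward)

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(ax % a.data.ndim for ax in axes):
                    gg = np.expand_dims(gg, ax)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(*inv))

        return Tensor._make(a.data.transpose(*axes), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(a.data[idx], (a,), backward)

    def matmul(self, other: "Tensor"):
        a, b = self, self._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul


# ---------------------------------------------------------------------------
# composite / structured ops
# ---------------------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 1) -> Tensor:
    """3x3 (or any kxk) convolution, NCHW layout, zero padding.

    Implemented as k*k shifted tensor contractions so the heavy lifting is
    BLAS matrix products.
    """
    N, C, H, W = x.data.shape
    K, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((K, N, Ho, Wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
            out += np.tensordot(w.data[:, :, i, j], patch, axes=([1], [1]))
    out = np.ascontiguousarray(out.transpose(1, 0, 2, 3))
    if b is not None:
        out += b.data.reshape(1, K, 1, 1)

    def backward(g):
        # g: (N, K, Ho, Wo)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
                if w.requires_grad:
                    dw[:, :, i, j] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
                if x.requires_grad:
                    dpatch = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0]))
                    dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += (
                        dpatch.transpose(0, 3, 1, 2)
                    )
        if w.requires_grad:
            w._accum(dw)
        if x.requires_grad:
            if padding:
                x._accum(dxp[:, :, padding:-padding, padding:-padding])
            else:
                x._accum(dxp)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def dense(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = x @ w
    if b is not None:
        out = out + b
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (even H, W required)."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(N, C, H, W))

    return Tensor._make(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    N, C, H, W = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def bilinear_sample(img: Tensor, coords: Tensor) -> Tensor:
    """Sample `img` (N,C,H,W) at absolute positions `coords` (N,2,H',W').

    coords[:, 0] are row positions, coords[:, 1] column positions, in pixels.
    Positions outside the frame read zero.  Differentiable in both arguments.
    """
    N, C, H, W = img.data.shape
    r = coords.data[:, 0]
    c = coords.data[:, 1]
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    fr = (r - r0).astype(np.float32)
    fc = (c - c0).astype(np.float32)

    nn = np.arange(N)[:, None, None]
    corners = []  # (value (N,C,h,w), weight (N,h,w), valid, ri_clip, ci_clip)
    for dr, wr in ((0, 1.0 - fr), (1, fr)):
        for dc, wc in ((0, 1.0 - fc), (1, fc)):
            ri, ci = r0 + dr, c0 + dc
            valid = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
            ric = np.clip(ri, 0, H - 1)
            cic = np.clip(ci, 0, W - 1)
            val = img.data[nn, :, ric, cic].transpose(0, 3, 1, 2)
            val = val * valid[:, None].astype(np.float32)
            corners.append((val, (wr * wc).astype(np.float32), valid, ric, cic))
    out = sum(val * w[:, None] for val, w, *_ in corners)

    def backward(g):
        if img.requires_grad:
            dimg = np.zeros_like(img.data)
            for val, w, valid, ric, cic in corners:
                contrib = (g * w[:, None] * valid[:, None]).transpose(0, 2, 3, 1)
                np.add.at(dimg, (nn, slice(None), ric, cic), contrib)
            img._accum(dimg)
        if coords.requires_grad:
            (v00, _, _, _, _), (v01, _, _, _, _), (v10, _, _, _, _), (v11, _, _, _, _) = corners
            gchan = g
            d_r = ((v10 - v00) * (1.0 - fc)[:, None] + (v11 - v01) * fc[:, None])
            d_c = ((v01 - v00) * (1.0 - fr)[:, None] + (v11 - v10) * fr[:, None])
            gr = (gchan * d_r).sum(axis=1)
            gc = (gchan * d_c).sum(axis=1)
            coords._accum(np.stack([gr, gc], axis=1))

    return Tensor._make(out, (img, coords), backward)


# ---------------------------------------------------------------------------
# initialisers and optimisers
# ---------------------------------------------------------------------------


def he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def glorot_init(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 0.01, momentum: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        bc1 = 1.0 - self.b1**self._t
        bc2 = 1.0 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
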