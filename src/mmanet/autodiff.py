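"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the segmentation network needs: broadcasted
arithmetic, reductions, elementwise nonlinearities, channel concatenation,
same-padded stride-1 convolution (im2col), 2x2 max pooling, factor-2 bilinear
upsampling, and batch normalization.  Tensors form a tape (DAG) and
``Tensor.backward`` runs reverse accumulation in topological order.

Dtypes are preserved: feed float64 arrays and every gradient is float64 (the
finite-difference tests rely on this); the network itself runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "maxpool2x",
    "upsample2x",
    "batch_norm",
]


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, g))
        self.grad += g

    def backward(self, grad=None):
        """Reverse-accumulate gradients from this tensor through the tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, _add_back)

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = _make(-a.data, (a,))
        if out._parents:
            out._backward = lambda g: a._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        return _binary(self, other, np.multiply, _mul_back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide, _div_back)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        out = _make(a.data ** exponent, (a,))
        if out._parents:
            out._backward = lambda g: a._accumulate(
                g * exponent * a.data ** (exponent - 1)
            )
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = _make(a.data.sum(axis=axis, keepdims=keepdims), (a,))
        if out._parents:
            def back(g):
                gg = g
                if not keepdims and axis is not None:
                    gg = np.expand_dims(gg, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())
            out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ------------------------------------
    def relu(self):
        a = self
        out = _make(np.maximum(a.data, 0), (a,))
        if out._parents:
            mask = a.data > 0
            out._backward = lambda g: a._accumulate(g * mask)
        return out

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        out = _make(s, (a,))
        if out._parents:
            out._backward = lambda g: a._accumulate(g * s * (1.0 - s))
        return out

    def log(self):
        a = self
        out = _make(np.log(a.data), (a,))
        if out._parents:
            out._backward = lambda g: a._accumulate(g / a.data)
        return out

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only through the unclipped region."""
        a = self
        out = _make(np.clip(a.data, lo, hi), (a,))
        if out._parents:
            mask = (a.data >= lo) & (a.data <= hi)
            out._backward = lambda g: a._accumulate(g * mask)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    """Create an output tensor; keep the tape only if a parent needs grad."""
    out = Tensor(data)
    tracked = tuple(p for p in parents if p.requires_grad or p._parents)
    if tracked:
        out._parents = tracked
    return out


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a, b, fwd, back_maker):
    a, b = as_tensor(a), as_tensor(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out._parents:
        out._backward = back_maker(a, b)
    return out


def _add_back(a, b):
    def back(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))
    return back


def _mul_back(a, b):
    def back(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))
    return back


def _div_back(a, b):
    def back(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
    return back


# ---------------------------------------------------------------------------
# Structural ops
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel axis by default)."""
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accumulate(piece)

        out._backward = back
    return out


# ---------------------------------------------------------------------------
# Convolution (stride 1, 'same' zero padding) via im2col
# ---------------------------------------------------------------------------

def _im2col(x, k, pad):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (N, C, H, W, k, k) -> (C*k*k, N*H*W)
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * h * w)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2D convolution, stride 1, zero padding k//2 (output side = input side).

    ``x``: (N, C, H, W); ``w``: (O, C, k, k); ``b``: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    o, ci, k, k2 = w.data.shape
    if ci != c or k != k2:
        raise ValueError(f"weight shape {w.data.shape} incompatible with input {x.data.shape}")
    pad = k // 2
    cols = _im2col(x.data, k, pad)
    wm = w.data.reshape(o, c * k * k)
    out_data = (wm @ cols).reshape(o, n, h, wd).transpose(1, 0, 2, 3)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out._parents:
        def back(g):
            g2 = g.transpose(1, 0, 2, 3).reshape(o, n * h * wd)
            if b is not None and (b.requires_grad or b._parents):
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad or w._parents:
                w._accumulate((g2 @ cols.T).reshape(w.data.shape))
            if x.requires_grad or x._parents:
                dcols = (wm.T @ g2).reshape(c, k, k, n, h, wd)
                dxp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad), dtype=g.dtype)
                for ki in range(k):
                    for kj in range(k):
                        dxp[:, :, ki:ki + h, kj:kj + wd] += dcols[:, ki, kj].transpose(1, 0, 2, 3)
                if pad:
                    dxp = dxp[:, :, pad:-pad, pad:-pad]
                x._accumulate(dxp)

        out._backward = back
    return out


# ---------------------------------------------------------------------------
# 2x2 max pooling, stride 2
# ---------------------------------------------------------------------------

def maxpool2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x needs even spatial sides, got {h}x{w}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = _make(out_data, (x,))
    if out._parents:
        def back(g):
            dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
            dx = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(dx.reshape(n, c, h, w))

        out._backward = back
    return out


# ---------------------------------------------------------------------------
# Factor-2 bilinear upsampling (separable; edge-replicated half-pixel grid)
# ---------------------------------------------------------------------------

def _up_last(a):
    left = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    right = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    out = np.empty(a.shape[:-1] + (2 * a.shape[-1],), dtype=a.dtype)
    out[..., 0::2] = 0.75 * a + 0.25 * left
    out[..., 1::2] = 0.75 * a + 0.25 * right
    return out


def _down_last(g):
    ge = g[..., 0::2]
    go = g[..., 1::2]
    da = 0.75 * (ge + go)
    da[..., :-1] += 0.25 * ge[..., 1:]
    da[..., 0] += 0.25 * ge[..., 0]
    da[..., 1:] += 0.25 * go[..., :-1]
    da[..., -1] += 0.25 * go[..., -1]
    return da


def upsample2x(x: Tensor) -> Tensor:
    """Double both spatial sides by bilinear interpolation; channels unchanged.

    A constant map upsamples to the same constant (interpolation weights sum
    to 1), and values stay within the input's range (convex combinations).
    """
    x = as_tensor(x)
    out_data = _up_last(_up_last(x.data).swapaxes(-1, -2)).swapaxes(-1, -2)
    out = _make(out_data, (x,))
    if out._parents:
        def back(g):
            x._accumulate(_down_last(_down_last(g.swapaxes(-1, -2)).swapaxes(-1, -2)))

        out._backward = back
    return out


# ---------------------------------------------------------------------------
# Batch normalization (per-channel over N, H, W)
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """BN over the channel axis of an (N, C, H, W) tensor.

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = _make(out_data.astype(x.data.dtype, copy=False), (x, gamma, beta))
    if out._parents:
        def back(g):
            if beta.requires_grad or beta._parents:
                beta._accumulate(g.sum(axis=axes))
            if gamma.requires_grad or gamma._parents:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if x.requires_grad or x._parents:
                scale = (gamma.data * inv)[None, :, None, None]
                if training:
                    gm = g.mean(axis=axes, keepdims=True)
                    gxm = (g * xhat).mean(axis=axes, keepdims=True)
                    x._accumulate(scale * (g - gm - xhat * gxm))
                else:
                    x._accumulate(scale * g)

        out._backward = back
    return out
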