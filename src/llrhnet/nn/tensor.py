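"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order.  Only the operations the segmentation network needs are
provided, each with a hand-written vector-Jacobian product.  Convolution is
lowered to a single BLAS matmul per layer via im2col, which is what makes
CPU training of the full network practical.

Gradient tracking can be suspended with :func:`no_grad` (used for
inference), which also skips building the tape.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def _accum_owned(self, g):
        """Accumulate a freshly allocated gradient without copying it."""
        if self.grad is None and g.dtype == self.data.dtype:
            self.grad = g
        else:
            self._accum(g)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed: ones)."""
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _astensor(other, self.dtype)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_astensor(other, self.dtype))

    def __rsub__(self, other):
        return _astensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _astensor(other, self.dtype)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _astensor(other, self.dtype)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _astensor(other, self.dtype)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(np.ascontiguousarray(self.data.reshape(shape)), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(np.ascontiguousarray(self.data.transpose(axes)), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                ge = np.expand_dims(g, axis) if not keepdims else g
                self._accum(np.broadcast_to(ge, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum_owned(g * mask)

        return Tensor._make(np.where(mask, self.data, 0), (self,), backward)

    def gelu(self):
        """Exact GELU: x * Phi(x) with Phi the standard normal CDF."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))

        def backward(g):
            if self.requires_grad:
                pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
                self._accum(g * (phi + x * pdf).astype(x.dtype))

        return Tensor._make((x * phi).astype(x.dtype), (self,), backward)

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

        return Tensor._make(y, (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis (with gradient splitting)."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    edges = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, edges, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def _astensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


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
    return grad


# ---------------------------------------------------------------------------
# Convolution (im2col) and spatial resampling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(B,C,Hp,Wp) padded input -> contiguous (B, C*kh*kw, ho*wo) columns.

    Built by kh*kw strided slice copies (fast memcpy paths) rather than one
    gather over a 6D strided view, which is an order of magnitude slower.
    """
    b, c, _, _ = xp.shape
    cols = np.empty((b, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        hi = i + stride * ho
        for j in range(kw):
            wj = j + stride * wo
            cols[:, :, i, j] = xp[:, :, i:hi:stride, j:wj:stride]
    return cols.reshape(b, c * kh * kw, ho * wo)


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo) -> np.ndarray:
    """Scatter-add column gradients back to the (unpadded) input."""
    b, c, h, w = x_shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        hi = i + stride * ho
        for j in range(kw):
            wj = j + stride * wo
            dxp[:, :, i:hi:stride, j:wj:stride] += d6[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2D cross-correlation. x:(B,C,H,W), weight:(O,C,kh,kw), bias:(O,)."""
    b, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {ci}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    pointwise = kh == 1 and kw == 1 and padding == 0
    if pointwise:
        xs = x.data[:, :, ::stride, ::stride] if stride != 1 else x.data
        cols = np.ascontiguousarray(xs).reshape(b, c, ho * wo)
    else:
        if padding:
            xp = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=x.data.dtype)
            xp[:, :, padding:padding + h, padding:padding + w] = x.data
        else:
            xp = x.data
        cols = _im2col(xp, kh, kw, stride, ho, wo)      # (B, CK, Q)
    w2 = weight.data.reshape(o, c * kh * kw)            # (O, CK)
    out = np.matmul(w2, cols)                           # (B, O, Q)
    if bias is not None:
        out += bias.data[None, :, None]
    out = out.reshape(b, o, ho, wo)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = np.ascontiguousarray(g.reshape(b, o, ho * wo))
        if weight.requires_grad:
            # batched gemm with implicit transB, summed over the batch
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)                 # (B, CK, Q)
            if pointwise and stride == 1:
                x._accum_owned(dcols.reshape(b, c, h, w))
            elif pointwise:
                dx = np.zeros((b, c, h, w), dtype=dcols.dtype)
                dx[:, :, ::stride, ::stride] = dcols.reshape(b, c, ho, wo)
                x._accum_owned(dx)
            else:
                x._accum_owned(_col2im(dcols, (b, c, h, w), kh, kw, stride,
                                       padding, ho, wo))

    return Tensor._make(out, parents, backward)


@lru_cache(maxsize=128)
def _interp_matrix(n_in: int, n_out: int, dtype_str: str) -> np.ndarray:
    """Row-stochastic 1D linear-interpolation matrix (align_corners=False)."""
    a = np.zeros((n_out, n_in), dtype=np.dtype(dtype_str))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


def interpolate_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of (B,C,H,W) to (B,C,*size) as two 1D interpolations."""
    _, _, h, w = x.data.shape
    ho, wo = size
    if (ho, wo) == (h, w):
        return x
    ah = _interp_matrix(h, ho, x.data.dtype.str)
    aw = _interp_matrix(w, wo, x.data.dtype.str)
    out = np.matmul(np.matmul(ah, x.data), aw.T)

    def backward(g):
        if x.requires_grad:
            x._accum(np.matmul(np.matmul(ah.T, g), aw))

    return Tensor._make(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    _, _, h, w = x.data.shape
    return interpolate_bilinear(x, (2 * h, 2 * w))


# ---------------------------------------------------------------------------
# Normalisation layers (functional forms)
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
               var: np.ndarray, eps: float) -> Tensor:
    """Normalise (B,C,H,W) per channel with the given statistics.

    In training mode callers pass batch statistics (and the backward pass
    differentiates through them); in eval mode they pass running statistics,
    which the backward pass then treats as constants — handled by the
    `stats_are_batch` flag on :func:`batch_norm_train`.
    """
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum_owned(g * (gamma.data * inv)[None, :, None, None])

    return Tensor._make(out.astype(x.data.dtype), (x, gamma, beta), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float,
                     stats: tuple[np.ndarray, np.ndarray] | None = None) -> Tensor:
    """Batch normalisation using (and differentiating through) batch stats.

    ``stats`` lets the caller pass precomputed (mean, var) so the running-
    statistics update does not recompute them.
    """
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    if stats is None:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
    else:
        mean, var = stats
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data[None, :, None, None]
            s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (gxhat - s1 / n - xhat * s2 / n) * inv[None, :, None, None]
            x._accum_owned(dx.astype(x.data.dtype, copy=False))

    return Tensor._make(out.astype(x.data.dtype), (x, gamma, beta), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    """Layer normalisation over the last axis of x."""
    d = x.data.shape[-1]
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, d).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, d).sum(axis=0))
        if x.requires_grad:
            gxhat = g * gamma.data
            s1 = gxhat.mean(axis=-1, keepdims=True)
            s2 = (gxhat * xhat).mean(axis=-1, keepdims=True)
            x._accum_owned(((gxhat - s1 - xhat * s2) * inv).astype(x.data.dtype, copy=False))

    return Tensor._make(out.astype(x.data.dtype), (x, gamma, beta), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    u = rng.random(x.data.shape, dtype=np.float32)
    mask = (u < keep).astype(x.data.dtype)
    mask /= keep

    def backward(g):
        if x.requires_grad:
            x._accum_owned(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)
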