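"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape: every operation returns a new :class:`Tensor`
holding a closure that propagates the output gradient to its parents.
``backward()`` runs a topological sweep.  All arithmetic is float32.

Only the primitives needed by the segmentation network live here; the
convolution primitives are written so that the heavy lifting stays inside
BLAS (1x1 convolutions as batched matmuls, k x k depth-wise convolutions as
k^2 shifted fused multiply-adds, general convolutions via im2col).
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True
_DTYPE = np.dtype(np.float32)


def set_default_dtype(dtype):
    """Set the array dtype used by the tape (float32 for speed; float64 is
    useful when verifying gradients against numerical differentiation)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype)


def get_default_dtype():
    return _DTYPE


@contextlib.contextmanager
def autodiff_dtype(dtype):
    prev = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != _DTYPE:
        a = a.astype(_DTYPE)
    return a


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_gb")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._gb = False  # grad buffer is borrowed (not safe to mutate)

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
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
        self.grad = _f32(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / float(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    """Accumulate a gradient contribution without copying: the first
    contribution is borrowed by reference and never mutated in place."""
    if not t.requires_grad:
        return
    g = _f32(g)
    if t.grad is None:
        t.grad = g
        t._gb = True
    elif t._gb:
        t.grad = t.grad + g
        t._gb = False
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    if not isinstance(b, Tensor) and np.isscalar(b):
        a = as_tensor(a)
        s = float(b)

        def backward_s(g):
            _accum(a, g * s)

        return _make(a.data * np.float32(s), (a,), backward_s)
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def power(a, p: float):
    a = as_tensor(a)
    p = float(p)
    out_data = a.data ** np.float32(p)

    def backward(g):
        _accum(a, g * p * a.data ** np.float32(p - 1.0))

    return _make(out_data, (a,), backward)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)

    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def clip(a, lo: float, hi: float):
    """Clamp; gradient passes only where the input is inside the interval."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = ((a.data > lo) & (a.data < hi)).astype(np.float32)

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


def relu(a):
    a = as_tensor(a)
    mask = (a.data > 0).astype(np.float32)

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def swish(a):
    """x * sigmoid(x) (SiLU)."""
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return _make(out_data, (a,), backward)


def softmax_channels(a):
    """Softmax over axis 1 of an NCHW tensor."""
    a = as_tensor(a)
    z = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=1, keepdims=True)
        _accum(a, out_data * (g - dot))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    old = a.shape

    def backward(g):
        _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def mean_hw(a):
    """Global average pool over the two trailing spatial axes (keepdims)."""
    a = as_tensor(a)
    n, c, h, w = a.shape
    out_data = a.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        _accum(a, np.broadcast_to(g / (h * w), a.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# linear-algebra / convolution primitives
# ---------------------------------------------------------------------------

def linear(x, w, b=None):
    """x (N, F) @ w.T (F, O) + b."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = x.data @ w.data.T
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data

    def backward(g):
        _accum(x, g @ w.data)
        _accum(w, g.T @ x.data)
        if b is not None:
            _accum(b, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def conv1x1(x, w, b=None):
    """Point-wise convolution.  x: (N,C,H,W), w: (O,C), b: (O,) or None."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    xr = x.data.reshape(n, c, h * wd)
    out = np.matmul(w.data, xr)                       # (N, O, HW)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :, None]
    out = out.reshape(n, w.shape[0], h, wd)

    def backward(g):
        gr = g.reshape(n, w.shape[0], h * wd)
        _accum(x, np.matmul(w.data.T, gr).reshape(x.shape))
        _accum(w, np.einsum("nop,ncp->oc", gr, xr, optimize=True))
        if b is not None:
            _accum(b, gr.sum(axis=(0, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def depthwise_conv(x, w, stride: int = 1, padding: int | None = None):
    """Depth-wise convolution.  x: (N,C,H,W), w: (C,k,k); 'same' padding by default."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    k = w.shape[1]
    pad = (k - 1) // 2 if padding is None else padding
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
    tmp = np.empty_like(out)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride]
            np.multiply(w.data[:, i, j][None, :, None, None], patch, out=tmp)
            out += tmp

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        buf = np.empty_like(g)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride]
                dw[:, i, j] = np.einsum("nchw,nchw->c", g, patch, optimize=True)
                np.multiply(w.data[:, i, j][None, :, None, None], g, out=buf)
                dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += buf
        _accum(w, dw)
        if pad:
            _accum(x, dxp[:, :, pad:pad + h, pad:pad + wd])
        else:
            _accum(x, dxp)

    return _make(out, (x, w), backward)


def _im2col(xp, k, stride, ho, wo):
    n, c = xp.shape[:2]
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, k, k, ho, wo),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    return np.ascontiguousarray(win.transpose(0, 4, 5, 1, 2, 3)).reshape(n * ho * wo, c * k * k)


def conv2d(x, w, stride: int = 1, padding: int | None = None, b=None):
    """General convolution via im2col.  x: (N,C,H,W), w: (O,C,k,k)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    pad = (k - 1) // 2 if padding is None else padding
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, k, stride, ho, wo)             # (N*ho*wo, C*k*k)
    wmat = w.data.reshape(o, -1)
    out = cols @ wmat.T
    if b is not None:
        b = as_tensor(b)
        out = out + b.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(g):
        gcols = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        _accum(w, (gcols.T @ cols).reshape(w.shape))
        if b is not None:
            _accum(b, gcols.sum(axis=0))
        dcols = (gcols @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2))
        if pad:
            _accum(x, dxp[:, :, pad:pad + h, pad:pad + wd])
        else:
            _accum(x, dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def batch_norm_train(x, gamma, beta, eps: float = 1e-5):
    """Batch normalization over (N,H,W) per channel, training statistics.

    Returns (out, batch_mean, batch_var) with the usual BN vjp.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    m = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - m
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = xc
    xhat *= invstd
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    cnt = x.data.size // x.shape[1]

    def backward(g):
        _accum(beta, g.sum(axis=axes))
        _accum(gamma, (g * xhat).sum(axis=axes))
        gs = g.sum(axis=axes, keepdims=True)
        gx = (g * xhat).sum(axis=axes, keepdims=True)
        dx = (gamma.data[None, :, None, None] * invstd / cnt) * (
            cnt * g - gs - xhat * gx)
        _accum(x, dx)

    return _make(out, (x, gamma, beta), backward), m.squeeze(), var.squeeze()


def affine_channels(x, scale: np.ndarray, shift: np.ndarray):
    """Per-channel affine with constant (non-learned) scale/shift.

    Used for batch-norm inference with running statistics folded into
    ``scale``/``shift``; gradients flow to ``x`` only.
    """
    x = as_tensor(x)
    out = x.data * scale[None, :, None, None] + shift[None, :, None, None]

    def backward(g):
        _accum(x, g * scale[None, :, None, None])

    return _make(out, (x,), backward)


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    key = (n_out, n_in)
    mat = _INTERP_CACHE.get(key)
    if mat is None:
        mat = np.zeros((n_out, n_in), dtype=np.float32)
        scale = n_in / n_out
        for i in range(n_out):
            src = (i + 0.5) * scale - 0.5
            lo = int(np.floor(src))
            t = src - lo
            lo_c = min(max(lo, 0), n_in - 1)
            hi_c = min(max(lo + 1, 0), n_in - 1)
            mat[i, lo_c] += 1.0 - t
            mat[i, hi_c] += t
        _INTERP_CACHE[key] = mat
    return mat


def upsample_bilinear(x, out_h: int, out_w: int):
    """Bilinear resize of an NCHW tensor to (out_h, out_w)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    ah = _interp_matrix(out_h, h)
    aw = _interp_matrix(out_w, w)
    tmp = np.einsum("oh,nchw->ncow", ah, x.data, optimize=True)
    out = np.einsum("pw,ncow->ncop", aw, tmp, optimize=True)

    def backward(g):
        t = np.einsum("pw,ncop->ncow", aw, g, optimize=True)
        _accum(x, np.einsum("oh,ncow->nchw", ah, t, optimize=True))

    return _make(out, (x,), backward)
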