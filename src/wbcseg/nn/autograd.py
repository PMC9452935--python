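"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the segmentation network needs:
elementwise arithmetic, ReLU/sigmoid/log/pow/clamp, reductions, channel
concatenation, 2-D convolution (stride/dilation/padding), 3x3 max pooling,
batch normalization, fully-connected layers, global average pooling and
exact 2x bilinear upsampling (half-pixel convention, corners not aligned).

All tensors are float32. Gradients are accumulated with ``Tensor.backward``
on a scalar; ``no_grad`` disables graph construction for inference.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables gradient-graph construction."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # defer mixed ndarray-Tensor arithmetic to the Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (≈300 ops)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def mean(self):
        return mean(self)

    def sum(self):
        return tsum(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*tensors: Tensor) -> bool:
    return _grad_enabled and any(t.requires_grad for t in tensors)


def _attach(out: Tensor, parents: tuple, backward) -> None:
    out.requires_grad = True
    out._parents = parents
    out._backward = backward


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data)
    if _track(a, b):
        def bw():
            _accum(a, _unbroadcast(out.grad, a.data.shape))
            _accum(b, _unbroadcast(out.grad, b.data.shape))
        _attach(out, (a, b), bw)
    return out


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data - b.data)
    if _track(a, b):
        def bw():
            _accum(a, _unbroadcast(out.grad, a.data.shape))
            _accum(b, _unbroadcast(-out.grad, b.data.shape))
        _attach(out, (a, b), bw)
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data)
    if _track(a, b):
        def bw():
            _accum(a, _unbroadcast(out.grad * b.data, a.data.shape))
            _accum(b, _unbroadcast(out.grad * a.data, b.data.shape))
        _attach(out, (a, b), bw)
    return out


def power(x, p: float) -> Tensor:
    x = as_tensor(x)
    p = float(p)
    out = Tensor(x.data ** p)
    if _track(x):
        def bw():
            _accum(x, out.grad * p * x.data ** (p - 1.0))
        _attach(out, (x,), bw)
    return out


def log(x) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data))
    if _track(x):
        def bw():
            _accum(x, out.grad / x.data)
        _attach(out, (x,), bw)
    return out


def clamp(x, lo: float, hi: float) -> Tensor:
    """Clip to [lo, hi]; gradient passes only through unclipped entries."""
    x = as_tensor(x)
    out = Tensor(np.clip(x.data, lo, hi))
    if _track(x):
        mask = (x.data >= lo) & (x.data <= hi)
        def bw():
            _accum(x, out.grad * mask)
        _attach(out, (x,), bw)
    return out


def relu(x) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0))
    if _track(x):
        mask = x.data > 0.0
        def bw():
            _accum(x, out.grad * mask)
        _attach(out, (x,), bw)
    return out


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic
    d = x.data
    s = np.empty_like(d)
    pos = d >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    s[~pos] = e / (1.0 + e)
    out = Tensor(s)
    if _track(x):
        def bw():
            _accum(x, out.grad * s * (1.0 - s))
        _attach(out, (x,), bw)
    return out


# ---------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------

def mean(x) -> Tensor:
    x = as_tensor(x)
    out = Tensor(x.data.mean())
    if _track(x):
        def bw():
            _accum(x, np.full_like(x.data, out.grad / x.data.size))
        _attach(out, (x,), bw)
    return out


def tsum(x) -> Tensor:
    x = as_tensor(x)
    out = Tensor(x.data.sum())
    if _track(x):
        def bw():
            _accum(x, np.full_like(x.data, out.grad))
        _attach(out, (x,), bw)
    return out


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    out = Tensor(x.data.reshape(shape))
    if _track(x):
        def bw():
            _accum(x, out.grad.reshape(x.data.shape))
        _attach(out, (x,), bw)
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _track(*tensors):
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def bw():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                _accum(t, out.grad[tuple(sl)])
        _attach(out, tuple(tensors), bw)
    return out


# ---------------------------------------------------------------------
# neural-network primitives
# ---------------------------------------------------------------------

def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=x.dtype)
    out[:, :, p:-p, p:-p] = x
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, d: int):
    """Channel-major column matrix (n, c*kh*kw, oh*ow)."""
    ekh, ekw = (kh - 1) * d + 1, (kw - 1) * d + 1
    win = sliding_window_view(xp, (ekh, ekw), axis=(2, 3))
    win = win[:, :, ::s, ::s, ::d, ::d]
    n, c, oh, ow = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _conv1x1(x, weight, bias, stride):
    """Fast path: a 1x1 convolution is a channel-mixing matmul."""
    xd = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    n, c, oh, ow = xd.shape
    o = weight.data.shape[0]
    wmat = weight.data.reshape(o, c)
    out_d = (wmat @ xd.reshape(n, c, oh * ow)).reshape(n, o, oh, ow)
    if bias is not None:
        out_d += bias.data[None, :, None, None]
    out = Tensor(out_d)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if _track(*parents):
        def bw():
            g = out.grad.reshape(n, o, oh * ow)
            if weight.requires_grad:
                xr = xd.reshape(n, c, oh * ow)
                dw_ = np.einsum("nop,ncp->oc", g, xr, optimize=True)
                _accum(weight, dw_.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                _accum(bias, out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxs = (wmat.T @ g).reshape(n, c, oh, ow)
                if stride > 1:
                    dx = np.zeros_like(x.data)
                    dx[:, :, ::stride, ::stride] = dxs
                else:
                    dx = dxs
                _accum(x, dx)
        _attach(out, parents, bw)
    return out


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding/dilation."""
    x, weight = as_tensor(x), as_tensor(weight)
    bias = as_tensor(bias) if bias is not None else None
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    if kh == 1 and kw == 1 and padding == 0:
        return _conv1x1(x, weight, bias, stride)
    xp = _pad2d(x.data, padding)
    cols, oh, ow = _im2col(xp, kh, kw, stride, dilation)
    wmat = weight.data.reshape(o, c * kh * kw)
    out_d = (wmat @ cols).reshape(n, o, oh, ow)
    if bias is not None:
        out_d += bias.data[None, :, None, None]
    out = Tensor(out_d)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if _track(*parents):
        def bw():
            g = out.grad.reshape(n, o, oh * ow)
            if weight.requires_grad:
                dw_ = np.einsum("nop,nkp->ok", g, cols, optimize=True)
                _accum(weight, dw_.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                _accum(bias, out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.matmul(wmat.T, g)                 # (n, k, p)
                d6 = dcols.reshape(n, c, kh, kw, oh, ow)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :,
                            i * dilation: i * dilation + stride * oh: stride,
                            j * dilation: j * dilation + stride * ow: stride] += d6[:, :, i, j]
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                _accum(x, dxp)
        _attach(out, parents, bw)
    return out


def max_pool2d(x, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    hp, wp = xp.shape[2:]
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, oh, ow, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0])
    if _track(x):
        def bw():
            ih, iw = arg // kernel, arg % kernel
            rows = np.arange(oh)[None, None, :, None] * stride + ih
            cls = np.arange(ow)[None, None, None, :] * stride + iw
            idx = rows * wp + cls
            dxp = np.zeros((n, c, hp * wp), dtype=np.float32)
            np.add.at(dxp,
                      (np.arange(n)[:, None, None, None],
                       np.arange(c)[None, :, None, None], idx),
                      out.grad)
            dxp = dxp.reshape(n, c, hp, wp)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            _accum(x, dxp)
        _attach(out, (x,), bw)
    return out


_UP_CACHE: dict = {}


def _upsample_matrix(n_in: int) -> np.ndarray:
    """(2n, n) interpolation matrix for exact 2x bilinear resize,
    half-pixel centers (corners not aligned)."""
    m = _UP_CACHE.get(n_in)
    if m is None:
        n_out = 2 * n_in
        src = np.clip((np.arange(n_out) + 0.5) / 2.0 - 0.5, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        frac = (src - i0).astype(np.float32)
        m = np.zeros((n_out, n_in), dtype=np.float32)
        m[np.arange(n_out), i0] += 1.0 - frac
        m[np.arange(n_out), i1] += frac
        _UP_CACHE[n_in] = m
    return m


def upsample_bilinear2x(x) -> Tensor:
    x = as_tensor(x)
    h, w = x.data.shape[2], x.data.shape[3]
    mh, mw = _upsample_matrix(h), _upsample_matrix(w)
    out = Tensor(np.matmul(np.matmul(mh, x.data), mw.T))
    if _track(x):
        def bw():
            _accum(x, np.matmul(np.matmul(mh.T, out.grad), mw))
        _attach(out, (x,), bw)
    return out


def batch_norm2d(x, gamma, beta, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool,
                 momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode batch statistics are used and the running buffers are
    updated in place (unbiased variance, matching the common convention);
    in eval mode the running buffers are used.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, h, w = x.data.shape
    m = n * h * w
    xr = x.data.reshape(n, c, h * w)
    if training:
        mu = xr.mean(axis=(0, 2))
        var = np.einsum("ncp,ncp->c", xr, xr) / m - mu * mu
        np.maximum(var, 0.0, out=var)
        if m > 1:
            running_var *= (1.0 - momentum)
            running_var += momentum * var * (m / (m - 1.0))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    scale = (gamma.data * invstd).astype(np.float32)
    shift = (beta.data - mu * scale).astype(np.float32)
    out = Tensor(x.data * scale[None, :, None, None]
                 + shift[None, :, None, None])
    if _track(x, gamma, beta):
        def bw():
            g = out.grad
            gr = g.reshape(n, c, h * w)
            dbeta = gr.sum(axis=(0, 2))
            # sum of g * xhat, without materializing xhat
            dgamma = (np.einsum("ncp,ncp->c", gr, xr, optimize=True)
                      - mu * dbeta) * invstd
            if gamma.requires_grad:
                _accum(gamma, dgamma.astype(np.float32))
            if beta.requires_grad:
                _accum(beta, dbeta.astype(np.float32))
            if x.requires_grad:
                if training:
                    c1 = gamma.data * invstd
                    t1 = (c1 * dbeta / m).astype(np.float32)
                    t2 = (c1 * invstd * dgamma / m).astype(np.float32)
                    dx = (g * c1[None, :, None, None].astype(np.float32)
                          - t1[None, :, None, None]
                          - t2[None, :, None, None]
                          * (x.data - mu[None, :, None, None].astype(np.float32)))
                else:
                    dx = g * scale[None, :, None, None]
                _accum(x, dx)
        _attach(out, (x, gamma, beta), bw)
    return out


def linear(x, weight, bias=None) -> Tensor:
    """Fully-connected layer: (N, C) @ (M, C)^T + b."""
    x, weight = as_tensor(x), as_tensor(weight)
    bias = as_tensor(bias) if bias is not None else None
    out_d = x.data @ weight.data.T
    if bias is not None:
        out_d = out_d + bias.data
    out = Tensor(out_d)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if _track(*parents):
        def bw():
            if x.requires_grad:
                _accum(x, out.grad @ weight.data)
            if weight.requires_grad:
                _accum(weight, out.grad.T @ x.data)
            if bias is not None and bias.requires_grad:
                _accum(bias, out.grad.sum(axis=0))
        _attach(out, parents, bw)
    return out


def global_avg_pool(x) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over the spatial grid."""
    x = as_tensor(x)
    h, w = x.data.shape[2], x.data.shape[3]
    out = Tensor(x.data.mean(axis=(2, 3)))
    if _track(x):
        def bw():
            g = out.grad[:, :, None, None] / (h * w)
            _accum(x, np.broadcast_to(g, x.data.shape).copy())
        _attach(out, (x,), bw)
    return out
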