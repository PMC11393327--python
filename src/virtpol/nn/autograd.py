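"""Minimal reverse-mode autodiff on NumPy arrays.

Everything here is deliberately small: a :class:`Tensor` wrapping a float32
ndarray, a handful of differentiable ops sized for the networks in this
package (NCHW convolutions via im2col, 2x2 max-pooling, bilinear 2x
upsampling, bilinear warping by a displacement field), and nothing else.
Gradient flow is defined per-op through closures; ``Tensor.backward`` runs a
topological sweep.

All ops accept plain ndarrays (treated as constants) or Tensors.
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeError

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "neg",
    "square",
    "absolute",
    "log",
    "sigmoid",
    "relu",
    "leaky_relu",
    "tanh",
    "clip",
    "instance_norm",
    "matmul",
    "tsum",
    "tmean",
    "concat",
    "conv2d",
    "maxpool2x",
    "upsample2x_bilinear",
    "global_avg_pool",
    "grid_warp",
]


class Tensor:
    """A float32 ndarray with an optional gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        # float64 passes through (loss primitives double as exact metrics);
        # everything else is cast to the float32 training dtype
        data = np.asarray(data)
        if data.dtype != np.float64:
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __float__(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ShapeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not isinstance(t, Tensor):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not isinstance(parent, Tensor):
                        continue
                    if not (parent.requires_grad or parent._parents):
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # arithmetic sugar -----------------------------------------------------
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

    def __neg__(self):
        return neg(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward):
    track = any(isinstance(p, Tensor) and (p.requires_grad or p._parents) for p in parents)
    if not track:
        return Tensor(data)
    return Tensor(data, parents=tuple(p for p in parents if isinstance(p, Tensor)), backward=backward)


def _unbroadcast(grad, shape):
    """Sum grad down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.astype(np.float32, copy=False)


# elementwise --------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def bwd(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return _node(out, (a, b), bwd)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data

    def bwd(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(-g, b.data.shape)))

    return _node(out, (a, b), bwd)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def bwd(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return _node(out, (a, b), bwd)


def neg(a):
    a = as_tensor(a)
    return _node(-a.data, (a,), lambda g: ((a, -g),))


def square(a):
    a = as_tensor(a)
    return _node(a.data * a.data, (a,), lambda g: ((a, 2.0 * a.data * g),))


def absolute(a):
    a = as_tensor(a)
    s = np.sign(a.data)
    return _node(np.abs(a.data), (a,), lambda g: ((a, g * s),))


def log(a):
    a = as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: ((a, g / a.data),))


def sigmoid(a):
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
    return _node(out, (a,), lambda g: ((a, g * out * (1.0 - out)),))


def clip(a, lo, hi):
    """Clamp values; gradient is passed only where unclamped."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)
    return _node(out, (a,), lambda g: ((a, g * mask),))


def instance_norm(x, eps=1e-5):
    """Per-sample, per-channel spatial standardisation of an NCHW tensor."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    m = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - m
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out = xc * inv

    def bwd(g):
        k = h * w
        gs = g.sum(axis=(2, 3), keepdims=True)
        gxs = (g * out).sum(axis=(2, 3), keepdims=True)
        gx = inv * (g - gs / k - out * gxs / k)
        return ((x, gx.astype(np.float32)),)

    return _node(out, (x,), bwd)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: ((a, g * mask),))


def leaky_relu(a, slope=0.1):
    a = as_tensor(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope).astype(np.float32)
    return _node(a.data * scale, (a,), lambda g: ((a, g * scale),))


def tanh(a):
    a = as_tensor(a)
    out = np.tanh(a.data)
    return _node(out, (a,), lambda g: ((a, g * (1.0 - out * out)),))


# reductions / shape -------------------------------------------------------

def tsum(a):
    a = as_tensor(a)
    dt = a.data.dtype.type
    return _node(dt(a.data.sum()), (a,), lambda g: ((a, np.full(a.data.shape, g, dtype=a.data.dtype)),))


def tmean(a):
    a = as_tensor(a)
    n = a.data.size
    dt = a.data.dtype.type
    return _node(dt(a.data.mean()), (a,), lambda g: ((a, np.broadcast_to(g / n, a.data.shape).astype(a.data.dtype)),))


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return _node(out, tuple(tensors), bwd)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def bwd(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return _node(out, (a, b), bwd)


# convolution --------------------------------------------------------------

def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    ho, wo = win.shape[2], win.shape[3]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(col), ho, wo


def _col2im(dcol, xshape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    gx = np.zeros((n, c, hp, wp), dtype=np.float32)
    dwin = dcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for a in range(kh):
        for b in range(kw):
            gx[:, :, a : a + stride * ho : stride, b : b + stride * wo : stride] += dwin[:, :, :, :, a, b]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + w]
    return gx


def conv2d(x, weight, bias=None, stride=1, pad=1):
    """NCHW convolution (cross-correlation), weight (O, C, kh, kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    if bias is not None:
        bias = as_tensor(bias)
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ShapeError(f"conv2d channel mismatch: input {c}, weight {ci}")
    col, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(o, -1)
    out = col @ wmat.T
    if bias is not None:
        out += bias.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def bwd(g):
        gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        gw = (gflat.T @ col).reshape(weight.data.shape)
        dcol = gflat @ wmat
        gx = _col2im(dcol, x.data.shape, kh, kw, stride, pad, ho, wo)
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, gflat.sum(axis=0)))
        return tuple(grads)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(out, parents, bwd)


def maxpool2x(x):
    """2x2 max pooling, stride 2; H and W must be even."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ShapeError("maxpool2x requires even spatial dims")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return ((x, gx),)

    return _node(out, (x,), bwd)


def _linear_axis_weights(size_out, size_in):
    """Indices/weights for 2x bilinear upsampling along one axis
    (half-pixel convention, edges clamped)."""
    src = (np.arange(size_out, dtype=np.float32) + 0.5) / 2.0 - 0.5
    i0 = np.floor(src).astype(np.int64)
    frac = (src - i0).astype(np.float32)
    i1 = np.clip(i0 + 1, 0, size_in - 1)
    i0 = np.clip(i0, 0, size_in - 1)
    return i0, i1, 1.0 - frac, frac


def _interp_axis(data, axis, i0, i1, w0, w1):
    sh = [1] * data.ndim
    sh[axis] = -1
    return data.take(i0, axis=axis) * w0.reshape(sh) + data.take(i1, axis=axis) * w1.reshape(sh)


def _interp_axis_T(grad, axis, size_in, i0, i1, w0, w1):
    sh = [1] * grad.ndim
    sh[axis] = -1
    out_shape = list(grad.shape)
    out_shape[axis] = size_in
    gx = np.zeros(out_shape, dtype=np.float32)
    np.add.at(gx, _axis_index(grad.shape, axis, i0), grad * w0.reshape(sh))
    np.add.at(gx, _axis_index(grad.shape, axis, i1), grad * w1.reshape(sh))
    return gx


def _axis_index(shape, axis, idx):
    index = [slice(None)] * len(shape)
    index[axis] = idx
    return tuple(index)


def upsample2x_bilinear(x):
    """Bilinear 2x spatial upsampling (align_corners=False)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    r0, r1, rw0, rw1 = _linear_axis_weights(2 * h, h)
    c0, c1, cw0, cw1 = _linear_axis_weights(2 * w, w)
    tmp = _interp_axis(x.data, 2, r0, r1, rw0, rw1)
    out = _interp_axis(tmp, 3, c0, c1, cw0, cw1)

    def bwd(g):
        gt = _interp_axis_T(g, 3, w, c0, c1, cw0, cw1)
        gx = _interp_axis_T(gt, 2, h, r0, r1, rw0, rw1)
        return ((x, gx),)

    return _node(out, (x,), bwd)


def global_avg_pool(x):
    """(N, C, H, W) -> (N, C) spatial mean."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def bwd(g):
        gx = np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).astype(np.float32)
        return ((x, gx),)

    return _node(out, (x,), bwd)


def grid_warp(image, field):
    """Bilinearly resample ``image`` at displaced coordinates.

    output(n, c, i, j) = image(n, c, i + dy, j + dx) with
    field = (N, 2, H, W) ordered (dx, dy); samples outside the image clamp
    to the border (replication). Differentiable in both arguments.
    """
    image, field = as_tensor(image), as_tensor(field)
    n, c, h, w = image.data.shape
    if field.data.shape != (n, 2, h, w):
        raise ShapeError(f"field shape {field.data.shape} != {(n, 2, h, w)}")
    rows = np.arange(h, dtype=np.float32)[None, :, None] + field.data[:, 1]
    cols = np.arange(w, dtype=np.float32)[None, None, :] + field.data[:, 0]
    rows = np.clip(rows, 0.0, h - 1.0)
    cols = np.clip(cols, 0.0, w - 1.0)
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    r0 = np.minimum(r0, h - 2) if h > 1 else r0 * 0
    c0 = np.minimum(c0, w - 2) if w > 1 else c0 * 0
    fr = (rows - r0).astype(np.float32)
    fc = (cols - c0).astype(np.float32)
    r1, c1 = r0 + (1 if h > 1 else 0), c0 + (1 if w > 1 else 0)

    flat = image.data.reshape(n, c, h * w)
    i00 = (r0 * w + c0).reshape(n, 1, -1)
    i01 = (r0 * w + c1).reshape(n, 1, -1)
    i10 = (r1 * w + c0).reshape(n, 1, -1)
    i11 = (r1 * w + c1).reshape(n, 1, -1)
    p00 = np.take_along_axis(flat, np.broadcast_to(i00, (n, c, h * w)), axis=2).reshape(n, c, h, w)
    p01 = np.take_along_axis(flat, np.broadcast_to(i01, (n, c, h * w)), axis=2).reshape(n, c, h, w)
    p10 = np.take_along_axis(flat, np.broadcast_to(i10, (n, c, h * w)), axis=2).reshape(n, c, h, w)
    p11 = np.take_along_axis(flat, np.broadcast_to(i11, (n, c, h * w)), axis=2).reshape(n, c, h, w)
    frb = fr[:, None]
    fcb = fc[:, None]
    w00 = (1 - frb) * (1 - fcb)
    w01 = (1 - frb) * fcb
    w10 = frb * (1 - fcb)
    w11 = frb * fcb
    out = w00 * p00 + w01 * p01 + w10 * p10 + w11 * p11

    inside_r = (rows > 0.0) & (rows < h - 1.0)
    inside_c = (cols > 0.0) & (cols < w - 1.0)

    def bwd(g):
        grads = []
        if image.requires_grad or image._parents:
            gflat = np.zeros((n, c, h * w), dtype=np.float32)
            for idx, wgt in ((i00, w00), (i01, w01), (i10, w10), (i11, w11)):
                np.add.at(gflat, (np.arange(n)[:, None, None], np.arange(c)[None, :, None], np.broadcast_to(idx, (n, c, h * w))), (g * wgt).reshape(n, c, h * w))
            grads.append((image, gflat.reshape(image.data.shape)))
        if field.requires_grad or field._parents:
            # d out / d row and d out / d col (zero where clamped at border)
            drow = ((1 - fcb) * (p10 - p00) + fcb * (p11 - p01)) * inside_r[:, None]
            dcol = ((1 - frb) * (p01 - p00) + frb * (p11 - p10)) * inside_c[:, None]
            gfield = np.stack([(g * dcol).sum(axis=1), (g * drow).sum(axis=1)], axis=1)
            grads.append((field, gfield.astype(np.float32)))
        return tuple(grads)

    return _node(out, (image, field), bwd)
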