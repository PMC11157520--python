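"""Compact reverse-mode automatic differentiation over numpy arrays.

Provides the handful of differentiable operations the volumetric
classifier needs: broadcasting arithmetic, matmul, activations,
reductions, 3D convolution (strided and dilated), max pooling,
adaptive average pooling, trilinear resampling, spatial softmax and
concatenation.  Gradients are accumulated on every node of the graph
(not only leaves), which Grad-CAM relies on.

The engine is deliberately small: dense layers and convolutions reduce
to BLAS matmuls via im2col, so CPU training at phantom scale stays
fast without any compiled extension.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_DTYPE = np.float32

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv3d",
    "max_pool3d",
    "adaptive_avg_pool3d",
    "upsample_trilinear",
    "trilinear_resize_array",
    "softmax",
    "cross_entropy",
    "relu",
    "sigmoid",
]


class Tensor:
    """A numpy array plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype if dtype is not None else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return _add(self, as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return _mul_scalar(self, -1.0)

    def __sub__(self, other):
        return _add(self, -as_tensor(other))

    def __rsub__(self, other):
        return _add(-self, as_tensor(other))

    def __mul__(self, other):
        if np.isscalar(other):
            return _mul_scalar(self, float(other))
        return _mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return _mul_scalar(self, 1.0 / float(other))
        return _mul(self, as_tensor(other) ** -1.0)

    def __pow__(self, p: float):
        return _pow(self, float(p))

    def __matmul__(self, other):
        return _matmul(self, as_tensor(other))

    def __getitem__(self, idx):
        return _getitem(self, idx)

    def sum(self, axis=None, keepdims: bool = False):
        return _sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return _sum(self, axis, keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _reshape(self, shape)

    def transpose(self, axes: Sequence[int]):
        return _transpose(self, tuple(axes))

    def relu(self):
        return relu(self)

    def sigmoid(self):
        return sigmoid(self)

    def exp(self):
        return _exp(self)

    def log(self):
        return _log(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce `grad` back to `shape` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _accum(t: Tensor, g: np.ndarray) -> None:
    g = g.astype(t.data.dtype, copy=False)
    t.grad = g if t.grad is None else t.grad + g


# --------------------------------------------------------------------------
# elementwise / linear algebra
# --------------------------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def _mul_scalar(a: Tensor, s: float) -> Tensor:
    data = a.data * s

    def backward(g):
        _accum(a, g * s)

    return _make(data, (a,), backward)


def _pow(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0)

    def backward(g):
        _accum(a, g * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * data * (1.0 - data))

    return _make(data, (a,), backward)


def _exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        _accum(a, g * data)

    return _make(data, (a,), backward)


def _log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _make(data, (a,), backward)


def _sum(a: Tensor, axis, keepdims: bool) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            ga = np.broadcast_to(g, a.data.shape)
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(sorted(ax % a.data.ndim for ax in axes)))
            ga = np.broadcast_to(g, a.data.shape)
        _accum(a, ga)

    return _make(data, (a,), backward)


def _reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def _transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(data, (a,), backward)


def _getitem(a: Tensor, idx) -> Tensor:
    data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        _accum(a, ga)

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                _accum(t, g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        _accum(a, data * (g - dot))

    return _make(data, (a,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under row-wise softmax of `logits`."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        _accum(logits, g * p / n)

    return _make(np.asarray(loss, dtype=z.dtype), (logits,), backward)


# --------------------------------------------------------------------------
# spatial operations (rank-5 feature maps: B, C, D, H, W)
# --------------------------------------------------------------------------

def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected 3 values, got {v!r}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def _conv3d_forward(xd: np.ndarray, wd: np.ndarray, stride, padding, dilation):
    """im2col + matmul forward pass on plain arrays.

    Returns (output, cols2) where cols2 is the (N, Cin*k^3) patch matrix
    reused for the weight gradient.
    """
    B, Cin, D, H, W = xd.shape
    Cout, Cw, kd, kh, kw = wd.shape
    if Cw != Cin:
        raise ValueError(f"kernel expects {Cw} input channels, feature map has {Cin}")
    eff = tuple(k + (k - 1) * (r - 1) for k, r in zip((kd, kh, kw), dilation))
    for e, n, p, axname in zip(eff, (D, H, W), padding, "DHW"):
        if e > n + 2 * p:
            raise ValueError(
                f"effective kernel extent {e} exceeds padded input size "
                f"{n + 2 * p} along axis {axname}"
            )
    pd, ph, pw = padding
    xp = np.pad(xd, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    view = sliding_window_view(xp, eff, axis=(2, 3, 4))
    sd, sh, sw = stride
    rd, rh, rw = dilation
    view = view[:, :, ::sd, ::sh, ::sw, ::rd, ::rh, ::rw]
    _, _, Do, Ho, Wo, *_ = view.shape
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    cols2 = cols.reshape(B * Do * Ho * Wo, Cin * kd * kh * kw)
    out2 = cols2 @ wd.reshape(Cout, -1).T
    out = out2.reshape(B, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)
    return out, cols2


def conv3d(
    x,
    w,
    b=None,
    stride=1,
    padding=0,
    dilation=1,
) -> Tensor:
    """3D cross-correlation with zero padding, stride and kernel dilation.

    x: (B, Cin, D, H, W); w: (Cout, Cin, kd, kh, kw); b: (Cout,) or None.
    A dilation rate r spaces kernel taps r voxels apart, so a k-tap axis
    covers an effective extent of k + (k-1)(r-1) voxels.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    stride = _triple(stride)
    dilation = _triple(dilation)
    padding = _triple(padding)
    if any(s < 1 for s in stride) or any(r < 1 for r in dilation):
        raise ValueError("stride and dilation must be >= 1")

    B, Cin, D, H, W = x.data.shape
    Cout, _, kd, kh, kw = w.data.shape
    data, cols2 = _conv3d_forward(x.data, w.data, stride, padding, dilation)
    _, _, Do, Ho, Wo = data.shape
    if b is not None:
        data = data + b.data.reshape(1, Cout, 1, 1, 1)

    # grad wrt input for unit stride is itself a convolution with the
    # channel-swapped, axis-flipped kernel (BLAS path); strided convs
    # fall back to an explicit scatter over kernel taps.
    back_pads = tuple(
        r * (k - 1) - p for k, r, p in zip((kd, kh, kw), dilation, padding)
    )
    use_transposed = stride == (1, 1, 1) and all(p >= 0 for p in back_pads)

    def backward(g):
        g = np.ascontiguousarray(g)
        g2 = g.transpose(0, 2, 3, 4, 1).reshape(-1, Cout)
        if w.requires_grad:
            gw = (g2.T @ cols2).reshape(w.data.shape)
            _accum(w, gw)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            if use_transposed:
                wt = np.ascontiguousarray(
                    w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
                )
                gx, _ = _conv3d_forward(g, wt, (1, 1, 1), back_pads, dilation)
            else:
                sd, sh, sw = stride
                rd, rh, rw = dilation
                pd, ph, pw = padding
                wmat = w.data.reshape(Cout, -1)
                gcols = (g2 @ wmat).reshape(B, Do, Ho, Wo, Cin, kd, kh, kw)
                gcols = gcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
                gxp = np.zeros(
                    (B, Cin, D + 2 * pd, H + 2 * ph, W + 2 * pw), dtype=x.data.dtype
                )
                for i, j, k in itertools.product(range(kd), range(kh), range(kw)):
                    gxp[
                        :,
                        :,
                        i * rd : i * rd + sd * Do : sd,
                        j * rh : j * rh + sh * Ho : sh,
                        k * rw : k * rw + sw * Wo : sw,
                    ] += gcols[:, :, :, :, :, i, j, k]
                gx = gxp[:, :, pd : pd + D, ph : ph + H, pw : pw + W]
            _accum(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def max_pool3d(x, kernel: int = 2) -> Tensor:
    """Non-overlapping max pooling (kernel == stride); trailing voxels that
    do not fill a window are dropped, matching floor-mode pooling."""
    x = as_tensor(x)
    k = int(kernel)
    B, C, D, H, W = x.data.shape
    Do, Ho, Wo = D // k, H // k, W // k
    if min(Do, Ho, Wo) < 1:
        raise ValueError(f"input spatial dims {(D, H, W)} too small for pool kernel {k}")
    xc = x.data[:, :, : Do * k, : Ho * k, : Wo * k]
    v = xc.reshape(B, C, Do, k, Ho, k, Wo, k).transpose(0, 1, 2, 4, 6, 3, 5, 7)
    vf = np.ascontiguousarray(v).reshape(B, C, Do, Ho, Wo, k ** 3)
    idx = vf.argmax(axis=-1)
    data = np.take_along_axis(vf, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gvf = np.zeros_like(vf)
        np.put_along_axis(gvf, idx[..., None], g[..., None], axis=-1)
        gv = gvf.reshape(B, C, Do, Ho, Wo, k, k, k).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gx = np.zeros_like(x.data)
        gx[:, :, : Do * k, : Ho * k, : Wo * k] = gv.reshape(B, C, Do * k, Ho * k, Wo * k)
        _accum(x, gx)

    return _make(data, (x,), backward)


def _adaptive_bounds(n_in: int, n_out: int) -> list[tuple[int, int]]:
    return [
        (int(np.floor(i * n_in / n_out)), int(np.ceil((i + 1) * n_in / n_out)))
        for i in range(n_out)
    ]


def adaptive_avg_pool3d(x, out_shape) -> Tensor:
    """Average pooling onto an arbitrary (smaller or equal) output grid,
    with cell boundaries floor(i*n/m) .. ceil((i+1)*n/m)."""
    x = as_tensor(x)
    od, oh, ow = _triple(out_shape)
    B, C, D, H, W = x.data.shape
    bz = _adaptive_bounds(D, od)
    by = _adaptive_bounds(H, oh)
    bx = _adaptive_bounds(W, ow)
    data = np.empty((B, C, od, oh, ow), dtype=x.data.dtype)
    for i, (z0, z1) in enumerate(bz):
        for j, (y0, y1) in enumerate(by):
            for k, (x0, x1) in enumerate(bx):
                data[:, :, i, j, k] = x.data[:, :, z0:z1, y0:y1, x0:x1].mean(axis=(2, 3, 4))

    def backward(g):
        gx = np.zeros_like(x.data)
        for i, (z0, z1) in enumerate(bz):
            for j, (y0, y1) in enumerate(by):
                for k, (x0, x1) in enumerate(bx):
                    cnt = (z1 - z0) * (y1 - y0) * (x1 - x0)
                    gx[:, :, z0:z1, y0:y1, x0:x1] += g[:, :, i, j, k, None, None, None] / cnt
        _accum(x, gx)

    return _make(data, (x,), backward)


def _linear_coords(n_in: int, n_out: int):
    """align_corners=True source coordinates: index pairs and weights."""
    if n_out == 1 or n_in == 1:
        src = np.zeros(n_out)
    else:
        src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    i0 = np.floor(src).astype(np.intp)
    i0 = np.minimum(i0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(np.float64)
    return i0, i1, f


def _trilinear_terms(in_shape, out_shape):
    (i0z, i1z, fz) = _linear_coords(in_shape[0], out_shape[0])
    (i0y, i1y, fy) = _linear_coords(in_shape[1], out_shape[1])
    (i0x, i1x, fx) = _linear_coords(in_shape[2], out_shape[2])
    terms = []
    for iz, wz in ((i0z, 1 - fz), (i1z, fz)):
        for iy, wy in ((i0y, 1 - fy), (i1y, fy)):
            for ix, wx in ((i0x, 1 - fx), (i1x, fx)):
                wgt = wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
                terms.append((iz, iy, ix, wgt))
    return terms


def trilinear_resize_array(a: np.ndarray, out_shape) -> np.ndarray:
    """Trilinear resize of the trailing three axes of a plain array."""
    out_shape = _triple(out_shape)
    in_shape = a.shape[-3:]
    if tuple(in_shape) == out_shape:
        return a.copy()
    out = np.zeros(a.shape[:-3] + out_shape, dtype=np.result_type(a.dtype, np.float64))
    for iz, iy, ix, wgt in _trilinear_terms(in_shape, out_shape):
        out += wgt * a[..., iz[:, None, None], iy[None, :, None], ix[None, None, :]]
    return out.astype(a.dtype, copy=False)


def upsample_trilinear(x, out_shape) -> Tensor:
    """Differentiable trilinear resize (align_corners convention) of a
    (B, C, D, H, W) feature map to a new spatial grid."""
    x = as_tensor(x)
    out_shape = _triple(out_shape)
    B, C, D, H, W = x.data.shape
    if (D, H, W) == out_shape:
        return x * 1.0
    terms = _trilinear_terms((D, H, W), out_shape)
    data = np.zeros((B, C) + out_shape, dtype=np.float64)
    for iz, iy, ix, wgt in terms:
        data += wgt * x.data[:, :, iz[:, None, None], iy[None, :, None], ix[None, None, :]]
    data = data.astype(x.data.dtype, copy=False)

    def backward(g):
        gx = np.zeros((B, C, D * H * W), dtype=np.float64)
        for iz, iy, ix, wgt in terms:
            lin = (iz[:, None, None] * H + iy[None, :, None]) * W + ix[None, None, :]
            np.add.at(gx, (slice(None), slice(None), lin), wgt * g)
        _accum(x, gx.reshape(B, C, D, H, W))

    return _make(data, (x,), backward)
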