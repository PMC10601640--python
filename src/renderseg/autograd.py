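"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerical core of the package: a small, vectorised autodiff
engine in the micrograd style.  A :class:`Tensor` wraps a ``numpy.ndarray``
together with an optional gradient buffer and a closure that propagates
upstream gradients to its parents.  ``Tensor.backward()`` runs a topological
sort of the recorded graph and accumulates gradients into every tensor
created with ``requires_grad=True``.

Only the operations the segmentation network needs are implemented:
elementwise arithmetic, (batched) matrix multiplication, reductions,
shape manipulation, the nonlinearities used by the model, 2-D convolution,
average pooling, bilinear sampling on a half-open pixel grid, and a
scatter used for point replacement.  All forward values are plain float64
numpy arrays; nothing here owns random state.

Conventions
-----------
* Broadcasting follows numpy; gradients are summed back over broadcast
  axes (`_unbroadcast`).
* Image tensors are laid out ``(B, C, H, W)``; token tensors ``(B, N, D)``.
* Pixel centres sit at ``(i + 0.5, j + 0.5)`` on a half-open
  ``[0, H) x [0, W)`` grid; :func:`bilinear_sample` and the 2x upsampling
  built on it both use this convention, with border clamping.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _special


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph ---------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        # never mutate in place: `g` may be aliased between siblings
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        """Accumulate d(self)/d(leaf) into every requires_grad leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (training loops)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _prev=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, _prev=(self,), _backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _prev=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return Tensor(self.data ** e, _prev=(self,), _backward=bwd)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor(self.data @ other.data, _prev=(self, other), _backward=bwd)

    # -- elementwise functions ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, _prev=(self,), _backward=bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), _prev=(self,), _backward=bwd)

    def sigmoid(self):
        out_data = _special.expit(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _prev=(self,), _backward=bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(np.where(mask, self.data, 0.0), _prev=(self,), _backward=bwd)

    def gelu(self):
        # exact Gaussian-error-function form
        x = self.data
        cdf = 0.5 * (1.0 + _special.erf(x / np.sqrt(2.0)))

        def bwd(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                self._accum(g * (cdf + x * pdf))

        return Tensor(x * cdf, _prev=(self,), _backward=bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed only where unclamped."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * inside)

        return Tensor(np.clip(self.data, lo, hi), _prev=(self,), _backward=bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    axes = tuple(a % self.ndim for a in axes)
                    gg = np.expand_dims(g, axes)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out_data, _prev=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(shape), _prev=(self,), _backward=bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _prev=(self,), _backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accum(buf)

        return Tensor(self.data[idx], _prev=(self,), _backward=bwd)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _prev=tuple(tensors),
        _backward=bwd,
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        _prev=tuple(tensors),
        _backward=bwd,
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select from `a` where boolean `mask` holds, else `b` (mask is constant)."""
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(mask, g, 0.0), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(mask, 0.0, g), b.shape))

    return Tensor(np.where(mask, a.data, b.data), _prev=(a, b), _backward=bwd)


# ---------------------------------------------------------------------------
# structured ops: convolution, pooling, bilinear sampling, scatter
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    x: (B, Cin, H, W); weight: (Cout, Cin, kH, kW); bias: (Cout,).
    Implemented with im2col + matmul; backward uses col2im scatter-add.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    B, Cin, H, W = x.shape
    Cout, Cin2, kH, kW = weight.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d channel mismatch: input has {Cin}, kernel expects {Cin2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kH) // stride + 1
    Wo = (W + 2 * padding - kW) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kH, kW), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (B, Cin, Ho, Wo, kH, kW)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, Cin * kH * kW)
    wmat = weight.data.reshape(Cout, Cin * kH * kW)
    out_data = cols @ wmat.T                          # (B, Ho*Wo, Cout)
    out_data = out_data.transpose(0, 2, 1).reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, Cout, 1, 1)

    prev = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gcols = g.reshape(B, Cout, Ho * Wo).transpose(0, 2, 1)  # (B, Ho*Wo, Cout)
        if weight.requires_grad:
            gw = np.einsum("bpc,bpk->ck", gcols, cols)
            weight._accum(gw.reshape(Cout, Cin, kH, kW))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gc = gcols @ wmat                                   # (B, Ho*Wo, Cin*kH*kW)
            gc = gc.reshape(B, Ho, Wo, Cin, kH, kW)
            gx = np.zeros_like(xp)
            for i in range(kH):
                for j in range(kW):
                    gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += (
                        gc[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)

    return Tensor(out_data, _prev=prev, _backward=bwd)


def avg_pool2x2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (even spatial dims required)."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"avg_pool2x2 needs even spatial dims, got {H}x{W}")
    r = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    out_data = r.mean(axis=(3, 5))

    def bwd(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accum(gx)

    return Tensor(out_data, _prev=(x,), _backward=bwd)


def _bilinear_corners(H: int, W: int, ys: np.ndarray, xs: np.ndarray):
    """Corner indices and weights for continuous pixel coords (ys, xs).

    Coordinates are in pixel units with centres at integer positions after
    the half-pixel shift has been applied by the caller; borders clamp.
    """
    y = np.clip(ys, 0.0, H - 1.0)
    x = np.clip(xs, 0.0, W - 1.0)
    y0 = np.floor(y).astype(np.int64)
    x0 = np.floor(x).astype(np.int64)
    y0 = np.minimum(y0, H - 2) if H > 1 else np.zeros_like(y0)
    x0 = np.minimum(x0, W - 2) if W > 1 else np.zeros_like(x0)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    wy = y - y0
    wx = x - x0
    w00 = (1 - wy) * (1 - wx)
    w01 = (1 - wy) * wx
    w10 = wy * (1 - wx)
    w11 = wy * wx
    return (y0, x0, y1, x1), (w00, w01, w10, w11)


def bilinear_sample(grid: Tensor, ys_norm: np.ndarray, xs_norm: np.ndarray) -> Tensor:
    """Sample `grid` (B, C, H, W) at normalised positions in [0, 1]^2.

    Positions follow the half-pixel convention: normalised coordinate u maps
    to continuous pixel coordinate ``u * H - 0.5``.  `ys_norm`/`xs_norm` have
    shape (B, P) (or (P,) broadcast over batch); output is (B, C, P).
    Positions are constants — gradients flow only into `grid`.
    """
    grid = as_tensor(grid)
    B, C, H, W = grid.shape
    ys_norm = np.asarray(ys_norm, dtype=np.float64)
    xs_norm = np.asarray(xs_norm, dtype=np.float64)
    if ys_norm.ndim == 1:
        ys_norm = np.broadcast_to(ys_norm, (B,) + ys_norm.shape)
        xs_norm = np.broadcast_to(xs_norm, (B,) + xs_norm.shape)
    if np.any(ys_norm < 0) or np.any(ys_norm > 1) or np.any(xs_norm < 0) or np.any(xs_norm > 1):
        raise ValueError("normalised sample positions must lie in [0, 1]")
    P = ys_norm.shape[1]
    ys = ys_norm * H - 0.5
    xs = xs_norm * W - 0.5
    (y0, x0, y1, x1), (w00, w01, w10, w11) = _bilinear_corners(H, W, ys, xs)
    b = np.arange(B)[:, None]
    d = grid.data
    out_data = (
        d[b, :, y0, x0].transpose(0, 2, 1) * w00[:, None, :]
        + d[b, :, y0, x1].transpose(0, 2, 1) * w01[:, None, :]
        + d[b, :, y1, x0].transpose(0, 2, 1) * w10[:, None, :]
        + d[b, :, y1, x1].transpose(0, 2, 1) * w11[:, None, :]
    )

    def bwd(g):
        if not grid.requires_grad:
            return
        gg = np.zeros_like(grid.data)
        bb = np.broadcast_to(np.arange(B)[:, None, None], (B, C, P))
        cc = np.broadcast_to(np.arange(C)[None, :, None], (B, C, P))
        for yy, xx, ww in ((y0, x0, w00), (y0, x1, w01), (y1, x0, w10), (y1, x1, w11)):
            np.add.at(
                gg,
                (bb, cc, np.broadcast_to(yy[:, None, :], (B, C, P)),
                 np.broadcast_to(xx[:, None, :], (B, C, P))),
                g * ww[:, None, :],
            )
        grid._accum(gg)

    return Tensor(out_data, _prev=(grid,), _backward=bwd)


def _up2_fwd(a: np.ndarray, axis: int) -> np.ndarray:
    """Separable 2x bilinear upsampling along one axis (half-pixel centres).

    Output centre 2j maps to input coordinate j - 0.25, centre 2j+1 to
    j + 0.25, so with border clamping:
    ``out[2j] = 0.25 in[j-1] + 0.75 in[j]``,
    ``out[2j+1] = 0.75 in[j] + 0.25 in[j+1]``.
    """
    n = a.shape[axis]
    idx_prev = np.concatenate([[0], np.arange(n - 1)])
    idx_next = np.concatenate([np.arange(1, n), [n - 1]])
    prev = np.take(a, idx_prev, axis=axis)
    nxt = np.take(a, idx_next, axis=axis)
    even = 0.25 * prev + 0.75 * a
    odd = 0.75 * a + 0.25 * nxt
    out = np.stack([even, odd], axis=axis + 1)
    shape = list(a.shape)
    shape[axis] = 2 * n
    return out.reshape(shape)


def _up2_bwd(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_up2_fwd` along one axis."""
    n = g.shape[axis] // 2
    shape = list(g.shape)
    shape[axis] = n
    shape.insert(axis + 1, 2)
    pair = g.reshape(shape)
    ge = np.take(pair, 0, axis=axis + 1)
    go = np.take(pair, 1, axis=axis + 1)
    out = 0.75 * (ge + go)
    # out_even[j+1] gave 0.25 to in[j]; out_odd[j-1] gave 0.25 to in[j]
    sl_head = [slice(None)] * out.ndim
    sl_head[axis] = slice(0, n - 1)
    sl_tail = [slice(None)] * out.ndim
    sl_tail[axis] = slice(1, n)
    out[tuple(sl_head)] += 0.25 * np.take(ge, np.arange(1, n), axis=axis)
    out[tuple(sl_tail)] += 0.25 * np.take(go, np.arange(0, n - 1), axis=axis)
    # border clamps
    sl0 = [slice(None)] * out.ndim
    sl0[axis] = 0
    out[tuple(sl0)] += 0.25 * np.take(ge, 0, axis=axis)
    sl1 = [slice(None)] * out.ndim
    sl1[axis] = n - 1
    out[tuple(sl1)] += 0.25 * np.take(go, n - 1, axis=axis)
    return out


def upsample2x_bilinear(x: Tensor) -> Tensor:
    """Double spatial resolution with bilinear interpolation (half-pixel centres).

    Equivalent to :func:`bilinear_sample` on the regular grid of output
    pixel centres, but computed separably for speed.
    """
    x = as_tensor(x)
    if x.ndim != 4:
        raise ValueError(f"expected (B, C, H, W), got shape {x.shape}")
    out_data = _up2_fwd(_up2_fwd(x.data, 2), 3)

    def bwd(g):
        if x.requires_grad:
            x._accum(_up2_bwd(_up2_bwd(g, 3), 2))

    return Tensor(out_data, _prev=(x,), _backward=bwd)


def scatter_replace(base: Tensor, rows: np.ndarray, cols: np.ndarray,
                    values: Tensor) -> Tensor:
    """Copy `base` (B, 1, H, W) and overwrite pixels (rows, cols) with `values`.

    rows/cols: integer arrays (B, P); values: Tensor (B, P).  Coordinates must
    be unique within each batch element (enforced upstream by point selection).
    """
    base = as_tensor(base)
    values = as_tensor(values)
    B, C, H, W = base.shape
    if C != 1:
        raise ValueError("scatter_replace expects a single-channel map")
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    out_data = base.data.copy()
    b = np.arange(B)[:, None]
    if rows.size:
        out_data[b, 0, rows, cols] = values.data

    def bwd(g):
        if base.requires_grad:
            gb = g.copy()
            if rows.size:
                gb[b, 0, rows, cols] = 0.0
            base._accum(gb)
        if values.requires_grad and rows.size:
            values._accum(g[b, 0, rows, cols])

    return Tensor(out_data, _prev=(base, values), _backward=bwd)
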