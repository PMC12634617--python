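"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's networks (the contour net and the browning U-Net) are small
enough to train on one CPU, so the engine favours clarity over generality:
a flat tape of :class:`Tensor` nodes, each holding a numpy array, its
gradient, and a closure that pushes gradients to its parents.  Convolution
and pooling are fused ops (im2col forward, col2im backward) rather than
compositions of primitives, which keeps training fast enough for the
test-scale models.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2d", "max_pool2d",
           "upsample2d", "batch_norm", "bce_with_logits"]


class Tensor:
    """An array node on the autodiff tape.

    Parameters
    ----------
    data : array-like
        Wrapped value; stored as float32 unless already a float array.
    requires_grad : bool
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph machinery ----------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64) \
                if self.data.dtype == np.float64 else np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    @staticmethod
    def _unbroadcast(g, shape):
        """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, s in enumerate(shape):
            if s == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw(g):
            self._accumulate(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(
                    -g * self.data / (other.data ** 2), other.shape))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bw(g):
            self._accumulate(g.reshape(orig))
        out._backward = bw
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def bw(g):
            self._accumulate(g.transpose(inv))
        out._backward = bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            gx = np.zeros_like(self.data)
            gx[key] = g
            self._accumulate(gx)
        out._backward = bw
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; gradient flows to the arg-max entries."""
        idx = self.data.argmax(axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        out = Tensor(val if keepdims else val.squeeze(axis), _parents=(self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis)
            self._accumulate(gx)
        out._backward = bw
        return out

    # -- nonlinearities -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))

        def bw(g):
            self._accumulate(g * mask)
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _parents=(self,))

        def bw(g):
            self._accumulate(g * s * (1.0 - s))
        out._backward = bw
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -60, 60))
        out = Tensor(e, _parents=(self,))

        def bw(g):
            self._accumulate(g * e)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw(g):
            self._accumulate(g / self.data)
        out._backward = bw
        return out


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gp in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(gp)
    out._backward = bw
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*kh*kw, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # N,C,Ho,Wo,kh,kw
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, xshape, kh, kw, stride, pad):
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:hp - pad, pad:wp - pad]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) with optional channel groups.

    ``weight`` has shape (out, in/groups, kh, kw).
    """
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"weight expects {cin_g * groups} input channels, got {cin}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    if groups == 1:
        wmat = weight.data.reshape(cout, -1)
        y = np.einsum("ok,nkl->nol", wmat, cols, optimize=True)
    else:
        og = cout // groups
        cols_g = cols.reshape(n, groups, cin_g * kh * kw, ho * wo)
        wmat = weight.data.reshape(groups, og, cin_g * kh * kw)
        y = np.einsum("gok,ngkl->ngol", wmat, cols_g, optimize=True)
        y = y.reshape(n, cout, ho * wo)
    if bias is not None:
        y = y + bias.data.reshape(1, cout, 1)
    out = Tensor(y.reshape(n, cout, ho, wo),
                 _parents=tuple(t for t in (x, weight, bias) if t is not None))

    def bw(g):
        gf = g.reshape(n, cout, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gf.sum(axis=(0, 2)))
        if groups == 1:
            if weight.requires_grad:
                gw = np.einsum("nol,nkl->ok", gf, cols, optimize=True)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                wmat_ = weight.data.reshape(cout, -1)
                gcols = np.einsum("ok,nol->nkl", wmat_, gf, optimize=True)
                x._accumulate(_col2im(gcols, x.shape, kh, kw, stride, padding))
        else:
            og = cout // groups
            gf_g = gf.reshape(n, groups, og, ho * wo)
            cols_g = cols.reshape(n, groups, cin_g * kh * kw, ho * wo)
            if weight.requires_grad:
                gw = np.einsum("ngol,ngkl->gok", gf_g, cols_g, optimize=True)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                wmat_ = weight.data.reshape(groups, og, cin_g * kh * kw)
                gcols = np.einsum("gok,ngol->ngkl", wmat_, gf_g, optimize=True)
                x._accumulate(_col2im(
                    gcols.reshape(n, cin * kh * kw, ho * wo),
                    x.shape, kh, kw, stride, padding))
    out._backward = bw
    return out


def avg_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    cols, ho, wo = _im2col(
        x.data.reshape(n * c, 1, h, w), kernel, kernel, stride, padding)
    y = cols.mean(axis=1).reshape(n, c, ho, wo)
    out = Tensor(y, _parents=(x,))
    k2 = kernel * kernel

    def bw(g):
        gcols = np.repeat(g.reshape(n * c, 1, ho * wo) / k2, k2, axis=1)
        gx = _col2im(gcols, (n * c, 1, h, w), kernel, kernel, stride, padding)
        x._accumulate(gx.reshape(n, c, h, w))
    out._backward = bw
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    xr = x.data.reshape(n * c, 1, h, w)
    if padding:
        fill = -np.inf
        xr = np.pad(xr, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding)), constant_values=fill)
    cols, ho, wo = _im2col(xr, kernel, kernel, stride, 0)
    idx = cols.argmax(axis=1)
    y = np.take_along_axis(cols, idx[:, None, :], axis=1)[:, 0, :]
    out = Tensor(y.reshape(n, c, ho, wo), _parents=(x,))

    def bw(g):
        gcols = np.zeros_like(cols)
        np.put_along_axis(gcols, idx[:, None, :],
                          g.reshape(n * c, 1, ho * wo), axis=1)
        gx = _col2im(gcols, (n * c, 1, h + 2 * padding, w + 2 * padding),
                     kernel, kernel, stride, 0)
        if padding:
            gx = gx[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(gx.reshape(n, c, h, w))
    out._backward = bw
    return out


def _bilinear_weights(size_in: int, size_out: int):
    """align_corners=False resampling: per output index, two source indices
    and their weights."""
    scale = size_in / size_out
    pos = (np.arange(size_out) + 0.5) * scale - 0.5
    lo = np.clip(np.floor(pos).astype(int), 0, size_in - 1)
    hi = np.clip(lo + 1, 0, size_in - 1)
    frac = np.clip(pos - np.floor(pos), 0.0, 1.0)
    frac[pos < 0] = 0.0
    return lo, hi, frac.astype(np.float32)


def upsample2d(x: Tensor, size: tuple[int, int], mode: str = "bilinear") -> Tensor:
    """Resize (N,C,H,W) to ``size`` by nearest or bilinear interpolation."""
    n, c, h, w = x.shape
    ho, wo = size
    if mode == "nearest":
        ri = (np.arange(ho) * h // ho)
        ci = (np.arange(wo) * w // wo)
        y = x.data[:, :, ri][:, :, :, ci]
        out = Tensor(y, _parents=(x,))

        def bw(g):
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), ri[:, None], ci[None, :]),
                      g)
            x._accumulate(gx)
        out._backward = bw
        return out
    rlo, rhi, rf = _bilinear_weights(h, ho)
    clo, chi, cf = _bilinear_weights(w, wo)
    rf = rf[:, None]
    cf = cf[None, :]
    d = x.data
    top = d[:, :, rlo][:, :, :, clo] * (1 - cf) + d[:, :, rlo][:, :, :, chi] * cf
    bot = d[:, :, rhi][:, :, :, clo] * (1 - cf) + d[:, :, rhi][:, :, :, chi] * cf
    y = top * (1 - rf) + bot * rf
    out = Tensor(y, _parents=(x,))

    def bw(g):
        gx = np.zeros_like(x.data)
        for rs, rwt in ((rlo, 1 - rf), (rhi, rf)):
            for cs, cwt in ((clo, 1 - cf), (chi, cf)):
                np.add.at(gx, (slice(None), slice(None),
                               rs[:, None], cs[None, :]), g * (rwt * cwt))
        x._accumulate(gx)
    out._backward = bw
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Channel batch normalisation over (N,H,W); updates running stats in place."""
    n, c, h, w = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(y, _parents=(x, gamma, beta))
    m = n * h * w

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * gamma.data[None, :, None, None]
            if training:
                s1 = gxh.sum(axis=(0, 2, 3))[None, :, None, None]
                s2 = (gxh * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                gx = (gxh - s1 / m - xhat * s2 / m) * inv[None, :, None, None]
            else:
                gx = gxh * inv[None, :, None, None]
            x._accumulate(gx)
    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    weight: np.ndarray | None = None) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    z = logits.data
    t = np.asarray(target, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weight is not None:
        loss = loss * weight
        denom = max(float(np.sum(weight)), 1e-12)
    else:
        denom = loss.size
    out = Tensor(loss.sum() / denom, _parents=(logits,))

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        gx = (s - t)
        if weight is not None:
            gx = gx * weight
        logits._accumulate(g * gx / denom)
    out._backward = bw
    return out
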