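"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape sufficient for the spatiotemporal networks in this
package: 3D convolution/pooling, dense layers, batch normalization, recurrent
cells and attention are all composed from the primitives here. Tensors are
channels-last ``(batch, T, H, W, C)`` for video features.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "matmul", "conv3d", "pool3d", "softmax"]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph walk ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
        # The tape is single-use: break the closure cycles (node <-> backward
        # fn) so step graphs are reclaimed by refcounting, not the gc. Leaf
        # gradients (parameters) are kept for the optimizer.
        for t in topo:
            if t._backward is not None:
                t._backward = None
                t._parents = ()
                if t is not self:
                    t.grad = None

    def _accum(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (_wrap(other) ** -1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        out._backward = bw
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        shape = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise nonlinearity ------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data ** 2))

        out._backward = bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))

        out._backward = bw
        return out

    def leaky_relu(self, slope=0.1):
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    def relu(self):
        return self.leaky_relu(slope=0.0)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(grad, shape):
    """Sum a gradient down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def concat(tensors, axis=-1):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D or batched last-two-axes matrix product."""
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            b._accum(np.swapaxes(a.data, -1, -2) @ g)

    out._backward = bw
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# 3D convolution / pooling primitives
# ---------------------------------------------------------------------------

def _same_pad(size, k, s):
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2, out


def conv3d_out_shape(in_shape, kernel, stride):
    """(T,H,W) output extents for SAME padding."""
    return tuple(-(-d // s) for d, s in zip(in_shape, stride))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride=(1, 1, 1)) -> Tensor:
    """SAME-padded 3D convolution.

    x: (B,T,H,W,Cin); w: (kd,kh,kw,Cin,Cout); b: (Cout,) or None.
    """
    B, T, H, W, Cin = x.data.shape
    kd, kh, kw, _, Cout = w.data.shape
    sd, sh, sw = stride
    (pd0, pd1, To) = _same_pad(T, kd, sd)
    (ph0, ph1, Ho) = _same_pad(H, kh, sh)
    (pw0, pw1, Wo) = _same_pad(W, kw, sw)
    xp = np.pad(x.data, ((0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1), (0, 0)))
    view = sliding_window_view(xp, (kd, kh, kw), axis=(1, 2, 3))
    view = view[:, ::sd, ::sh, ::sw]            # (B,To,Ho,Wo,Cin,kd,kh,kw)
    cols = view.transpose(0, 1, 2, 3, 5, 6, 7, 4)  # (B,To,Ho,Wo,kd,kh,kw,Cin)
    cols2 = np.ascontiguousarray(cols).reshape(B * To * Ho * Wo, kd * kh * kw * Cin)
    wmat = w.data.reshape(kd * kh * kw * Cin, Cout)
    y = cols2 @ wmat
    if b is not None:
        y = y + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y.reshape(B, To, Ho, Wo, Cout), parents=parents)

    def bw(g):
        g2 = g.reshape(B * To * Ho * Wo, Cout)
        if w.requires_grad:
            w._accum((cols2.T @ g2).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ wmat.T).reshape(B, To, Ho, Wo, kd, kh, kw, Cin)
            dxp = np.zeros_like(xp)
            for a in range(kd):
                for c in range(kh):
                    for e in range(kw):
                        dxp[:, a:a + sd * To:sd,
                            c:c + sh * Ho:sh,
                            e:e + sw * Wo:sw, :] += gcols[:, :, :, :, a, c, e, :]
            x._accum(dxp[:, pd0:pd0 + T, ph0:ph0 + H, pw0:pw0 + W, :])

    out._backward = bw
    return out


def pool3d(x: Tensor, window=(3, 3, 3), stride=(1, 1, 1), mode="max") -> Tensor:
    """SAME-padded 3D max/average pooling over (T,H,W)."""
    B, T, H, W, C = x.data.shape
    kd, kh, kw = window
    sd, sh, sw = stride
    (pd0, pd1, To) = _same_pad(T, kd, sd)
    (ph0, ph1, Ho) = _same_pad(H, kh, sh)
    (pw0, pw1, Wo) = _same_pad(W, kw, sw)
    fill = -np.inf if mode == "max" else 0.0
    xp = np.pad(x.data, ((0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1), (0, 0)),
                constant_values=fill)
    view = sliding_window_view(xp, (kd, kh, kw), axis=(1, 2, 3))
    view = view[:, ::sd, ::sh, ::sw]  # (B,To,Ho,Wo,C,kd,kh,kw)
    flat = view.reshape(B, To, Ho, Wo, C, kd * kh * kw)
    if mode == "max":
        y = flat.max(axis=-1)
        arg = flat.argmax(axis=-1)
    else:
        y = flat.mean(axis=-1)
        arg = None
    out = Tensor(y, parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp, dtype=np.float32)
        if mode == "max":
            onehot = np.eye(kd * kh * kw)[arg]          # (B,To,Ho,Wo,C,k3)
            gk = (g[..., None] * onehot).reshape(B, To, Ho, Wo, C, kd, kh, kw)
        else:
            gk = np.broadcast_to(
                (g / (kd * kh * kw))[..., None, None, None],
                (B, To, Ho, Wo, C, kd, kh, kw))
        for a in range(kd):
            for c in range(kh):
                for e in range(kw):
                    dxp[:, a:a + sd * To:sd,
                        c:c + sh * Ho:sh,
                        e:e + sw * Wo:sw, :] += gk[:, :, :, :, :, a, c, e]
        x._accum(dxp[:, pd0:pd0 + T, ph0:ph0 + H, pw0:pw0 + W, :])

    out._backward = bw
    return out
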