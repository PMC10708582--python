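"""Trainable layers built on the autograd engine.

Parameters are declared by shape and materialized lazily, so that models can
be built and audited (parameter counts, shape traces) without allocating or
initializing any weights.
"""
from __future__ import annotations

import numpy as np

from .engine import Tensor, concat, conv3d, conv3d_out_shape, matmul, pool3d, softmax

__all__ = [
    "Parameter", "Layer", "Conv3D", "Dense", "BatchNorm", "Dropout",
    "LSTMCellParams", "BiLSTM", "MultiHeadAttention",
]


class Parameter:
    """A lazily-allocated trainable array."""

    def __init__(self, shape, init="he", name=""):
        self.shape = tuple(int(s) for s in shape)
        self.init = init
        self.name = name
        self.tensor: Tensor | None = None

    @property
    def size(self):
        return int(np.prod(self.shape))

    def materialize(self, rng: np.random.Generator):
        if self.init == "zeros":
            data = np.zeros(self.shape)
        elif self.init == "ones":
            data = np.ones(self.shape)
        elif self.init == "he":
            fan_in = max(int(np.prod(self.shape[:-1])), 1)
            data = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.shape)
        elif self.init == "glorot":
            fan_in = max(int(np.prod(self.shape[:-1])), 1)
            fan_out = self.shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            data = rng.uniform(-lim, lim, self.shape)
        else:  # pragma: no cover - guarded by construction
            raise ValueError(f"unknown init {self.init!r}")
        self.tensor = Tensor(data, requires_grad=True)


class Layer:
    """Base class: collects Parameters from attributes (recursively)."""

    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Layer):
                        out.extend(item.parameters())
        return out

    def param_count(self):
        return sum(p.size for p in self.parameters())

    def sublayers(self):
        """All nested Layer instances, depth-first, including self."""
        out = [self]
        for v in vars(self).values():
            if isinstance(v, Layer):
                out.extend(v.sublayers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.sublayers())
        return out


class Conv3D(Layer):
    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), bias=True, init="he"):
        if isinstance(kernel, int):
            kernel = (kernel, kernel, kernel)
        self.kernel = kernel
        self.stride = tuple(stride)
        self.w = Parameter((*kernel, cin, cout), init=init)
        self.b = Parameter((cout,), init="zeros") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w.tensor, None if self.b is None else self.b.tensor,
                      self.stride)

    def out_shape(self, shape):
        t, h, w, _ = shape
        to, ho, wo = conv3d_out_shape((t, h, w), self.kernel, self.stride)
        return (to, ho, wo, self.w.shape[-1])


class Dense(Layer):
    def __init__(self, cin, cout, bias=True, init="glorot"):
        self.w = Parameter((cin, cout), init=init)
        self.b = Parameter((cout,), init="zeros") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = x.reshape(-1, shape[-1])
        y = matmul(flat, self.w.tensor)
        if self.b is not None:
            y = y + self.b.tensor
        return y.reshape(*shape[:-1], self.w.shape[-1])

    def out_shape(self, shape):
        return (*shape[:-1], self.w.shape[1])


class BatchNorm(Layer):
    """Channel-wise batch normalization over all non-channel axes."""

    def __init__(self, c, momentum=0.9, eps=1e-3):
        self.gamma = Parameter((c,), init="ones")
        self.beta = Parameter((c,), init="zeros")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean)
            xc = x - mu
            var = Tensor(self.running_var)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma.tensor + self.beta.tensor

    def out_shape(self, shape):
        return shape


class Dropout(Layer):
    def __init__(self, rate):
        self.rate = float(rate)

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        if not train or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)

    def out_shape(self, shape):
        return shape


class LSTMCellParams(Layer):
    """Weights of one LSTM direction (Keras gate order i,f,c,o)."""

    def __init__(self, fin, hidden):
        self.hidden = hidden
        self.w = Parameter((fin, 4 * hidden), init="glorot")
        self.u = Parameter((hidden, 4 * hidden), init="glorot")
        self.b = Parameter((4 * hidden,), init="zeros")

    def run(self, xs):
        """xs: list of (B, F) tensors in time order; returns final hidden state."""
        B = xs[0].shape[0]
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        for x in xs:
            z = matmul(x, self.w.tensor) + matmul(h, self.u.tensor) + self.b.tensor
            i = z[:, 0 * H:1 * H].sigmoid()
            f = z[:, 1 * H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class BiLSTM(Layer):
    """Bidirectional LSTM returning concatenated final states (2*hidden)."""

    def __init__(self, fin, hidden):
        self.fwd = LSTMCellParams(fin, hidden)
        self.bwd = LSTMCellParams(fin, hidden)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, L, F) -> (B, 2*hidden)."""
        L = x.shape[1]
        steps = [x[:, t, :] for t in range(L)]
        hf = self.fwd.run(steps)
        hb = self.bwd.run(steps[::-1])
        return concat([hf, hb], axis=-1)

    def out_shape(self, shape):
        return (2 * self.hidden,)


class MultiHeadAttention(Layer):
    """Multi-head scaled dot-product self-attention.

    Scores are Q K^T scaled by 1/sqrt(d_k) by default; ``scale="dk"``
    reproduces the plain 1/d_k variant.
    """

    def __init__(self, d_model, d_k, heads, scale="sqrt"):
        self.d_model, self.d_k, self.heads = d_model, d_k, heads
        self.scale = scale
        self.wq = [Dense(d_model, d_k) for _ in range(heads)]
        self.wk = [Dense(d_model, d_k) for _ in range(heads)]
        self.wv = [Dense(d_model, d_k) for _ in range(heads)]
        self.wo = Dense(heads * d_k, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, L, d_model) -> (B, L, d_model)."""
        heads = []
        for q_l, k_l, v_l in zip(self.wq, self.wk, self.wv):
            heads.append(attention(q_l(x), k_l(x), v_l(x), self.d_k, self.scale))
        return self.wo(concat(heads, axis=-1))

    def out_shape(self, shape):
        return shape


def attention(q: Tensor, k: Tensor, v: Tensor, d_k: int, scale="sqrt") -> Tensor:
    """softmax(Q K^T / scale) V with rows of Q attending over rows of K/V."""
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    denom = np.sqrt(d_k) if scale == "sqrt" else float(d_k)
    scores = matmul(q, k.transpose(tuple(range(k.ndim - 2)) + (k.ndim - 1, k.ndim - 2)))
    weights = softmax(scores * (1.0 / denom), axis=-1)
    return matmul(weights, v)
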