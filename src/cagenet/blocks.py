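"""Reusable network building blocks for the dual-stream architectures.

Six block families are provided:

* ``PrimaryConvBlock`` — two stacked 3D convolutions (``n`` then ``k*n``
  filters), each followed by batch normalization, with dropout; downsampling
  is via strides on the convolutions.
* ``InceptionV3DBlock`` — a 3D grid-style module with three parallel branches
  (1x1x1 -> 3x3x3; 1x1x1 -> 3x3x3 -> 3x3x3; pool -> 1x1x1) concatenated on
  channels; used as the joint-processing block of the Inception-augmented
  dual-stream models.
* ``InceptionV13DBlock`` — the classic dimensionality-reduction Inception
  module lifted to 3D, without the lone 1x1 branch: 1x1x1 -> 3x3x3,
  1x1x1 -> 5x5x5 and pool -> 1x1x1 branches of equal width ``k*n``.
* ``DenseDropoutJoint`` — sums two streams and processes the result with a
  channel-wise dense layer plus dropout (the baseline joint block).
* ``AttentionBlock`` — multi-head self-attention over the end features of a
  stream, with batch normalization in place of layer normalization and a
  learned positional embedding.
* ``BiLSTMHead`` — bidirectional LSTM over the flattened spatiotemporal
  positions, replacing the flatten that usually precedes the FC stack.

All blocks consume channels-last ``(B, T, H, W, C)`` tensors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.engine import Tensor, concat, pool3d
from .nn.layers import (
    BatchNorm, BiLSTM, Conv3D, Dense, Dropout, Layer, MultiHeadAttention,
    attention,
)

__all__ = [
    "BlockConfig", "AttentionConfig", "PrimaryConvBlock", "InceptionV3DBlock",
    "InceptionV13DBlock", "DenseDropoutJoint", "AttentionBlock", "BiLSTMHead",
    "attention", "BLOCK_REGISTRY",
]


@dataclass
class BlockConfig:
    """Per-block hyperparameters: base filters n, multiplier k, kernel m."""
    n: int
    k: float = 1.5
    m: int = 3
    dropout_rate: float = 0.2

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.m % 2 == 0:
            raise ValueError("kernel edge m must be odd")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class AttentionConfig:
    d_model: int
    d_k: int
    heads: int = 4
    scale: str = "sqrt"

    def __post_init__(self):
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.d_k < 1:
            raise ValueError("d_k must be >= 1")


def _act(x: Tensor, kind: str) -> Tensor:
    return x.relu() if kind == "relu" else x.leaky_relu(0.1)


class PrimaryConvBlock(Layer):
    """conv(n, m1) + BN + act, conv(k*n, m2) + BN + act, dropout."""

    def __init__(self, cin, cfg: BlockConfig, kernels=None, strides=((1, 1, 1), (1, 1, 1)),
                 activation="leaky_relu", use_dropout=True):
        m1, m2 = kernels if kernels is not None else (cfg.m, cfg.m)
        cmid = cfg.n
        cout = int(round(cfg.k * cfg.n))
        self.conv1 = Conv3D(cin, cmid, m1, strides[0])
        self.bn1 = BatchNorm(cmid)
        self.conv2 = Conv3D(cmid, cout, m2, strides[1])
        self.bn2 = BatchNorm(cout)
        self.drop = Dropout(cfg.dropout_rate) if use_dropout else None
        self.activation = activation
        self.cout = cout

    def __call__(self, x, train=False, rng=None):
        x = _act(self.bn1(self.conv1(x), train), self.activation)
        x = _act(self.bn2(self.conv2(x), train), self.activation)
        if self.drop is not None:
            x = self.drop(x, train, rng)
        return x

    def out_shape(self, shape):
        return self.conv2.out_shape(self.conv1.out_shape(shape))


class InceptionV13DBlock(Layer):
    """Three equal-width branches concatenated on channels (output 3*k*n)."""

    def __init__(self, cin, cfg: BlockConfig, r1, r2, stride=(1, 1, 1),
                 activation="relu", bias=True):
        w = int(round(cfg.k * cfg.n))
        self.red1 = Conv3D(cin, r1, 1, bias=bias)
        self.bn_r1 = BatchNorm(r1)
        self.conv3 = Conv3D(r1, w, 3, stride, bias=bias)
        self.bn3 = BatchNorm(w)
        self.red2 = Conv3D(cin, r2, 1, bias=bias)
        self.bn_r2 = BatchNorm(r2)
        self.conv5 = Conv3D(r2, w, 5, stride, bias=bias)
        self.bn5 = BatchNorm(w)
        self.pool_proj = Conv3D(cin, w, 1, bias=bias)
        self.bn_p = BatchNorm(w)
        self.stride = tuple(stride)
        self.activation = activation
        self.cout = 3 * w

    def __call__(self, x, train=False, rng=None):
        a = _act(self.bn_r1(self.red1(x), train), self.activation)
        a = _act(self.bn3(self.conv3(a), train), self.activation)
        b = _act(self.bn_r2(self.red2(x), train), self.activation)
        b = _act(self.bn5(self.conv5(b), train), self.activation)
        p = pool3d(x, (3, 3, 3), self.stride, mode="max")
        p = _act(self.bn_p(self.pool_proj(p), train), self.activation)
        return concat([a, b, p], axis=-1)

    def out_shape(self, shape):
        t, h, w, _ = self.conv3.out_shape(self.red1.out_shape(shape))
        return (t, h, w, self.cout)


class InceptionV3DBlock(Layer):
    """3D Inception-v3 block-D style joint module.

    Branches: 1x1x1->3x3x3 (width u1); 1x1x1->3x3x3->3x3x3 (width u2);
    pool->1x1x1 (width u3). Output channels = u1+u2+u3.
    """

    def __init__(self, cin, splits, r1, r2, s, stride=(1, 1, 1),
                 activation="leaky_relu", bias=True):
        u1, u2, u3 = splits
        self.red1 = Conv3D(cin, r1, 1, bias=bias)
        self.bn_r1 = BatchNorm(r1)
        self.conv_a = Conv3D(r1, u1, 3, stride, bias=bias)
        self.bn_a = BatchNorm(u1)
        self.red2 = Conv3D(cin, r2, 1, bias=bias)
        self.bn_r2 = BatchNorm(r2)
        self.conv_b1 = Conv3D(r2, s, 3, bias=bias)
        self.bn_b1 = BatchNorm(s)
        self.conv_b2 = Conv3D(s, u2, 3, stride, bias=bias)
        self.bn_b2 = BatchNorm(u2)
        self.pool_proj = Conv3D(cin, u3, 1, bias=bias)
        self.bn_p = BatchNorm(u3)
        self.stride = tuple(stride)
        self.activation = activation
        self.cout = u1 + u2 + u3

    def __call__(self, x, train=False, rng=None):
        a = _act(self.bn_r1(self.red1(x), train), self.activation)
        a = _act(self.bn_a(self.conv_a(a), train), self.activation)
        b = _act(self.bn_r2(self.red2(x), train), self.activation)
        b = _act(self.bn_b1(self.conv_b1(b), train), self.activation)
        b = _act(self.bn_b2(self.conv_b2(b), train), self.activation)
        p = pool3d(x, (3, 3, 3), self.stride, mode="max")
        p = _act(self.bn_p(self.pool_proj(p), train), self.activation)
        return concat([a, b, p], axis=-1)

    def out_shape(self, shape):
        t, h, w, _ = self.conv_a.out_shape(self.red1.out_shape(shape))
        return (t, h, w, self.cout)


class DenseDropoutJoint(Layer):
    """Baseline joint block: channel-wise dense + BN + dropout on the sum."""

    def __init__(self, cin, cout, dropout_rate=0.2, bias=True,
                 activation="leaky_relu"):
        self.dense = Dense(cin, cout, bias=bias)
        self.bn = BatchNorm(cout)
        self.drop = Dropout(dropout_rate)
        self.activation = activation
        self.cout = cout

    def __call__(self, x, train=False, rng=None):
        y = _act(self.bn(self.dense(x), train), self.activation)
        return self.drop(y, train, rng)

    def joint(self, x_rgb: Tensor, x_flow: Tensor, train=False, rng=None):
        """Sum the streams and jointly process; returns the shared output."""
        if x_rgb.shape != x_flow.shape:
            raise ValueError("stream shapes differ: "
                             f"{x_rgb.shape} vs {x_flow.shape}")
        return self(x_rgb + x_flow, train, rng)

    def out_shape(self, shape):
        return (*shape[:-1], self.cout)


class AttentionBlock(Layer):
    """Self-attention over stream end features.

    The T*H*W positions of the final feature map are the token sequence; a
    learned positional embedding is added, tokens are batch-normalized and a
    residual multi-head attention is applied.
    """

    def __init__(self, tokens, cfg: AttentionConfig):
        from .nn.layers import Parameter
        self.pos = Parameter((tokens, cfg.d_model), init="zeros")
        self.bn = BatchNorm(cfg.d_model)
        self.mha = MultiHeadAttention(cfg.d_model, cfg.d_k, cfg.heads, cfg.scale)
        self.tokens = tokens
        self.d_model = cfg.d_model

    def __call__(self, x, train=False, rng=None):
        """x: (B,T,H,W,C); tokens are the T*H*W positions."""
        b = x.shape[0]
        t, h, w, c = x.shape[1:]
        seq = x.reshape(b, t * h * w, c) + self.pos.tensor
        out = seq + self.mha(self.bn(seq, train))
        return out.reshape(b, t, h, w, c)

    def out_shape(self, shape):
        return shape


class BiLSTMHead(Layer):
    """Reshape (T,H,W,C) -> (T*H*W, C) sequence and run a BiLSTM."""

    def __init__(self, feature_width, hidden):
        self.rnn = BiLSTM(feature_width, hidden)

    def __call__(self, x, train=False, rng=None):
        b = x.shape[0]
        t, h, w, c = x.shape[1:]
        return self.rnn(x.reshape(b, t * h * w, c))

    def out_shape(self, shape):
        return (2 * self.rnn.hidden,)


BLOCK_REGISTRY = {
    "primary": PrimaryConvBlock,
    "inception_v3d": InceptionV3DBlock,
    "inception_v1_3d": InceptionV13DBlock,
    "dense_joint": DenseDropoutJoint,
    "mha": AttentionBlock,
    "bilstm": BiLSTMHead,
}
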