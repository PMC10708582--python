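"""Builders for the five dual-stream architectures and model accounting.

Each architecture comes in a *sharing* form (streams are jointly processed at
regular intervals) and a *standalone* form (the joint blocks are replicated
per stream and the streams merge only before the common FC stack):

* ``baseline``      — primary 3D conv blocks, dense-dropout joint processing.
* ``civ3d_mha``     — Inception-v3-block-D joints plus per-stream self-attention.
* ``civ3d_bilstm``  — Inception-v3-block-D joints plus a BiLSTM head.
* ``srs``           — Singly Reinforced Stream: one running stream repeatedly
  concatenated with strided computations of the optical-flow sequence.
* ``crs``           — Cross Reinforced Streams: each block consumes the joint
  concatenation plus the other stream's past features.

Default widths reproduce the published per-model trainable-parameter counts
exactly; where internal branch widths are not determined by the stacked-module
table they were tuned once against the published totals and ship here as the
package defaults.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .blocks import (
    AttentionBlock, AttentionConfig, BlockConfig, BiLSTMHead,
    DenseDropoutJoint, InceptionV13DBlock, InceptionV3DBlock, PrimaryConvBlock,
)
from .nn.engine import Tensor, concat, pool3d, softmax
from .nn.layers import Dense, Layer

__all__ = [
    "ModelSpec", "ModelAccount", "build_model", "build_srs", "build_crs",
    "count_parameters", "count_flops", "layer_output_shapes", "MODEL_NAMES",
]

MODEL_NAMES = ("baseline", "civ3d_mha", "civ3d_bilstm", "srs", "crs")

# ---------------------------------------------------------------------------
# Tuned internal widths (reduction widths of Inception branches, attention and
# LSTM dimensions). These are free parameters of the block designs; the values
# below reproduce the published parameter totals for every model and variant.
# ---------------------------------------------------------------------------
DEFAULT_WIDTHS = {
    "civ3d": {
        "joint_r": [(214, 104), (429, 213), (866, 434), (1738, 866)],
        "joint_s": [16, 32, 64, 128],
        "joint_r_standalone_mha": [(144, 71), (293, 145), (590, 297), (1190, 594)],
        "joint_r_standalone_bilstm": [(143, 69), (291, 146), (590, 298), (1178, 585)],
    },
    "srs": {
        "rgb": [(11, 4), (27, 11), (57, 28), (119, 57), (119, 57), (160, 85)],
        "flow": [(11, 8), (28, 19), (63, 35), (124, 65), (127, 65)],
        "rgb_standalone": [(12, 5), (27, 11), (57, 28), (119, 57), (119, 57)],
        "flow_standalone": [(11, 4), (27, 11), (60, 35), (127, 65), (122, 65)],
        "final_standalone": (168, 85),
    },
    "crs": {
        "stream": [(16, 6), (36, 17), (74, 35), (152, 79), (308, 159)],
        "stream_standalone": [(17, 7), (37, 17), (78, 44), (161, 85), (321, 161)],
    },
}


@dataclass
class ModelSpec:
    """Fully determines a buildable network."""

    name: str
    variant: str = "sharing"
    input_shape: tuple = (8, 96, 128, 3)       # (T, H, W, C) of the RGB stream
    flow_channels: int = 3                     # C of the flow-stream encoding
    num_classes: int = 8
    n: tuple = ()                              # primary filters per module
    k: tuple = ()                              # intra-block multipliers
    m: tuple = ()                              # kernel edges (conv blocks)
    fc_units: tuple = (512, 64, 8)
    combine: str = "add"
    learning_rate: float = 0.001
    dropout_rate: float = 0.2
    temporal_crop: int = 2                     # SRS flow-stream frame crop
    attention_heads: int = 4
    attention_dk: int = 514
    attention_scale: str = "sqrt"
    lstm_hidden: int = 370
    widths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.variant not in ("sharing", "standalone"):
            raise ValueError(f"variant must be sharing|standalone, got {self.variant!r}")

    # -- canonical configurations ---------------------------------------
    @classmethod
    def default(cls, name, variant="sharing", **overrides):
        """The full-size configuration of the stacked-module table."""
        base = dict(name=name, variant=variant)
        if name == "baseline":
            base.update(n=(16, 32, 64, 128), k=(1.5,) * 4, m=(5, 3, 5, 5),
                        combine="add", learning_rate=0.0005, widths={})
        elif name in ("civ3d_mha", "civ3d_bilstm"):
            base.update(n=(16, 32, 64, 128), k=(1.5,) * 4, m=(7, 5, 5, 3),
                        combine="add", learning_rate=0.001,
                        widths=dict(DEFAULT_WIDTHS["civ3d"]))
        elif name == "srs":
            base.update(n=(8, 16, 32, 64, 64, 128),
                        k=(1.5, 1.5, 1.5, 1.5, 1.5, 1.0), m=(),
                        combine="concat", learning_rate=0.001,
                        widths=dict(DEFAULT_WIDTHS["srs"]))
        elif name == "crs":
            base.update(n=(12, 24, 48, 96, 192), k=(1.0,) * 5, m=(),
                        combine="concat", learning_rate=0.001,
                        widths=dict(DEFAULT_WIDTHS["crs"]))
        base.update(overrides)
        return cls(**base)

    @classmethod
    def desk(cls, name, variant="sharing", **overrides):
        """A reduced configuration for CPU-scale experiments.

        Quarter-width filters on 8x16x16x3 cuboids; internal reduction widths
        follow the conventional Inception rule (r1 ~ branch width, r2 ~ half).
        """
        spec = cls.default(name, variant)
        desk_lr = {"baseline": 0.02, "civ3d_mha": 0.01, "civ3d_bilstm": 0.015,
                   "srs": 0.02, "crs": 0.02}
        geo = dict(input_shape=(8, 16, 16, 3), fc_units=(128, 32, 8),
                   attention_dk=12, lstm_hidden=48, learning_rate=desk_lr[name])
        if name == "baseline":
            geo.update(n=(8, 16, 32, 64), widths={})
        elif name in ("civ3d_mha", "civ3d_bilstm"):
            n = (8, 16, 32, 64)
            cs = [int(1.5 * ni) for ni in n]
            geo.update(n=n, widths={
                "joint_r": [(c, max(c // 2, 1)) for c in cs],
                "joint_s": [max(c // 3, 1) for c in cs],
                "joint_r_standalone_mha": [(c, max(c // 2, 1)) for c in cs],
                "joint_r_standalone_bilstm": [(c, max(c // 2, 1)) for c in cs],
            })
        elif name == "srs":
            n = (2, 4, 8, 16, 16, 32)
            ws = [int(round(ki * ni)) for ki, ni in zip(spec.k, n)]
            geo.update(n=n, widths={
                "rgb": [(2 * w, w) for w in ws],
                "flow": [(2 * w, w) for w in ws[:5]],
                "rgb_standalone": [(2 * w, w) for w in ws[:5]],
                "flow_standalone": [(2 * w, w) for w in ws[:5]],
                "final_standalone": (2 * ws[5], ws[5]),
            })
        elif name == "crs":
            n = (4, 8, 16, 32, 64)
            geo.update(n=n, widths={
                "stream": [(2 * ni, ni) for ni in n],
                "stream_standalone": [(2 * ni, ni) for ni in n],
            })
        geo.update(overrides)
        return replace(spec, **geo)


@dataclass
class ModelAccount:
    parameter_count: int
    flops: float
    per_module_output_shapes: list


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------

class FCStack(Layer):
    def __init__(self, fin, units, activation="leaky_relu"):
        dims = [fin] + list(units)
        self.layers = [Dense(dims[i], dims[i + 1]) for i in range(len(units))]
        self.activation = activation

    def __call__(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu() if self.activation == "relu" else x.leaky_relu(0.1)
        return x


class DualStreamModel(Layer):
    """Base class: two-input (RGB cuboid, flow cuboid) classifier."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self._module_shapes: list = []
        self.traced_module_shapes: list = []   # filled by each forward pass
        self._rng = np.random.default_rng(0)

    # -- lifecycle -------------------------------------------------------
    def initialize(self, seed=0):
        rng = np.random.default_rng(seed)
        for p in self.parameters():
            p.materialize(rng)
        self._rng = np.random.default_rng((seed + 1) * 7919)
        return self

    def forward(self, rgb: Tensor, flow: Tensor, train=False) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, rgb, flow):
        logits = self.forward(Tensor(rgb), Tensor(flow), train=False)
        return softmax(logits, axis=-1).data

    def module_shapes(self):
        """(T,H,W,C) of the combined-stream tensor at each stacked module."""
        return list(self._module_shapes)

    def state(self):
        """Parameter arrays plus batch-norm running statistics."""
        from .nn.layers import BatchNorm
        arrays = [None if p.tensor is None else p.tensor.data.copy()
                  for p in self.parameters()]
        for layer in self.sublayers():
            if isinstance(layer, BatchNorm):
                arrays.append(layer.running_mean.copy())
                arrays.append(layer.running_var.copy())
        return arrays

    def load_state(self, state):
        from .nn.layers import BatchNorm
        params = self.parameters()
        for p, data in zip(params, state):
            p.tensor = Tensor(np.array(data), requires_grad=True)
        rest = iter(state[len(params):])
        for layer in self.sublayers():
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(next(rest))
                layer.running_var = np.array(next(rest))


def _tstride(t):
    """Temporal stride 2 while the temporal extent is still > 1."""
    return 2 if t > 1 else 1


def _tap_stride(src, dst):
    """Stride mapping a full-resolution extent onto a target (SAME/ceil)."""
    s = -(-src // dst)
    if -(-src // s) != dst:
        raise ValueError(f"cannot stride {src} onto {dst}")
    return s


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

class BaselineModel(DualStreamModel):
    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        T, H, W, C = spec.input_shape
        sharing = spec.variant == "sharing"
        self.blocks_rgb, self.blocks_flow = [], []
        self.joints, self.joints_rgb, self.joints_flow = [], [], []
        shape = (T, H, W, C)
        cin_r, cin_f = C, spec.flow_channels
        for i, (ni, ki, mi) in enumerate(zip(spec.n, spec.k, spec.m)):
            cfg = BlockConfig(ni, ki, mi, spec.dropout_rate)
            s1 = (_tstride(shape[0]) if i < len(spec.n) - 1 else 1, 2, 2)
            s2 = (1, 2, 2) if i == 0 else (1, 1, 1)
            mk = dict(kernels=(mi, mi), strides=(s1, s2))
            br = PrimaryConvBlock(cin_r, cfg, **mk)
            bf = PrimaryConvBlock(cin_f, cfg, **mk)
            self.blocks_rgb.append(br)
            self.blocks_flow.append(bf)
            shape = br.out_shape(shape)
            self._module_shapes.append(shape)       # combined (added) streams
            if sharing:
                self.joints.append(DenseDropoutJoint(br.cout, ni,
                                                     spec.dropout_rate, bias=True))
            else:
                self.joints_rgb.append(DenseDropoutJoint(br.cout, ni,
                                                         spec.dropout_rate, bias=False))
                self.joints_flow.append(DenseDropoutJoint(br.cout, ni,
                                                          spec.dropout_rate, bias=False))
            cin_r = cin_f = ni
            shape = (*shape[:3], ni)
        flat = int(np.prod(shape))
        self.fc = FCStack(flat, spec.fc_units)

    def forward(self, rgb, flow, train=False):
        x_r, x_f = rgb, flow
        rng = self._rng
        self.traced_module_shapes = []
        for i in range(len(self.blocks_rgb)):
            x_r = self.blocks_rgb[i](x_r, train, rng)
            x_f = self.blocks_flow[i](x_f, train, rng)
            self.traced_module_shapes.append(tuple(x_r.shape[1:]))
            if self.spec.variant == "sharing":
                j = self.joints[i].joint(x_r, x_f, train, rng)
                x_r = x_f = j
            else:
                x_r = self.joints_rgb[i](x_r, train, rng)
                x_f = self.joints_flow[i](x_f, train, rng)
        merged = x_r if x_r is x_f else x_r + x_f
        b = merged.shape[0]
        return self.fc(merged.reshape(b, -1))


# ---------------------------------------------------------------------------
# CIv3D (Inception-v3-block-D joints; MHA or BiLSTM head)
# ---------------------------------------------------------------------------

class CIv3DModel(DualStreamModel):
    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        T, H, W, C = spec.input_shape
        sharing = spec.variant == "sharing"
        head = "mha" if spec.name == "civ3d_mha" else "bilstm"
        self.head_kind = head
        use_drop = head == "mha"   # the BiLSTM model drops the dropout layers
        wcfg = spec.widths
        rkey = ("joint_r" if sharing
                else f"joint_r_standalone_{head}")
        joint_bias = sharing
        self.blocks_rgb, self.blocks_flow = [], []
        self.joints, self.joints_rgb, self.joints_flow = [], [], []
        shape = (T, H, W, C)
        cin_r, cin_f = C, spec.flow_channels
        for i, (ni, ki, mi) in enumerate(zip(spec.n, spec.k, spec.m)):
            cfg = BlockConfig(ni, ki, mi, spec.dropout_rate)
            kern = (mi, max(mi - 2, 1))         # rising/falling kernel pattern
            s1 = (_tstride(shape[0]) if i < len(spec.n) - 1 else 1, 2, 2)
            s2 = (1, 2, 2) if i == 0 else (1, 1, 1)
            mk = dict(kernels=kern, strides=(s1, s2), use_dropout=use_drop)
            br = PrimaryConvBlock(cin_r, cfg, **mk)
            bf = PrimaryConvBlock(cin_f, cfg, **mk)
            self.blocks_rgb.append(br)
            self.blocks_flow.append(bf)
            shape = br.out_shape(shape)
            self._module_shapes.append(shape)
            c = br.cout
            u = c // 3
            splits = (u, u, c - 2 * u)
            r1, r2 = wcfg[rkey][i]
            s = wcfg["joint_s"][i]
            mkj = dict(splits=splits, r1=r1, r2=r2, s=s, bias=joint_bias)
            if sharing:
                self.joints.append(InceptionV3DBlock(c, **mkj))
            else:
                self.joints_rgb.append(InceptionV3DBlock(c, **mkj))
                self.joints_flow.append(InceptionV3DBlock(c, **mkj))
            cin_r = cin_f = c
            shape = (*shape[:3], c)
        t, h, w, c = shape
        if head == "mha":
            acfg = AttentionConfig(c, spec.attention_dk, spec.attention_heads,
                                   spec.attention_scale)
            self.att_rgb = AttentionBlock(t * h * w, acfg)
            self.att_flow = AttentionBlock(t * h * w, acfg)
            self.fc = FCStack(int(np.prod(shape)), spec.fc_units)
        else:
            self.bilstm = BiLSTMHead(c, spec.lstm_hidden)
            self.fc = FCStack(2 * spec.lstm_hidden, spec.fc_units)

    def forward(self, rgb, flow, train=False):
        x_r, x_f = rgb, flow
        rng = self._rng
        self.traced_module_shapes = []
        sharing = self.spec.variant == "sharing"
        nblocks = len(self.blocks_rgb)
        for i in range(nblocks):
            x_r = self.blocks_rgb[i](x_r, train, rng)
            x_f = self.blocks_flow[i](x_f, train, rng)
            last = i == nblocks - 1
            if last and self.head_kind == "mha":
                x_r = self.att_rgb(x_r, train, rng)
                x_f = self.att_flow(x_f, train, rng)
            self.traced_module_shapes.append(tuple(x_r.shape[1:]))
            if sharing:
                j = self.joints[i](x_r + x_f, train, rng)
                x_r = x_f = j
            else:
                x_r = self.joints_rgb[i](x_r, train, rng)
                x_f = self.joints_flow[i](x_f, train, rng)
        merged = x_r if x_r is x_f else x_r + x_f
        b = merged.shape[0]
        if self.head_kind == "mha":
            return self.fc(merged.reshape(b, -1))
        return self.fc(self.bilstm(merged, train, rng))


# ---------------------------------------------------------------------------
# SRS (Singly Reinforced Stream)
# ---------------------------------------------------------------------------

class SRSModel(DualStreamModel):
    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        T, H, W, C = spec.input_shape
        crop = spec.temporal_crop
        if T - 2 * crop < 1:
            raise ValueError(f"temporal crop {crop}+{crop} leaves no frames of T={T}")
        self.crop = crop
        sharing = spec.variant == "sharing"
        n, k = spec.n, spec.k
        wcfg = spec.widths

        def blk(cin, i, r, stride):
            cfg = BlockConfig(n[i], k[i], 3, spec.dropout_rate)
            return InceptionV13DBlock(cin, cfg, r[0], r[1], stride,
                                      activation="relu")

        if sharing:
            rw, fw = wcfg["rgb"], wcfg["flow"]
            # module 1: both streams at full resolution
            self.rgb1 = blk(C, 0, rw[0], (1, 1, 1))
            self.flow1 = blk(spec.flow_channels, 0, fw[0], (1, 1, 1))
            shape = self.rgb1.out_shape((T, H, W, C))
            run_shape = (*shape[:3], 2 * shape[3])
            self._module_shapes.append(run_shape)
            flow_shape = (T - 2 * crop, H, W, spec.flow_channels)
            self.run_blocks, self.tap_blocks, self.tap_strides = [], [], []
            for i in range(1, 5):
                stride = (_tstride(run_shape[0]), 2, 2)
                rb = blk(run_shape[3], i, rw[i], stride)
                out = rb.out_shape(run_shape)
                ts = tuple(_tap_stride(flow_shape[d], out[d]) for d in range(3))
                tb = blk(spec.flow_channels, i, fw[i], ts)
                self.run_blocks.append(rb)
                self.tap_blocks.append(tb)
                self.tap_strides.append(ts)
                run_shape = (*out[:3], out[3] + tb.cout)
                self._module_shapes.append(run_shape)
            self.final_block = blk(run_shape[3], 5, rw[5],
                                   (_tstride(run_shape[0]), 2, 2))
            shape = self.final_block.out_shape(run_shape)
        else:
            rw, fw = wcfg["rgb_standalone"], wcfg["flow_standalone"]
            self.rgb_chain, self.flow_chain = [], []
            rs = (T, H, W, C)
            fs = (T, H, W, spec.flow_channels)
            for i in range(5):
                stride = (1, 1, 1) if i == 0 else (_tstride(rs[0]), 2, 2)
                rb = blk(rs[3], i, rw[i], stride)
                fb = blk(fs[3], i, fw[i], stride)
                self.rgb_chain.append(rb)
                self.flow_chain.append(fb)
                rs, fs = rb.out_shape(rs), fb.out_shape(fs)
                self._module_shapes.append((*rs[:3], rs[3] + fs[3]))
            cat = rs[3] + fs[3]
            self.final_block = blk(cat, 5, wcfg["final_standalone"],
                                   (_tstride(rs[0]), 2, 2))
            shape = self.final_block.out_shape((*rs[:3], cat))
        self._module_shapes.append(shape)
        self.fc = FCStack(int(np.prod(shape)), spec.fc_units, activation="relu")

    def forward(self, rgb, flow, train=False):
        rng = self._rng
        crop = self.crop
        b = rgb.shape[0]
        self.traced_module_shapes = []
        if self.spec.variant == "sharing":
            run = concat([self.rgb1(rgb, train, rng),
                          self.flow1(flow, train, rng)], axis=-1)
            self.traced_module_shapes.append(tuple(run.shape[1:]))
            flow_src = flow[:, crop:flow.shape[1] - crop] if crop else flow
            for rb, tb in zip(self.run_blocks, self.tap_blocks):
                run = concat([rb(run, train, rng),
                              tb(flow_src, train, rng)], axis=-1)
                self.traced_module_shapes.append(tuple(run.shape[1:]))
            out = self.final_block(run, train, rng)
        else:
            x_r, x_f = rgb, flow
            for rb, fb in zip(self.rgb_chain, self.flow_chain):
                x_r = rb(x_r, train, rng)
                x_f = fb(x_f, train, rng)
                self.traced_module_shapes.append(
                    (*x_r.shape[1:4], x_r.shape[4] + x_f.shape[4]))
            out = self.final_block(concat([x_r, x_f], axis=-1), train, rng)
        self.traced_module_shapes.append(tuple(out.shape[1:]))
        return self.fc(out.reshape(b, -1))


# ---------------------------------------------------------------------------
# CRS (Cross Reinforced Streams)
# ---------------------------------------------------------------------------

class CRSModel(DualStreamModel):
    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        T, H, W, C = spec.input_shape
        sharing = spec.variant == "sharing"
        n, k = spec.n, spec.k
        rws = spec.widths["stream" if sharing else "stream_standalone"]

        def blk(cin, i, stride):
            cfg = BlockConfig(n[i], k[i], 3, spec.dropout_rate)
            return InceptionV13DBlock(cin, cfg, rws[i][0], rws[i][1], stride,
                                      activation="relu")

        self.blocks_a, self.blocks_b = [], []
        shape = (T, H, W, C)
        ba = blk(C, 0, (1, 1, 1))
        bb = blk(spec.flow_channels, 0, (1, 1, 1))
        self.blocks_a.append(ba)
        self.blocks_b.append(bb)
        sa = ba.out_shape(shape)
        self._module_shapes.append((*sa[:3], 2 * sa[3]))
        prev_w = sa[3]
        cur = (*sa[:3], 2 * sa[3])
        for i in range(1, len(n)):
            cin = cur[3] + prev_w if sharing else prev_w
            stride = (_tstride(cur[0]), 2, 2)
            ba = blk(cin, i, stride)
            bb = blk(cin, i, stride)
            self.blocks_a.append(ba)
            self.blocks_b.append(bb)
            sa = ba.out_shape((cur[0], cur[1], cur[2], cin))
            prev_w = sa[3]
            cur = (*sa[:3], 2 * sa[3])
            self._module_shapes.append(cur)
        # spatial average-pool down to the common 1x3x4-style grid, then FC
        self.pool_stride = (1, 2, 2)
        pooled = tuple(-(-cur[d] // self.pool_stride[d]) for d in range(3))
        self.fc = FCStack(int(np.prod(pooled)) * cur[3], spec.fc_units,
                          activation="relu")

    def forward(self, rgb, flow, train=False):
        rng = self._rng
        sharing = self.spec.variant == "sharing"
        b = rgb.shape[0]
        self.traced_module_shapes = []
        x_a = self.blocks_a[0](rgb, train, rng)
        x_b = self.blocks_b[0](flow, train, rng)
        joint = concat([x_a, x_b], axis=-1)
        self.traced_module_shapes.append(tuple(joint.shape[1:]))
        for i in range(1, len(self.blocks_a)):
            if sharing:
                in_a = concat([joint, x_b], axis=-1)
                in_b = concat([joint, x_a], axis=-1)
            else:
                in_a, in_b = x_a, x_b
            x_a = self.blocks_a[i](in_a, train, rng)
            x_b = self.blocks_b[i](in_b, train, rng)
            joint = concat([x_a, x_b], axis=-1)
            self.traced_module_shapes.append(tuple(joint.shape[1:]))
        pooled = pool3d(joint, self.pool_stride, self.pool_stride, mode="avg")
        return self.fc(pooled.reshape(b, -1))


# ---------------------------------------------------------------------------
# Public builders and accounting
# ---------------------------------------------------------------------------

_BUILDERS = {
    "baseline": BaselineModel,
    "civ3d_mha": CIv3DModel,
    "civ3d_bilstm": CIv3DModel,
    "srs": SRSModel,
    "crs": CRSModel,
}


def build_model(spec: ModelSpec) -> DualStreamModel:
    """Build the (uninitialized) network described by ``spec``."""
    return _BUILDERS[spec.name](spec)


def build_srs(spec: ModelSpec) -> SRSModel:
    if spec.name != "srs":
        raise ValueError("build_srs requires spec.name == 'srs'")
    return SRSModel(spec)


def build_crs(spec: ModelSpec) -> CRSModel:
    if spec.name != "crs":
        raise ValueError("build_crs requires spec.name == 'crs'")
    return CRSModel(spec)


def count_parameters(model: DualStreamModel) -> int:
    """Total trainable scalars, including biases and norm parameters."""
    return model.param_count()


def count_flops(model: DualStreamModel) -> float:
    """Twice the MAC-bearing trainable-parameter count.

    This is the accounting convention of the published complexity table for
    the non-recurrent models; it is not a per-inference dense-FLOP count, and
    the published BiLSTM figure follows a different (unstated) convention.
    """
    return 2.0 * count_parameters(model)


def layer_output_shapes(model: DualStreamModel) -> list:
    """(T,H,W,C) at each stacked-module exit (the stream-combination point)."""
    return model.module_shapes()


def account(spec_or_model) -> ModelAccount:
    model = build_model(spec_or_model) if isinstance(spec_or_model, ModelSpec) \
        else spec_or_model
    return ModelAccount(count_parameters(model), count_flops(model),
                        layer_output_shapes(model))
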