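"""Network building blocks: shapes, closed-form identities, oracles."""
import numpy as np
import pytest

from cagenet.blocks import (
    AttentionBlock, AttentionConfig, BlockConfig, BiLSTMHead,
    DenseDropoutJoint, InceptionV13DBlock, InceptionV3DBlock,
    PrimaryConvBlock, attention, BLOCK_REGISTRY,
)
from cagenet.nn.engine import Tensor, concat, pool3d
from cagenet.nn.layers import BiLSTM, Dense, MultiHeadAttention


def _init(layer, seed=0):
    rng = np.random.default_rng(seed)
    for p in layer.parameters():
        p.materialize(rng)
    return layer


class TestPrimaryConvBlock:
    def test_first_module_geometry(self):
        """Block 1 (n=16, k=1.5) maps 8x96x128x3 to 4x24x32x24."""
        blk = PrimaryConvBlock(3, BlockConfig(16, 1.5, 5),
                               strides=((2, 2, 2), (1, 2, 2)))
        assert blk.out_shape((8, 96, 128, 3)) == (4, 24, 32, 24)
        _init(blk)
        out = blk(Tensor(np.random.default_rng(0).random((1, 8, 96, 128, 3))))
        assert out.shape == (1, 4, 24, 32, 24)

    def test_inference_is_deterministic(self):
        blk = _init(PrimaryConvBlock(3, BlockConfig(4, 1.5, 3, dropout_rate=0.0)))
        x = Tensor(np.random.default_rng(1).random((2, 4, 8, 8, 3)))
        a = blk(x, train=False).data
        b = blk(x, train=False).data
        np.testing.assert_array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BlockConfig(0, 1.5, 3)
        with pytest.raises(ValueError):
            BlockConfig(4, 1.5, 4)     # even kernel
        with pytest.raises(ValueError):
            BlockConfig(4, 1.5, 3, dropout_rate=1.0)


class TestInceptionBlocks:
    def test_v1_output_channels_sum_branches(self):
        blk = InceptionV13DBlock(6, BlockConfig(8, 1.5, 3), r1=8, r2=4)
        assert blk.cout == 3 * 12
        _init(blk)
        out = blk(Tensor(np.random.default_rng(0).random((1, 2, 4, 4, 6))))
        assert out.shape[-1] == 36

    def test_v1_matches_branchwise_reference(self):
        """Equivalence with manual branch-by-branch composition on a toy input."""
        blk = _init(InceptionV13DBlock(2, BlockConfig(2, 1.0, 3), r1=2, r2=2))
        x = Tensor(np.random.default_rng(3).random((1, 2, 4, 4, 2)))

        from cagenet.nn.engine import conv3d

        def branch(red, bn_r, conv, bn_c):
            h = bn_r(conv3d(x, red.w.tensor, red.b.tensor, (1, 1, 1)),
                     False).relu()
            return bn_c(conv3d(h, conv.w.tensor, conv.b.tensor,
                               conv.stride), False).relu()

        a = branch(blk.red1, blk.bn_r1, blk.conv3, blk.bn3)
        b = branch(blk.red2, blk.bn_r2, blk.conv5, blk.bn5)
        p = pool3d(x, (3, 3, 3), (1, 1, 1), "max")
        p = blk.bn_p(conv3d(p, blk.pool_proj.w.tensor, blk.pool_proj.b.tensor,
                            (1, 1, 1)), False).relu()
        ref = concat([a, b, p], axis=-1)
        np.testing.assert_allclose(blk(x).data, ref.data, rtol=1e-5)

    def test_v3d_zero_input_zero_conv_branches(self):
        """With zero betas, conv branches of a zero input stay zero pre-norm."""
        blk = _init(InceptionV3DBlock(6, (2, 2, 2), r1=4, r2=4, s=4))
        x = Tensor(np.zeros((1, 2, 4, 4, 6)))
        out = blk(x, train=False)
        assert np.isfinite(out.data).all()
        assert blk.cout == 6

    def test_registry_exposes_all_blocks(self):
        assert set(BLOCK_REGISTRY) == {"primary", "inception_v3d",
                                       "inception_v1_3d", "dense_joint",
                                       "mha", "bilstm"}


class TestDenseDropoutJoint:
    def test_zero_flow_is_additive_identity(self):
        joint = _init(DenseDropoutJoint(6, 4, dropout_rate=0.0))
        x = Tensor(np.random.default_rng(0).random((2, 2, 3, 3, 6)))
        z = Tensor(np.zeros_like(x.data))
        np.testing.assert_allclose(joint.joint(x, z).data, joint(x).data,
                                   rtol=1e-6)

    def test_sum_commutes(self):
        joint = _init(DenseDropoutJoint(6, 4, dropout_rate=0.0))
        r = np.random.default_rng(1)
        a = Tensor(r.random((1, 2, 2, 2, 6)))
        b = Tensor(r.random((1, 2, 2, 2, 6)))
        np.testing.assert_allclose(joint.joint(a, b).data,
                                   joint.joint(b, a).data, rtol=1e-6)

    def test_shape_mismatch_rejected(self):
        joint = _init(DenseDropoutJoint(6, 4))
        with pytest.raises(ValueError):
            joint.joint(Tensor(np.zeros((1, 2, 2, 2, 6))),
                        Tensor(np.zeros((1, 2, 2, 3, 6))))


class TestAttention:
    def test_uniform_weights_when_keys_identical(self):
        """All-identical keys give uniform weights; output = column mean of V."""
        q = Tensor(np.random.default_rng(0).normal(0, 1, (3, 2)))
        k = Tensor(np.ones((4, 2)))
        v = Tensor(np.arange(8.0).reshape(4, 2))
        out = attention(q, k, v, d_k=2)
        np.testing.assert_allclose(out.data,
                                   np.tile(v.data.mean(axis=0), (3, 1)),
                                   rtol=1e-5)

    def test_hand_evaluated_softmax_case(self):
        """Q=[[1,0]], K=V=I2, sqrt(2) scaling: output [sigma, 1-sigma]."""
        out = attention(Tensor([[1.0, 0.0]]), Tensor(np.eye(2)),
                        Tensor(np.eye(2)), d_k=2)
        sigma = np.exp(1 / np.sqrt(2)) / (np.exp(1 / np.sqrt(2)) + 1)
        np.testing.assert_allclose(out.data, [[sigma, 1 - sigma]], atol=1e-6)
        assert abs(sigma - 0.670) < 1e-3

    def test_rows_normalize_and_shift_invariant(self):
        r = np.random.default_rng(2)
        q, k = Tensor(r.normal(0, 1, (5, 3))), Tensor(r.normal(0, 1, (6, 3)))
        v = Tensor(np.eye(6))
        w = attention(q, k, v, d_k=3).data     # V=I makes output = weights
        np.testing.assert_allclose(w.sum(axis=1), np.ones(5), rtol=1e-5)
        shifted = attention(q + Tensor(np.zeros((5, 3))), k, v, d_k=3).data
        np.testing.assert_allclose(w, shifted, rtol=1e-5)

    def test_dk_scale_switch(self):
        q = Tensor([[1.0, 0.0]])
        by_dk = attention(q, Tensor(np.eye(2)), Tensor(np.eye(2)), 2, scale="dk")
        sigma = np.exp(0.5) / (np.exp(0.5) + 1)
        np.testing.assert_allclose(by_dk.data, [[sigma, 1 - sigma]], atol=1e-6)

    def test_invalid_dk(self):
        with pytest.raises(ValueError):
            attention(Tensor(np.eye(2)), Tensor(np.eye(2)), Tensor(np.eye(2)), 0)

    def test_single_head_with_identity_projections(self):
        mha = MultiHeadAttention(3, 3, heads=1)
        _init(mha)
        eye = np.eye(3)
        for layer in (mha.wq[0], mha.wk[0], mha.wv[0], mha.wo):
            layer.w.tensor = Tensor(eye, requires_grad=True)
            layer.b.tensor = Tensor(np.zeros(3), requires_grad=True)
        x = Tensor(np.random.default_rng(4).normal(0, 1, (2, 4, 3)))
        single = attention(x, x, x, d_k=3)
        np.testing.assert_allclose(mha(x).data, single.data, rtol=1e-5)

    def test_attention_block_preserves_shape(self):
        blk = _init(AttentionBlock(tokens=12, cfg=AttentionConfig(8, 4, 2)))
        x = Tensor(np.random.default_rng(5).random((2, 1, 3, 4, 8)))
        assert blk(x, train=False).shape == x.shape


class TestBiLSTMHead:
    def test_sequence_reversal_swaps_state_roles(self):
        rnn = _init(BiLSTM(5, 3))
        x = np.random.default_rng(0).normal(0, 1, (2, 4, 5))
        fwd = rnn(Tensor(x)).data
        # reversing time: forward pass sees the old backward sequence
        bwd_first = BiLSTM(5, 3)
        bwd_first.fwd, bwd_first.bwd = rnn.bwd, rnn.fwd
        out_rev = bwd_first(Tensor(x[:, ::-1])).data
        np.testing.assert_allclose(fwd[:, :3], out_rev[:, 3:], rtol=1e-5)
        np.testing.assert_allclose(fwd[:, 3:], out_rev[:, :3], rtol=1e-5)

    def test_zero_weights_zero_output(self):
        rnn = BiLSTM(4, 3)
        for p in rnn.parameters():
            p.materialize(np.random.default_rng(0))
            p.tensor = Tensor(np.zeros(p.shape), requires_grad=True)
        out = rnn(Tensor(np.random.default_rng(1).normal(0, 1, (2, 3, 4))))
        np.testing.assert_array_equal(out.data, 0)

    def test_single_step_duplicates_state(self):
        """For length-1 sequences both directions see the same input."""
        rnn = BiLSTM(4, 3)
        rng = np.random.default_rng(2)
        rnn.fwd.w.materialize(rng)
        # share weights across directions
        for a, b in ((rnn.fwd.u, rnn.bwd.u), (rnn.fwd.b, rnn.bwd.b),
                     (rnn.fwd.w, rnn.bwd.w)):
            a.materialize(rng)
            b.tensor = a.tensor
        out = rnn(Tensor(rng.normal(0, 1, (2, 1, 4)))).data
        np.testing.assert_allclose(out[:, :3], out[:, 3:], rtol=1e-6)

    def test_head_flattens_positions(self):
        head = _init(BiLSTMHead(6, 4))
        x = Tensor(np.random.default_rng(3).random((2, 1, 3, 4, 6)))
        assert head(x).shape == (2, 8)
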