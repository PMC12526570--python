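"""Attention-primitive contracts: row-stochastic weights, closed-form
two-way softmax, a literal two-loop oracle, single-head reduction of
multi-head attention, normalization algebra of the residual layer-norm
wrapper, channel-attention gates and the convex fusion gate."""

import numpy as np
import pytest

from ppgrhythm.attention import (
    AttentionConfig,
    ChannelAttention,
    GatedFusion,
    MultiHeadAttention,
    ResidualLayerNorm,
    scaled_dot_attention,
)
from ppgrhythm.exceptions import InvalidParameterError, ShapeError
from ppgrhythm.nn.autograd import Tensor


def two_loop_attention(q, k, v):
    """Literal oracle: explicit loops, per-row softmax, weighted sum."""
    nq, dk = q.shape
    nk = k.shape[0]
    weights = np.zeros((nq, nk))
    for i in range(nq):
        scores = np.array([q[i] @ k[j] / np.sqrt(dk) for j in range(nk)])
        e = np.exp(scores - scores.max())
        weights[i] = e / e.sum()
    return weights @ v, weights


class TestScaledDotAttention:
    def test_weight_rows_sum_to_one(self, rng):
        q, k, v = (rng.normal(size=(5, 8)) for _ in range(3))
        _, w = scaled_dot_attention(q, k, v)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_keys_give_column_mean_of_values(self, rng):
        q = rng.normal(size=(3, 4))
        k = np.tile(rng.normal(size=(1, 4)), (6, 1))
        v = rng.normal(size=(6, 7))
        out, _ = scaled_dot_attention(q, k, v)
        assert np.allclose(out, np.tile(v.mean(axis=0), (3, 1)))

    def test_two_way_softmax_closed_form(self):
        """Scores (s, s + sqrt(d_k)) put sigmoid(1) on the second key."""
        dk = 16
        q = np.zeros((1, dk))
        q[0, 0] = 1.0
        k = np.zeros((2, dk))
        k[0, 0] = 2.0
        k[1, 0] = 2.0 + np.sqrt(dk)
        v = np.eye(2, 3)
        _, w = scaled_dot_attention(q, k, v)
        assert w[0, 1] == pytest.approx(0.7310585786, abs=1e-9)

    def test_matches_two_loop_oracle(self, rng):
        for _ in range(20):
            q, k = rng.normal(size=(2, 4, 4)), rng.normal(size=(4, 4))
            v = rng.normal(size=(4, 4))
            out, w = scaled_dot_attention(q[0], k, v)
            out_o, w_o = two_loop_attention(q[0], k, v)
            assert np.allclose(out, out_o, atol=1e-8)
            assert np.allclose(w, w_o, atol=1e-8)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            scaled_dot_attention(rng.normal(size=(2, 3)),
                                 rng.normal(size=(2, 4)),
                                 rng.normal(size=(2, 4)))
        with pytest.raises(ShapeError):
            scaled_dot_attention(rng.normal(size=(2, 3)),
                                 rng.normal(size=(4, 3)),
                                 rng.normal(size=(5, 3)))


class TestMultiHeadAttention:
    def _identity_mha(self, d):
        mha = MultiHeadAttention(d, 1, np.random.default_rng(0), dropout=0.0)
        for dense in (mha.wq, mha.wk, mha.wv, mha.wo):
            dense.w.data = np.eye(d)
            dense.b.data = np.zeros(d)
        return mha

    def test_identity_projections_reduce_to_eq1(self, rng):
        d = 6
        mha = self._identity_mha(d).eval()
        q, k, v = (rng.normal(size=(1, 5, d)) for _ in range(3))
        out = mha(Tensor(q), Tensor(k), Tensor(v)).data[0]
        expected, _ = scaled_dot_attention(q[0], k[0], v[0])
        assert np.allclose(out, expected, atol=1e-6)

    def test_single_head_equals_projected_eq1(self, rng):
        d = 8
        mha = MultiHeadAttention(d, 1, np.random.default_rng(3),
                                 dropout=0.0).eval()
        x = rng.normal(size=(1, 4, d))
        out = mha(Tensor(x), Tensor(x), Tensor(x)).data[0]
        qp = x[0] @ mha.wq.w.data + mha.wq.b.data
        kp = x[0] @ mha.wk.w.data + mha.wk.b.data
        vp = x[0] @ mha.wv.w.data + mha.wv.b.data
        att, _ = scaled_dot_attention(qp, kp, vp)
        expected = att @ mha.wo.w.data + mha.wo.b.data
        assert np.allclose(out, expected, atol=1e-8)

    def test_invariant_to_joint_key_value_permutation(self, rng):
        d = 8
        mha = MultiHeadAttention(d, 4, np.random.default_rng(1),
                                 dropout=0.0).eval()
        q = rng.normal(size=(1, 3, d))
        kv = rng.normal(size=(1, 6, d))
        perm = rng.permutation(6)
        a = mha(Tensor(q), Tensor(kv), Tensor(kv)).data
        b = mha(Tensor(q), Tensor(kv[:, perm]), Tensor(kv[:, perm])).data
        assert np.allclose(a, b, atol=1e-10)

    def test_equivariant_to_query_permutation(self, rng):
        d = 8
        mha = MultiHeadAttention(d, 2, np.random.default_rng(2),
                                 dropout=0.0).eval()
        q = rng.normal(size=(1, 5, d))
        kv = rng.normal(size=(1, 4, d))
        perm = rng.permutation(5)
        a = mha(Tensor(q), Tensor(kv), Tensor(kv)).data[:, perm]
        b = mha(Tensor(q[:, perm]), Tensor(kv), Tensor(kv)).data
        assert np.allclose(a, b, atol=1e-10)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(InvalidParameterError):
            MultiHeadAttention(10, 4, np.random.default_rng(0))
        with pytest.raises(InvalidParameterError):
            AttentionConfig(d_model=10, n_heads=4).validate()


class TestResidualLayerNorm:
    def test_negated_sublayer_returns_affine_bias(self, rng):
        d = 6
        layer = ResidualLayerNorm(d)
        x = Tensor(rng.normal(size=(1, 3, d)))
        minus = Tensor(-x.data)
        out = layer(x, minus).data
        assert np.allclose(out, np.broadcast_to(layer.norm.beta.data,
                                                out.shape))

    def test_pre_affine_rows_standardized(self, rng):
        d = 10
        layer = ResidualLayerNorm(d)
        x = Tensor(rng.normal(size=(2, 4, d)))
        s = Tensor(rng.normal(size=(2, 4, d)))
        pre = layer.norm.normalized(x + s).data
        assert np.allclose(pre.mean(axis=-1), 0.0, atol=1e-6)
        assert np.allclose(pre.var(axis=-1), 1.0, atol=1e-3)

    def test_scale_invariance_of_pre_affine_output(self, rng):
        d = 8
        layer = ResidualLayerNorm(d)
        x = rng.normal(size=(1, 3, d))
        s = rng.normal(size=(1, 3, d))
        a = layer.norm.normalized(Tensor(x) + Tensor(s)).data
        c = 37.5
        b = layer.norm.normalized(Tensor(c * x) + Tensor(c * s)).data
        assert np.allclose(a, b, atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        layer = ResidualLayerNorm(4)
        with pytest.raises(ShapeError):
            layer(Tensor(rng.normal(size=(1, 3, 4))),
                  Tensor(rng.normal(size=(1, 2, 4))))


class TestChannelAttention:
    def test_gates_strictly_inside_unit_interval(self, rng):
        ca = ChannelAttention(8, 4, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 5, 8)))
        g = ca.gates(x).data
        assert np.all(g > 0) and np.all(g < 1)
        out = ca(x).data
        assert np.all(np.abs(out) <= np.abs(x.data))

    def test_zero_input_gives_zero_output(self):
        ca = ChannelAttention(8, 2, np.random.default_rng(1))
        out = ca(Tensor(np.zeros((1, 4, 8)))).data
        assert np.allclose(out, 0.0)

    def test_zeroed_expand_weights_scale_by_sigmoid_bias(self, rng):
        ca = ChannelAttention(8, 4, np.random.default_rng(2))
        ca.expand.w.data[:] = 0.0
        bias = 0.7
        ca.expand.b.data[:] = bias
        x = Tensor(rng.normal(size=(1, 5, 8)))
        out = ca(x).data
        expected = x.data / (1 + np.exp(-bias))
        assert np.allclose(out, expected, atol=1e-12)

    def test_reduction_exceeding_channels_rejected(self):
        with pytest.raises(InvalidParameterError):
            ChannelAttention(4, 8, np.random.default_rng(0))


class TestGatedFusion:
    def test_saturated_gate_selects_first_stream(self, rng):
        gf = GatedFusion(6, np.random.default_rng(0))
        gf.gate.w.data[:] = 0.0
        gf.gate.b.data[:] = 50.0  # sigmoid ~= 1
        a = Tensor(rng.normal(size=(1, 3, 6)))
        b = Tensor(rng.normal(size=(1, 3, 6)))
        assert np.allclose(gf(a, b).data, a.data, atol=1e-12)

    def test_equal_streams_are_fixed_point(self, rng):
        gf = GatedFusion(6, np.random.default_rng(1))
        a = Tensor(rng.normal(size=(2, 3, 6)))
        assert np.allclose(gf(a, a).data, a.data, atol=1e-12)

    def test_output_elementwise_between_inputs(self, rng):
        gf = GatedFusion(5, np.random.default_rng(2))
        a = Tensor(rng.normal(size=(2, 4, 5)))
        b = Tensor(rng.normal(size=(2, 4, 5)))
        out = gf(a, b).data
        lo = np.minimum(a.data, b.data)
        hi = np.maximum(a.data, b.data)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_shape_mismatch_raises(self, rng):
        gf = GatedFusion(5, np.random.default_rng(3))
        with pytest.raises(ShapeError):
            gf(Tensor(rng.normal(size=(1, 3, 5))),
               Tensor(rng.normal(size=(1, 4, 5))))
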