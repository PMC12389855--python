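"""CDA layer: atrous pyramid branches and spatial-pooling cross-attention
against explicit-loop oracles."""

import numpy as np
import pytest

import tacpose as tp
from tacpose import nn
from tacpose.cda import CDAConfig, CDALayer, CrossAttention, PyramidalPool
from tacpose.nn import Tensor


def _rng():
    return np.random.default_rng(0)


def dilated_conv_loop(x, w, dilation):
    """Direct-summation 'same' dilated cross-correlation, zero padding.

    x: [C, H, W]; w: [O, C, 3, 3].
    """
    C, H, W = x.shape
    O = w.shape[0]
    out = np.zeros((O, H, W))
    for o in range(O):
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for c in range(C):
                    for a in range(3):
                        for b in range(3):
                            ii = i + (a - 1) * dilation
                            jj = j + (b - 1) * dilation
                            if 0 <= ii < H and 0 <= jj < W:
                                acc += x[c, ii, jj] * w[o, c, a, b]
                out[o, i, j] = acc
    return out


def attention_loop_qkv(q, k, v):
    """softmax(q kᵀ / sqrt(d)) v with explicit loops; q:[Tq,d] k,v:[Tk,d]."""
    d = q.shape[1]
    out = np.zeros((q.shape[0], v.shape[1]))
    for i in range(q.shape[0]):
        logits = np.array([q[i] @ k[j] / np.sqrt(d) for j in range(k.shape[0])])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        out[i] = sum(w[j] * v[j] for j in range(k.shape[0]))
    return out


def zero_biases(module: nn.Module):
    for key, arr in module.named_state().items():
        if key.endswith("bias") or key.endswith("beta"):
            arr[...] = 0.0


class TestConfig:
    def test_rates_must_increase(self):
        with pytest.raises(ValueError):
            CDAConfig(atrous_rates=(2, 2, 4))

    def test_channels_divisible_by_heads(self):
        with pytest.raises(ValueError):
            CDAConfig(channels=10, n_heads=4)


class TestPyramidalPool:
    def test_zero_input_zero_output_without_biases(self):
        cfg = CDAConfig(channels=4, n_heads=2)
        pp = PyramidalPool(cfg, _rng())
        zero_biases(pp)
        out = pp(Tensor(np.zeros((1, 4, 20, 20))))
        np.testing.assert_allclose(out.data, 0.0)

    def test_single_branch_matches_loop_oracle(self):
        cfg = CDAConfig(atrous_rates=(2,), channels=1, n_heads=1)
        pp = PyramidalPool(cfg, _rng())
        zero_biases(pp)
        x = np.random.default_rng(3).normal(size=(1, 9, 9))
        out = pp(Tensor(x[None]))
        branch = dilated_conv_loop(x, pp.branches[0].weight.data, 2)
        # 1x1 projection of the single branch
        expected = pp.project.weight.data[0, 0, 0, 0] * branch
        np.testing.assert_allclose(out.data[0], expected, atol=1e-10)

    def test_too_small_input_reports_minimum_size(self):
        cfg = CDAConfig(channels=2, n_heads=2)
        pp = PyramidalPool(cfg, _rng())
        with pytest.raises(ValueError, match="minimum input size is 17x17"):
            pp(Tensor(np.zeros((1, 2, 10, 10))))

    def test_preserves_spatial_shape(self):
        cfg = CDAConfig(channels=4, n_heads=2)
        pp = PyramidalPool(cfg, _rng())
        out = pp(Tensor(np.random.default_rng(0).normal(size=(2, 4, 24, 18))))
        assert out.shape == (2, 4, 24, 18)


class TestCrossAttention:
    def test_constant_kv_gives_mean_value_plus_residual(self):
        cfg = CDAConfig(channels=4, n_heads=2, pool_size=2)
        ca = CrossAttention(cfg, _rng())
        zero_biases(ca)
        q = np.random.default_rng(1).normal(size=(1, 4, 8, 8))
        kv = np.ones((1, 4, 8, 8))  # all kv tokens identical -> uniform softmax
        out, w = ca(Tensor(q), Tensor(kv), return_weights=True)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        # every row of attention over identical tokens is uniform
        np.testing.assert_allclose(w, 1.0 / w.shape[-1], atol=1e-12)

    def test_single_token_kv_broadcasts_value(self):
        cfg = CDAConfig(channels=4, n_heads=1, pool_size=8)
        ca = CrossAttention(cfg, _rng())
        zero_biases(ca)
        q = np.random.default_rng(2).normal(size=(1, 4, 8, 8))
        kv = np.random.default_rng(3).normal(size=(1, 4, 8, 8))
        out = ca(Tensor(q), Tensor(kv))
        # pooled to a single token: attention output = Wo(Wv(token)), same everywhere
        attn_part = out.data - q
        flat = attn_part.reshape(4, -1)
        np.testing.assert_allclose(flat, np.broadcast_to(flat[:, :1], flat.shape), atol=1e-10)

    def test_matches_explicit_loop_attention(self):
        cfg = CDAConfig(channels=6, n_heads=1, pool_size=2)
        ca = CrossAttention(cfg, _rng())
        zero_biases(ca)
        rng = np.random.default_rng(4)
        q_map = rng.normal(size=(1, 6, 4, 4))
        kv_map = rng.normal(size=(1, 6, 4, 4))
        out = ca(Tensor(q_map), Tensor(kv_map))
        # oracle: pool kv 2x2 -> 4 tokens, 16 query tokens, explicit loops
        kv_pool = kv_map.reshape(1, 6, 2, 2, 2, 2).mean(axis=(3, 5))
        q_tok = q_map.reshape(6, 16).T @ ca.wq.weight.data
        k_tok = kv_pool.reshape(6, 4).T @ ca.wk.weight.data
        v_tok = kv_pool.reshape(6, 4).T @ ca.wv.weight.data
        att = attention_loop_qkv(q_tok, k_tok, v_tok) @ ca.wo.weight.data
        expected = q_map[0] + att.T.reshape(6, 4, 4)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-5)

    def test_key_permutation_invariance(self):
        cfg = CDAConfig(channels=4, n_heads=2, pool_size=1)
        ca = CrossAttention(cfg, _rng())
        rng = np.random.default_rng(5)
        q = Tensor(rng.normal(size=(1, 4, 3, 3)))
        kv = rng.normal(size=(1, 4, 3, 3))
        out1 = ca(q, Tensor(kv)).data
        perm = rng.permutation(9)
        kv_p = kv.reshape(1, 4, 9)[:, :, perm].reshape(1, 4, 3, 3)
        out2 = ca(q, Tensor(kv_p)).data
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        cfg = CDAConfig(channels=4, n_heads=2)
        ca = CrossAttention(cfg, _rng())
        with pytest.raises(ValueError, match="share"):
            ca(Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 4, 6, 8))))


class TestCDALayer:
    def test_zero_mask_zero_bias_returns_pressure_stem(self):
        cfg = CDAConfig(channels=8, n_heads=2, pool_size=4)
        layer = CDALayer(cfg, _rng())
        zero_biases(layer)
        p = np.random.default_rng(6).normal(size=(1, 32, 20))
        out = layer(Tensor(p), Tensor(np.zeros((1, 32, 20))), t=None)
        stem = layer.stem_p(Tensor(p.reshape(1, 1, 32, 20)))
        np.testing.assert_allclose(out.data, stem.data, atol=1e-10)

    def test_output_shape_contract(self):
        cfg = CDAConfig(channels=8, n_heads=2, pool_size=4)
        layer = CDALayer(cfg, _rng())
        out = layer(Tensor(np.zeros((2, 24, 20))), Tensor(np.zeros((2, 24, 20))), t=3)
        assert out.shape == (2, 8, 24, 20)

    def test_mask_stream_off_ignores_mask(self):
        cfg = CDAConfig(channels=8, n_heads=2)
        layer = CDALayer(cfg, _rng(), use_mask_stream=False)
        p = Tensor(np.random.default_rng(7).normal(size=(1, 20, 20)))
        a = layer(p, Tensor(np.zeros((1, 20, 20))), t=1).data
        b = layer(p, Tensor(np.ones((1, 20, 20))), t=1).data
        np.testing.assert_array_equal(a, b)
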