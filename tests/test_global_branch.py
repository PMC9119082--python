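"""Attention semantics against brute-force oracles; tokenization geometry."""

import numpy as np
import pytest

from llrhnet.global_branch import (
    GlobalBranch,
    MultiHeadSelfAttention,
    TransformerConfig,
    TransformerLayer,
    attention_multi,
    attention_single,
    map_to_tokens_reshape,
    sinusoidal_encoding,
    token_count,
    tokens_to_map_reshape,
)
from llrhnet.nn import Tensor, no_grad
from llrhnet.nn.tensor import concat

import oracles
from conftest import tiny_transformer


class TestTokenization:
    @pytest.mark.parametrize("hw,p,n", [(512, 8, 4096), (128, 8, 256),
                                        (128, 16, 64), (128, 32, 16)])
    def test_token_count_formula(self, hw, p, n):
        assert token_count(hw, hw, p) == n

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            token_count(100, 100, 8)

    def test_patchify_shapes_and_positions(self):
        cfg = tiny_transformer(patch_size=8)
        gb = GlobalBranch(cfg, bottleneck_width=16, rng=np.random.default_rng(0))
        gb.eval()
        x = Tensor(np.random.default_rng(1).normal(size=(2, 1, 32, 32))
                   .astype(np.float32))
        with no_grad():
            seq = gb.patchify_embed(x)
        assert seq.data.shape == (2, 16, cfg.embed_width)
        # positional encoding is additive: zero image -> exactly the table
        with no_grad():
            z = gb.patchify_embed(Tensor(np.zeros((1, 1, 32, 32), np.float32)))
        bias = gb.embed.bias.data[None, :]
        np.testing.assert_allclose(
            z.data[0], sinusoidal_encoding(16, cfg.embed_width) + bias, atol=1e-6)

    def test_reshape_roundtrip_is_bijective(self, rng):
        seq = rng.normal(size=(12, 7))
        fmap = tokens_to_map_reshape(seq, (3, 4))
        assert fmap.shape == (7, 3, 4)
        assert np.array_equal(map_to_tokens_reshape(fmap), seq)
        # multiset of elements preserved by the reshape
        assert np.array_equal(np.sort(fmap.ravel()), np.sort(seq.ravel()))

    def test_tokens_to_map_resizes_to_eighth(self):
        cfg = tiny_transformer(patch_size=16)
        gb = GlobalBranch(cfg, bottleneck_width=24, rng=np.random.default_rng(0))
        gb.eval()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 1, 128, 128))
                   .astype(np.float32))
        with no_grad():
            out = gb(x)
        assert out.data.shape == (1, 24, 16, 16)

    def test_token_count_mismatch_rejected(self):
        cfg = tiny_transformer(patch_size=8)
        gb = GlobalBranch(cfg, bottleneck_width=8, rng=np.random.default_rng(0))
        seq = Tensor(np.zeros((1, 9, cfg.embed_width), dtype=np.float32))
        with pytest.raises(ValueError, match="token count"):
            gb.tokens_to_map(seq, (32, 32))


class TestAttention:
    def test_single_token_passthrough(self, rng):
        seq = Tensor(rng.normal(size=(1, 6)))
        wv = Tensor(rng.normal(size=(6, 4)))
        wq = Tensor(rng.normal(size=(6, 4)))
        wk = Tensor(rng.normal(size=(6, 4)))
        out, w = attention_single(seq, wq, wk, wv)
        np.testing.assert_allclose(out.data, seq.data @ wv.data, atol=1e-12)
        assert w.data.shape == (1, 1) and w.data[0, 0] == 1.0

    def test_identical_keys_average_values(self, rng):
        seq = Tensor(np.ones((5, 6)))  # all tokens identical -> uniform softmax
        wq = Tensor(rng.normal(size=(6, 3)))
        wk = Tensor(rng.normal(size=(6, 3)))
        wv = Tensor(rng.normal(size=(6, 3)))
        out, w = attention_single(seq, wq, wk, wv)
        np.testing.assert_allclose(w.data, np.full((5, 5), 0.2), atol=1e-12)
        v = seq.data @ wv.data
        np.testing.assert_allclose(out.data, np.tile(v.mean(axis=0), (5, 1)),
                                   atol=1e-12)

    def test_matches_bruteforce_loop(self, rng):
        seq_np = rng.normal(size=(5, 8))
        wq, wk, wv = (rng.normal(size=(8, 4)) for _ in range(3))
        out, w = attention_single(Tensor(seq_np), Tensor(wq), Tensor(wk), Tensor(wv))
        ref_out, ref_w = oracles.brute_attention(seq_np, wq, wk, wv)
        np.testing.assert_allclose(out.data, ref_out, atol=1e-6)
        np.testing.assert_allclose(w.data, ref_w, atol=1e-6)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_mismatched_widths_rejected(self, rng):
        seq = Tensor(rng.normal(size=(3, 8)))
        with pytest.raises(ValueError, match="width"):
            attention_single(seq, Tensor(rng.normal(size=(8, 4))),
                             Tensor(rng.normal(size=(8, 5))),
                             Tensor(rng.normal(size=(8, 4))))

    def test_multi_head_single_head_reduction(self, rng):
        seq = rng.normal(size=(6, 8))
        wq, wk, wv = (rng.normal(size=(8, 8)) for _ in range(3))
        w_out = rng.normal(size=(8, 8))
        multi = attention_multi(Tensor(seq), [Tensor(wq)], [Tensor(wk)],
                                [Tensor(wv)], Tensor(w_out))
        single, _ = attention_single(Tensor(seq), Tensor(wq), Tensor(wk), Tensor(wv))
        np.testing.assert_allclose(multi.data, single.data @ w_out, atol=1e-10)

    def test_identity_projection_exposes_concatenation(self, rng):
        seq = rng.normal(size=(4, 6))
        heads = [[rng.normal(size=(6, 3)) for _ in range(3)] for _ in range(2)]
        outs = [oracles.brute_attention(seq, *h)[0] for h in heads]
        got = attention_multi(
            Tensor(seq),
            [Tensor(h[0]) for h in heads], [Tensor(h[1]) for h in heads],
            [Tensor(h[2]) for h in heads], Tensor(np.eye(6)))
        np.testing.assert_allclose(got.data, np.concatenate(outs, axis=-1),
                                   atol=1e-6)

    def test_four_head_compositional_oracle(self, rng):
        seq = rng.normal(size=(8, 16))
        heads = [[rng.normal(size=(16, 4)) for _ in range(3)] for _ in range(4)]
        w_out = rng.normal(size=(16, 16))
        got = attention_multi(
            Tensor(seq),
            [Tensor(h[0]) for h in heads], [Tensor(h[1]) for h in heads],
            [Tensor(h[2]) for h in heads], Tensor(w_out))
        ref = np.concatenate(
            [oracles.brute_attention(seq, *h)[0] for h in heads], axis=-1) @ w_out
        np.testing.assert_allclose(got.data, ref, atol=1e-6)

    def test_msa_module_rows_sum_to_one_and_equals_manual_heads(self, rng):
        cfg = TransformerConfig(patch_size=8, embed_width=16, n_layers=1,
                                n_heads=4, mlp_ratio=2)
        msa = MultiHeadSelfAttention(cfg, np.random.default_rng(3)).eval()
        x = rng.normal(size=(1, 6, 16)).astype(np.float64)
        with no_grad():
            got = msa(Tensor(x))
        # independent recomposition from the fused projection weights
        xq = x[0] @ msa.wq.weight.data + msa.wq.bias.data
        xk = x[0] @ msa.wk.weight.data + msa.wk.bias.data
        xv = x[0] @ msa.wv.weight.data + msa.wv.bias.data
        outs = []
        dh = 4
        for i in range(4):
            sl = slice(i * dh, (i + 1) * dh)
            s = xq[:, sl] @ xk[:, sl].T / np.sqrt(dh)
            e = np.exp(s - s.max(axis=-1, keepdims=True))
            w = e / e.sum(axis=-1, keepdims=True)
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
            outs.append(w @ xv[:, sl])
        ref = np.concatenate(outs, axis=-1) @ msa.w_out.weight.data \
            + msa.w_out.bias.data
        np.testing.assert_allclose(got.data[0], ref, atol=1e-6)


class TestTransformerLayer:
    def test_zeroed_sublayers_are_pure_residual(self, rng):
        cfg = TransformerConfig(patch_size=8, embed_width=12, n_layers=1,
                                n_heads=3, mlp_ratio=2)
        layer = TransformerLayer(cfg, np.random.default_rng(0)).eval()
        layer.msa.w_out.weight.data[:] = 0
        layer.msa.w_out.bias.data[:] = 0
        layer.fc2.weight.data[:] = 0
        layer.fc2.bias.data[:] = 0
        x = rng.normal(size=(2, 5, 12)).astype(np.float64)
        with no_grad():
            y = layer(Tensor(x))
        np.testing.assert_allclose(y.data, x, atol=1e-12)

    def test_shape_preserved_for_any_length(self, rng):
        cfg = TransformerConfig(patch_size=8, embed_width=8, n_layers=1,
                                n_heads=2, mlp_ratio=2)
        layer = TransformerLayer(cfg, np.random.default_rng(0)).eval()
        for n in (1, 3, 17):
            x = rng.normal(size=(1, n, 8)).astype(np.float32)
            with no_grad():
                assert layer(Tensor(x)).data.shape == (1, n, 8)

    def test_matches_stepwise_composition(self, rng):
        cfg = TransformerConfig(patch_size=8, embed_width=16, n_layers=1,
                                n_heads=2, mlp_ratio=2)
        layer = TransformerLayer(cfg, np.random.default_rng(1)).eval()
        x = rng.normal(size=(1, 7, 16)).astype(np.float64)
        with no_grad():
            got = layer(Tensor(x))
        # independent composition: LN -> MSA -> add; LN -> MLP -> add
        from scipy.special import erf
        ln1 = oracles.brute_layer_norm(x[0], layer.ln1.gamma.data,
                                       layer.ln1.beta.data)
        with no_grad():
            msa_out = layer.msa(Tensor(ln1[None])).data[0]
        xt = msa_out + x[0]
        ln2 = oracles.brute_layer_norm(xt, layer.ln2.gamma.data,
                                       layer.ln2.beta.data)
        h = ln2 @ layer.fc1.weight.data + layer.fc1.bias.data
        h = h * 0.5 * (1 + erf(h / np.sqrt(2)))
        mlp = h @ layer.fc2.weight.data + layer.fc2.bias.data
        np.testing.assert_allclose(got.data[0], mlp + xt, atol=1e-6)

    def test_permutation_equivariance_without_positions(self, rng):
        cfg = TransformerConfig(patch_size=8, embed_width=12, n_layers=1,
                                n_heads=3, mlp_ratio=2)
        layer = TransformerLayer(cfg, np.random.default_rng(2)).eval()
        x = rng.normal(size=(1, 6, 12)).astype(np.float64)
        perm = np.random.default_rng(9).permutation(6)
        with no_grad():
            y = layer(Tensor(x)).data
            y_perm = layer(Tensor(x[:, perm])).data
        np.testing.assert_allclose(y_perm, y[:, perm], atol=1e-10)


class TestConfigValidation:
    def test_head_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            TransformerConfig(embed_width=30, n_heads=4)

    def test_patch_size_domain(self):
        with pytest.raises(ValueError, match="patch size"):
            TransformerConfig(patch_size=7)
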