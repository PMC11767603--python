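"""Drug/target encoders: embeddings, conv branches, attention, transformer."""

import numpy as np
import pytest

from mcfdti.autograd import Tensor
from mcfdti.config import ModelConfig
from mcfdti.encoders import (
    ConvBranchParams,
    TargetEncoder,
    TransformerEncoder,
    adaptive_pool_matrix,
    align_time,
    conv_branch,
    embed,
    encode_drug,
    scaled_dot_attention,
    sinusoidal_positions,
)


class TestEmbed:
    def test_all_pad_input_repeats_pad_row(self, rng):
        table = Tensor(rng.normal(size=(5, 3)), requires_grad=True)
        idx = np.zeros((2, 4), dtype=np.int64)  # pad/unknown index is 0
        out = embed(idx, table)
        np.testing.assert_allclose(out.data,
                                   np.broadcast_to(table.data[0], (2, 4, 3)))

    def test_identity_table_yields_one_hot_rows(self):
        table = Tensor(np.eye(4))
        out = embed(np.array([[2, 0, 3]]), table)
        np.testing.assert_allclose(out.data[0], np.eye(4)[[2, 0, 3]])

    def test_distinct_tokens_get_distinct_rows(self, rng):
        table = Tensor(rng.normal(size=(6, 4)))
        out = embed(np.array([[1, 2]]), table)
        assert not np.allclose(out.data[0, 0], out.data[0, 1])

    def test_mask_zeroes_padded_positions(self, rng):
        table = Tensor(rng.normal(size=(6, 4)))
        mask = np.array([[1.0, 0.0]], dtype=np.float32)
        out = embed(np.array([[1, 2]]), table, mask)
        assert np.allclose(out.data[0, 1], 0.0)
        assert not np.allclose(out.data[0, 0], 0.0)


class TestConvBranch:
    def test_zero_input_zero_biases_gives_zero(self, rng):
        params = ConvBranchParams(rng, 3, (4, 5, 6), (3, 3, 3))
        out = conv_branch(Tensor(np.zeros((2, 7, 3))), params)
        np.testing.assert_allclose(out.data, 0.0)
        assert out.shape == (2, 7, 6)

    def test_scalar_chain_matches_hand_computation(self, rng):
        # T=1, kernel width 1, single channel: an affine/ReLU chain
        params = ConvBranchParams(rng, 1, (1, 1, 1), (1, 1, 1))
        w1, w2, w3 = 0.5, -2.0, 3.0
        b1, b2, b3 = 0.1, 0.7, -0.2
        for w, bias, val, bval in zip(params.weights, params.biases,
                                      (w1, w2, w3), (b1, b2, b3)):
            w.data = np.full((1, 1, 1), val, dtype=np.float32)
            bias.data = np.array([bval], dtype=np.float32)
        v = 1.3
        out = conv_branch(Tensor(np.full((1, 1, 1), v)), params)
        h1 = max(w1 * v + b1, 0.0)
        h2 = max(w2 * h1 + b2, 0.0)
        expected = w3 * h2 + b3  # no ReLU after the last layer
        np.testing.assert_allclose(out.data.ravel(), [expected], rtol=1e-6)

    def test_default_config_emits_96_channels(self, rng):
        cfg = ModelConfig()
        params = ConvBranchParams(rng, cfg.embed_dim, cfg.drug_conv_channels,
                                  cfg.drug_kernel_sizes)
        out = conv_branch(Tensor(np.zeros((1, 10, cfg.embed_dim))), params)
        assert out.shape[-1] == 96

    def test_negative_last_preactivation_survives(self, rng):
        # the final layer has no ReLU, so negative outputs are possible
        params = ConvBranchParams(rng, 1, (1, 1, 1), (1, 1, 1))
        for w, b in zip(params.weights, params.biases):
            w.data = np.ones((1, 1, 1), dtype=np.float32)
            b.data = np.zeros(1, dtype=np.float32)
        params.weights[2].data *= -1
        out = conv_branch(Tensor(np.ones((1, 1, 1))), params)
        assert out.data.ravel()[0] < 0


class TestEncodeDrug:
    def test_concatenates_branch_channels(self, rng):
        table = Tensor(rng.normal(size=(6, 4)), requires_grad=True)
        b1 = ConvBranchParams(rng, 4, (4, 4, 8), (3, 3, 3))
        b2 = ConvBranchParams(rng, 4, (4, 4, 8), (3, 3, 3))
        idx = rng.integers(0, 6, size=(2, 5))
        mask = np.ones((2, 5), dtype=np.float32)
        out = encode_drug(idx, mask, table, b1, b2)
        assert out.shape == (2, 5, 16)

    def test_shared_weights_give_identical_halves(self, rng):
        table = Tensor(rng.normal(size=(6, 4)))
        b1 = ConvBranchParams(rng, 4, (4, 4, 8), (3, 3, 3))
        idx = rng.integers(0, 6, size=(1, 5))
        mask = np.ones((1, 5), dtype=np.float32)
        out = encode_drug(idx, mask, table, b1, b1)
        np.testing.assert_allclose(out.data[..., :8], out.data[..., 8:])


class TestScaledDotAttention:
    def test_zero_queries_average_unmasked_values(self, rng):
        q = Tensor(np.zeros((2, 4)))
        k = Tensor(rng.normal(size=(3, 4)))
        v = Tensor(rng.normal(size=(3, 2)))
        out, attn = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out.data,
                                   np.broadcast_to(v.data.mean(axis=0), (2, 2)),
                                   rtol=1e-5, atol=1e-6)

    def test_single_unmasked_key_returns_its_value(self, rng):
        q = Tensor(rng.normal(size=(1, 2, 4)))
        k = Tensor(rng.normal(size=(1, 3, 4)))
        v = Tensor(rng.normal(size=(1, 3, 2)))
        mask = np.array([[0.0, 1.0, 0.0]], dtype=np.float32)
        out, _ = scaled_dot_attention(q, k, v, mask)
        np.testing.assert_allclose(
            out.data[0], np.broadcast_to(v.data[0, 1], (2, 2)), atol=1e-5)

    def test_two_key_softmax_matches_closed_form(self):
        # d_k = 1 so the scale is 1; logits are (2, 0)
        q = Tensor(np.array([[2.0]]))
        k = Tensor(np.array([[1.0], [0.0]]))
        v = Tensor(np.array([[1.0], [0.0]]))
        out, attn = scaled_dot_attention(q, k, v)
        w1 = np.exp(2.0) / (np.exp(2.0) + 1.0)
        np.testing.assert_allclose(out.data, [[w1]], rtol=1e-6)
        np.testing.assert_allclose(attn.data, [[w1, 1 - w1]], rtol=1e-6)

    def test_rows_sum_to_one_over_unmasked_keys(self, rng):
        q = Tensor(rng.normal(size=(2, 5, 8)))
        k = Tensor(rng.normal(size=(2, 7, 8)))
        v = Tensor(rng.normal(size=(2, 7, 3)))
        mask = np.ones((2, 7), dtype=np.float32)
        mask[:, 5:] = 0.0
        _, attn = scaled_dot_attention(q, k, v, mask)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)
        assert attn.data[..., 5:].max() < 1e-6

    def test_all_keys_masked_is_an_error(self, rng):
        q = Tensor(rng.normal(size=(1, 2, 4)))
        k = Tensor(rng.normal(size=(1, 3, 4)))
        v = Tensor(rng.normal(size=(1, 3, 2)))
        with pytest.raises(ValueError, match="every key is masked"):
            scaled_dot_attention(q, k, v, np.zeros((1, 3), dtype=np.float32))


class TestTransformer:
    def _encoder(self, rng, layers=1, d_model=8, vocab=11, max_len=10):
        return TransformerEncoder(rng, vocab, d_model, 2, layers, 16, max_len)

    def test_zero_layers_is_embedding_plus_positions(self, rng):
        enc = self._encoder(rng, layers=0)
        idx = rng.integers(0, 11, size=(2, 6))
        mask = np.ones((2, 6), dtype=np.float32)
        out = enc(idx, mask)
        expected = enc.table.data[idx] + enc.pe[:6]
        np.testing.assert_allclose(out.data, expected, rtol=1e-6)

    def test_internal_attention_rows_are_stochastic(self, rng):
        enc = self._encoder(rng, layers=2)
        idx = rng.integers(0, 11, size=(3, 8))
        mask = np.ones((3, 8), dtype=np.float32)
        mask[:, 6:] = 0.0
        enc(idx, mask)
        for layer in enc.layers:
            np.testing.assert_allclose(layer["mha"].last_attn.sum(axis=-1),
                                       1.0, atol=1e-6)

    def test_padded_tail_tokens_cannot_influence_valid_positions(self, rng):
        enc = self._encoder(rng, layers=2)
        idx = rng.integers(0, 11, size=(1, 8))
        mask = np.ones((1, 8), dtype=np.float32)
        mask[:, 5:] = 0.0
        out1 = enc(idx, mask)
        scrambled = idx.copy()
        scrambled[0, 5:] = (scrambled[0, 5:] + 3) % 11
        out2 = enc(scrambled, mask)
        np.testing.assert_allclose(out1.data[0, :5], out2.data[0, :5], atol=1e-6)

    def test_fully_masked_sequence_rejected(self, rng):
        enc = self._encoder(rng)
        idx = np.zeros((1, 4), dtype=np.int64)
        with pytest.raises(ValueError, match="entirely padded"):
            enc(idx, np.zeros((1, 4), dtype=np.float32))

    def test_positional_encoding_is_bounded_and_position_dependent(self):
        pe = sinusoidal_positions(20, 8)
        assert np.abs(pe).max() <= 1.0 + 1e-6
        assert not np.allclose(pe[0], pe[1])


class TestAlignment:
    @pytest.mark.parametrize("t_in,t_out", [(10, 4), (7, 3), (4, 8), (5, 5)])
    def test_pool_matrix_rows_average_to_one(self, t_in, t_out):
        p = adaptive_pool_matrix(t_in, t_out)
        assert p.shape == (t_out, t_in)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_align_constant_signal_is_preserved(self):
        x = Tensor(np.full((2, 9, 3), 2.5))
        out = align_time(x, 4)
        np.testing.assert_allclose(out.data, 2.5, rtol=1e-6)


class TestTargetEncoder:
    def _encoder(self, rng, cf=6, tf=5):
        return TargetEncoder(rng, char_vocab_size=21, bpe_vocab_size=30,
                             embed_dim=8, conv_channels=(4, 4, 8),
                             kernel_sizes=(3, 5, 7), d_model=8, num_heads=2,
                             num_layers=1, ffn_dim=16, bpe_max_tokens=12,
                             fusion_channels=cf, fusion_time_bins=tf)

    def _batch(self, rng, b=2):
        char_idx = rng.integers(0, 21, size=(b, 15))
        char_mask = np.ones((b, 15), dtype=np.float32)
        bpe_idx = rng.integers(0, 30, size=(b, 12))
        bpe_mask = np.ones((b, 12), dtype=np.float32)
        return char_idx, char_mask, bpe_idx, bpe_mask

    def test_output_shapes_follow_fusion_dimensions(self, rng):
        enc = self._encoder(rng)
        l_map, g_map, f_target = enc(*self._batch(rng))
        assert l_map.shape == (2, 5, 6)
        assert g_map.shape == (2, 5, 6)
        assert f_target.shape == (2, 5, 12)

    def test_zero_projection_weights_zero_output(self, rng):
        enc = self._encoder(rng)
        for lin in (enc.proj_local, enc.proj_global):
            lin.w.data[:] = 0.0
            lin.b.data[:] = 0.0
        _, _, f_target = enc(*self._batch(rng))
        np.testing.assert_allclose(f_target.data, 0.0)

    def test_single_path_variants(self, rng):
        enc = self._encoder(rng)
        batch = self._batch(rng)
        l_map, g_map, f_local = enc(*batch, use_global=False)
        assert g_map is None and f_local.shape == (2, 5, 6)
        l_map, g_map, f_glob = enc(*batch, use_local=False)
        assert l_map is None and f_glob.shape == (2, 5, 6)
        with pytest.raises(ValueError):
            enc(*batch, use_local=False, use_global=False)

    @pytest.mark.parametrize("embed_dim,d_model,cf,tf",
                             [(4, 4, 3, 2), (8, 16, 5, 7), (16, 8, 12, 3)])
    def test_shape_algebra_sweep(self, rng, embed_dim, d_model, cf, tf):
        enc = TargetEncoder(rng, 21, 30, embed_dim, (4, 4, 6), (3, 3, 3),
                            d_model, 2, 1, 8, 12, cf, tf)
        _, _, f_target = enc(*self._batch(rng))
        assert f_target.shape == (2, tf, 2 * cf)
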