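"""Unit and property tests for the attention regressor's building blocks."""

import numpy as np
import pytest

from conftest import random_record
from oracle import attend as oracle_attend
from oracle import oracle_forward
from seqddg._autodiff import Tensor
from seqddg.embedding import EmbedderSpec, embed_complex
from seqddg.model_core import (
    AttentionConfig,
    MaskError,
    ModelParameters,
    ShapeError,
    apply_rope,
    conv_gate,
    conv_pool,
    cross_attend,
    forward,
    forward_embedded,
    gate_weights,
    layer_norm,
    multi_head_merge,
    pad_batch,
    pool_weights,
    predict_head,
    project_qkv,
)

STREAMS = ("ab_wt", "ag_wt", "ab_mt", "ag_mt")


def random_streams(rng, config, d_in, B=1, L_ab=5, L_ag=7):
    emb = {}
    for name in STREAMS:
        L = L_ab if name.startswith("ab") else L_ag
        emb[name] = rng.standard_normal((B, L, d_in))
    return emb


class TestAttentionConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(d_model=15),
            dict(d_model=16, n_heads=3),
            dict(conv_kernel=2),
            dict(scale_mode="other"),
            dict(dropout_rate=1.0),
            dict(variant="bogus"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises((ShapeError, ValueError)):
            AttentionConfig(**kwargs)

    def test_json_round_trip(self):
        cfg = AttentionConfig(d_model=32, n_heads=4, conv_kernel=3)
        assert AttentionConfig.from_json(cfg.to_json()) == cfg


class TestConvGate:
    def test_identical_rows_give_uniform_weights(self, tiny_params):
        H = np.tile(np.linspace(-1, 1, 16), (6, 1))
        w = gate_weights(H, None, tiny_params)
        np.testing.assert_allclose(w, np.full(6, 1 / 6), atol=1e-12)

    def test_singleton_sequence_passes_layer_norm_through(self, tiny_params):
        rng = np.random.default_rng(0)
        H = rng.standard_normal((1, 16))
        out = conv_gate(H, None, tiny_params).data
        expected = layer_norm(
            Tensor(H), tiny_params["gate_ln_gain"], tiny_params["gate_ln_bias"]
        ).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_weights_sum_to_one_over_valid_positions(self, tiny_params, rng):
        H = rng.standard_normal((3, 8, 16))
        mask = np.ones((3, 8))
        mask[1, 5:] = 0
        w = gate_weights(H, mask, tiny_params)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(w[1, 5:] == 0)

    def test_all_masked_raises(self, tiny_params, rng):
        H = rng.standard_normal((1, 4, 16))
        with pytest.raises(MaskError):
            conv_gate(H, np.zeros((1, 4)), tiny_params)

    def test_wide_kernel_padding_invariance(self, rng):
        cfg = AttentionConfig(d_model=16, n_heads=2, conv_kernel=3,
                              dropout_rate=0.0)
        params = ModelParameters.initialize(cfg, 16, seed=1)
        H = rng.standard_normal((1, 6, 16))
        base = conv_gate(H, None, params).data
        padded = np.concatenate([H, np.zeros((1, 4, 16))], axis=1)
        mask = np.concatenate([np.ones((1, 6)), np.zeros((1, 4))], axis=1)
        out = conv_gate(padded, mask, params).data
        np.testing.assert_allclose(out[:, :6], base, atol=1e-10)


class TestRotaryEmbedding:
    def test_position_zero_is_identity(self, rng):
        X = rng.standard_normal((1, 16))
        out = apply_rope(X, positions=[0]).data
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_pair_norms_preserved(self, rng):
        X = rng.standard_normal((9, 16))
        out = apply_rope(X).data
        norms_in = np.hypot(X[:, 0::2], X[:, 1::2])
        norms_out = np.hypot(out[:, 0::2], out[:, 1::2])
        np.testing.assert_allclose(norms_in, norms_out, atol=1e-6)

    def test_relative_shift_invariance_of_dot_products(self, rng):
        d = 12
        for _ in range(200):
            q = rng.standard_normal(d)
            k = rng.standard_normal(d)
            m, n = rng.integers(0, 50, size=2)
            s = int(rng.integers(1, 30))
            a = apply_rope(q[None], positions=[m]).data[0] @ apply_rope(
                k[None], positions=[n]
            ).data[0]
            b = apply_rope(q[None], positions=[m + s]).data[0] @ apply_rope(
                k[None], positions=[n + s]
            ).data[0]
            assert abs(a - b) < 1e-5

    def test_odd_width_rejected(self, rng):
        with pytest.raises(ShapeError):
            apply_rope(rng.standard_normal((3, 5)))


class TestProjectQKV:
    def test_identity_projection_zero_positions(self, tiny_config, tiny_params):
        rng = np.random.default_rng(1)
        Hp = rng.standard_normal((4, 16))
        tiny_params.tensors["Wq"] = Tensor(np.eye(16), requires_grad=True)
        tiny_params.tensors["Wk"] = Tensor(np.eye(16), requires_grad=True)
        q, k, v = project_qkv(Hp, tiny_params, tiny_config,
                              positions=np.zeros(4))
        np.testing.assert_allclose(q.data, Hp, atol=1e-12)
        np.testing.assert_allclose(k.data, Hp, atol=1e-12)

    def test_value_stream_ignores_positions(self, tiny_config, tiny_params, rng):
        Hp = rng.standard_normal((4, 16))
        _, _, v1 = project_qkv(Hp, tiny_params, tiny_config,
                               positions=np.zeros(4))
        _, _, v2 = project_qkv(Hp, tiny_params, tiny_config,
                               positions=np.arange(4) * 3.0)
        np.testing.assert_allclose(v1.data, v2.data, atol=1e-15)

    def test_matches_dense_arithmetic_on_toy_input(self, tiny_config, tiny_params):
        rng = np.random.default_rng(2)
        Hp = rng.standard_normal((3, 16))
        q, k, v = project_qkv(Hp, tiny_params, tiny_config)
        np.testing.assert_allclose(
            v.data, Hp @ tiny_params["Wv"].data, atol=1e-12
        )
        from oracle import rope_rows

        np.testing.assert_allclose(
            q.data,
            rope_rows(Hp @ tiny_params["Wq"].data, tiny_config.rope_base),
            atol=1e-10,
        )


class TestCrossAttention:
    def test_single_key_gets_full_weight(self, tiny_config, rng):
        Q = rng.standard_normal((5, 16))
        K = rng.standard_normal((1, 16))
        V = rng.standard_normal((1, 16))
        ctx, w = cross_attend(Q, K, V, None, tiny_config)
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_rows_sum_to_one_over_unmasked_keys(self, tiny_config, rng):
        Q = rng.standard_normal((2, 5, 16))
        K = rng.standard_normal((2, 7, 16))
        V = rng.standard_normal((2, 7, 16))
        mask = np.ones((2, 7))
        mask[0, 4:] = 0
        _, w = cross_attend(Q, K, V, mask, tiny_config)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-10)
        assert np.all(w[0, :, :, 4:] == 0)

    @pytest.mark.parametrize("scale_mode", ["d_head", "sqrt_d"])
    def test_matches_loop_oracle(self, scale_mode, rng):
        cfg = AttentionConfig(d_model=8, n_heads=2, scale_mode=scale_mode,
                              dropout_rate=0.0)
        Q = rng.standard_normal((5, 8))
        K = rng.standard_normal((6, 8))
        V = rng.standard_normal((6, 8))
        ctx, _ = cross_attend(Q, K, V, None, cfg)
        merged = np.concatenate(
            [ctx.data[0, h] for h in range(2)], axis=-1
        )
        expected = oracle_attend(Q, K, V, 2, scale_mode)
        np.testing.assert_allclose(merged, expected, atol=1e-5)

    def test_all_keys_masked_raises(self, tiny_config, rng):
        Q = rng.standard_normal((1, 3, 16))
        K = rng.standard_normal((1, 4, 16))
        with pytest.raises(MaskError):
            cross_attend(Q, K, K, np.zeros((1, 4)), tiny_config)


class TestMultiHeadMerge:
    def test_single_head_identity_projection(self, rng):
        cfg = AttentionConfig(d_model=16, n_heads=1, dropout_rate=0.0)
        params = ModelParameters.initialize(cfg, 16, seed=0)
        params.tensors["Wo"] = Tensor(np.eye(16), requires_grad=True)
        ctx = Tensor(rng.standard_normal((1, 1, 5, 16)))
        out = multi_head_merge(ctx, params)
        np.testing.assert_allclose(out.data[0], ctx.data[0, 0], atol=1e-12)

    def test_two_head_concat_matches_dense_oracle(self, tiny_params, rng):
        heads = rng.standard_normal((1, 2, 4, 8))
        out = multi_head_merge(Tensor(heads), tiny_params).data[0]
        stitched = np.concatenate([heads[0, 0], heads[0, 1]], axis=-1)
        np.testing.assert_allclose(
            out, stitched @ tiny_params["Wo"].data, atol=1e-12
        )


class TestConvPool:
    def test_singleton_returns_normalized_row(self, tiny_params, rng):
        H = rng.standard_normal((1, 16))
        f = conv_pool(H, None, tiny_params).data
        expected = layer_norm(
            Tensor(H), tiny_params["pool_ln_gain"], tiny_params["pool_ln_bias"]
        ).data[0]
        np.testing.assert_allclose(f, expected, atol=1e-12)

    def test_weights_sum_to_one(self, tiny_params, rng):
        H = rng.standard_normal((2, 9, 16))
        w = pool_weights(H, None, tiny_params)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)

    def test_masked_padding_leaves_vector_unchanged(self, tiny_params, rng):
        H = rng.standard_normal((1, 6, 16))
        base = conv_pool(H, None, tiny_params).data
        padded = np.concatenate([H, rng.standard_normal((1, 3, 16))], axis=1)
        mask = np.concatenate([np.ones((1, 6)), np.zeros((1, 3))], axis=1)
        out = conv_pool(padded, mask, tiny_params).data
        np.testing.assert_allclose(out, base, atol=1e-6)


class TestPredictHead:
    def test_deterministic_without_dropout(self, tiny_params, rng):
        fs = [rng.standard_normal(16) for _ in range(4)]
        y1 = predict_head(*fs, tiny_params).data
        y2 = predict_head(*fs, tiny_params).data
        assert y1 == y2

    def test_swapping_wt_and_mt_changes_prediction(self, tiny_params, rng):
        fs = [rng.standard_normal(16) for _ in range(4)]
        y = float(predict_head(fs[0], fs[1], fs[2], fs[3], tiny_params).data)
        y_swapped = float(predict_head(fs[2], fs[3], fs[0], fs[1], tiny_params).data)
        assert y != pytest.approx(y_swapped)

    def test_two_unit_toy_network_hand_computed(self):
        cfg = AttentionConfig(d_model=2, n_heads=1, head_hidden=(2, 2),
                              dropout_rate=0.0)
        params = ModelParameters.initialize(cfg, 2, seed=0)
        params.tensors["head_W1"] = Tensor(np.array(
            [[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]]
        ), requires_grad=True)
        params.tensors["head_b1"] = Tensor(np.zeros(2), requires_grad=True)
        params.tensors["head_W2"] = Tensor(np.array([[0.5, 0.0], [0.0, 0.5]]),
                                           requires_grad=True)
        params.tensors["head_b2"] = Tensor(np.array([0.1, -0.1]),
                                           requires_grad=True)
        params.tensors["head_W3"] = Tensor(np.array([[2.0], [1.0]]),
                                           requires_grad=True)
        params.tensors["head_b3"] = Tensor(np.array([0.25]), requires_grad=True)
        f_ab_wt, f_ag_wt = np.array([1.0, -2.0]), np.array([0.5, 0.5])
        f_ab_mt, f_ag_mt = np.array([2.0, 0.0]), np.array([-0.5, 1.0])
        # f = concat(wt sum, mt sum) = [1.5, -1.5, 1.5, 1.0]
        # z = W1^T f = [1.5 - 1.5, -1.5 - 1.0] = [0, -2.5]; relu -> [0, 0]
        # tanh([0.1, -0.1]) -> y = 2 tanh(0.1) + tanh(-0.1) + 0.25
        expected = 2 * np.tanh(0.1) + np.tanh(-0.1) + 0.25
        got = float(predict_head(f_ab_wt, f_ag_wt, f_ab_mt, f_ag_mt, params).data)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_width_mismatch_raises(self, tiny_params, rng):
        fs = [rng.standard_normal(16) for _ in range(3)]
        with pytest.raises(ShapeError):
            predict_head(*fs, rng.standard_normal(8), tiny_params)

    def test_dropout_requires_rng_and_perturbs(self, tiny_params, rng):
        fs = [rng.standard_normal(16) for _ in range(4)]
        with pytest.raises(ValueError):
            predict_head(*fs, tiny_params, training=True, dropout_rate=0.5)
        y0 = float(predict_head(*fs, tiny_params).data)
        y1 = float(
            predict_head(*fs, tiny_params, training=True, dropout_rate=0.5,
                         rng=np.random.default_rng(0)).data
        )
        assert y0 != pytest.approx(y1)


class TestForward:
    def test_equal_wt_mt_streams_give_equal_pooled_vectors(
        self, tiny_config, tiny_params, rng
    ):
        emb = random_streams(rng, tiny_config, 16)
        emb["ab_mt"] = emb["ab_wt"].copy()
        emb["ag_mt"] = emb["ag_wt"].copy()
        y, state = forward_embedded(emb, None, tiny_params, capture=True)
        assert np.isfinite(y.data).all()
        np.testing.assert_allclose(
            state.pooled["ab_wt"], state.pooled["ab_mt"], atol=1e-12
        )
        np.testing.assert_allclose(
            state.pooled["ag_wt"], state.pooled["ag_mt"], atol=1e-12
        )

    def test_attention_map_shapes(self, tiny_config, tiny_spec, tiny_params, rng):
        rec = random_record(rng, ab_len=5, ag_len=7)
        _, state = forward(rec, tiny_spec, tiny_params, capture=True)
        assert state.attention[("ab2ag", "wt")].shape == (2, 5, 7)
        assert state.attention[("ag2ab", "wt")].shape == (2, 7, 5)

    def test_batched_equals_one_by_one(self, tiny_config, tiny_spec, tiny_params, rng):
        recs = [
            random_record(rng, ab_len=int(rng.integers(4, 9)),
                          ag_len=int(rng.integers(4, 9)), complex_id=f"B{i}")
            for i in range(6)
        ]
        embs = [embed_complex(r, tiny_spec) for r in recs]
        arrays, masks = pad_batch(embs)
        y_batch, _ = forward_embedded(arrays, masks, tiny_params)
        singles = [forward(r, tiny_spec, tiny_params, capture=False)[0] for r in recs]
        np.testing.assert_allclose(y_batch.data, singles, atol=1e-5)

    @pytest.mark.parametrize("variant", ["no_attention", "mlp_replacement"])
    def test_ablation_variants_produce_finite_predictions(
        self, tiny_spec, rng, variant
    ):
        cfg = AttentionConfig(d_model=16, n_heads=2, dropout_rate=0.0,
                              variant=variant)
        params = ModelParameters.initialize(cfg, 16, seed=0)
        rec = random_record(rng)
        y, state = forward(rec, tiny_spec, params, capture=True)
        assert np.isfinite(y)
        assert state.attention == {}

    def test_matches_straight_line_oracle(self, rng):
        cfg = AttentionConfig(d_model=16, n_heads=2, dropout_rate=0.0)
        spec = EmbedderSpec(d=12)
        params = ModelParameters.initialize(cfg, 12, seed=5)
        np_params = {k: t.data for k, t in params.items()}
        for i in range(5):
            rec = random_record(rng, ab_len=int(rng.integers(3, 9)),
                                ag_len=int(rng.integers(3, 9)),
                                complex_id=f"O{i}")
            emb = {k: m.values for k, m in embed_complex(rec, spec).as_dict().items()}
            y_model, _ = forward(rec, spec, params, capture=False)
            y_oracle = oracle_forward(emb, np_params, cfg)
            assert y_model == pytest.approx(y_oracle, abs=1e-5)

    def test_gradients_finite_for_every_parameter(self, tiny_config, tiny_params, rng):
        emb = random_streams(rng, tiny_config, 16, B=2)
        y, _ = forward_embedded(emb, None, tiny_params)
        (y * y).sum().backward()
        for name, t in tiny_params.items():
            assert t.grad is not None, name
            assert np.all(np.isfinite(t.grad)), name

    def test_masking_invariance_of_full_forward(self, tiny_config, tiny_params, rng):
        emb = random_streams(rng, tiny_config, 16, B=2, L_ab=6, L_ag=5)
        y_base, _ = forward_embedded(emb, None, tiny_params)
        padded, masks = {}, {}
        for name, arr in emb.items():
            B, L, d = arr.shape
            pad = rng.standard_normal((B, 10, d))
            padded[name] = np.concatenate([arr, pad], axis=1)
            masks[name] = np.concatenate(
                [np.ones((B, L)), np.zeros((B, 10))], axis=1
            )
        y_pad, _ = forward_embedded(padded, masks, tiny_params)
        np.testing.assert_allclose(y_pad.data, y_base.data, atol=1e-5)


class TestModelParameters:
    def test_save_load_round_trip(self, tiny_config, tiny_params, tmp_path):
        path = tmp_path / "ckpt.npz"
        tiny_params.save(path)
        back = ModelParameters.load(path)
        assert back.config == tiny_config
        assert back.checksum() == tiny_params.checksum()

    def test_checksum_changes_with_parameters(self, tiny_params):
        before = tiny_params.checksum()
        tiny_params.tensors["head_b3"].data += 1.0
        assert tiny_params.checksum() != before

    def test_mlp_replacement_parameter_count_matches_attention(self):
        full = ModelParameters.initialize(
            AttentionConfig(d_model=32, n_heads=4, variant="full"), 32, 0
        )
        mlp = ModelParameters.initialize(
            AttentionConfig(d_model=32, n_heads=4, variant="mlp_replacement"), 32, 0
        )
        n_full = full.interaction_param_count()
        n_mlp = mlp.interaction_param_count()
        assert abs(n_mlp - n_full) <= 0.10 * n_full


class TestStreamStacking:
    def test_unequal_wt_mt_lengths_supported(self, tiny_config, tiny_params, rng):
        emb = {
            "ab_wt": rng.standard_normal((1, 7, 16)),
            "ab_mt": rng.standard_normal((1, 4, 16)),
            "ag_wt": rng.standard_normal((1, 5, 16)),
            "ag_mt": rng.standard_normal((1, 5, 16)),
        }
        y, state = forward_embedded(emb, None, tiny_params, capture=True)
        assert np.isfinite(y.data).all()
        assert state.attention[("ab2ag", "wt")].shape[-2:] == (7, 5)
        assert state.attention[("ab2ag", "mt")].shape[-2:] == (4, 5)

    def test_stacked_and_per_stream_paths_agree(self, tiny_config, tiny_params, rng):
        from seqddg.model_core import _forward_per_stream
        from seqddg._autodiff import as_tensor

        emb = {n: rng.standard_normal((2, 6, 16)) for n in
               ("ab_wt", "ab_mt", "ag_wt", "ag_mt")}
        y_fast, _ = forward_embedded(emb, None, tiny_params)
        xs = {n: as_tensor(a) for n, a in emb.items()}
        ms = {n: np.ones((2, 6)) for n in emb}
        y_slow = _forward_per_stream(
            xs, ms, tiny_params, tiny_config, False, None, False, None,
            lambda a: a,
        )
        np.testing.assert_allclose(y_fast.data, y_slow.data, atol=1e-12)
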