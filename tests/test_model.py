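"""Architecture contracts: shapes, attention algebra, determinism, variants,
and gradient correctness against numerical/naive oracles."""

import numpy as np
import pytest

import earattn.nn as nn
from earattn.errors import InvalidConfigError, UnsupportedVariantError
from earattn.model import (
    VARIANTS,
    AttentionRecord,
    ModelConfig,
    build_model,
    build_variant,
    classify,
    cross_attention,
    describe,
    load_checkpoint,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def default_model():
    return build_model(ModelConfig(), seed=42)


@pytest.fixture(scope="module")
def ear_batch():
    return np.random.default_rng(0).standard_normal((4, 2, 7500)).astype(np.float32)


class TestForwardContract:
    def test_logits_and_attention_shapes(self, default_model, ear_batch):
        logits = default_model.forward(ear_batch)
        assert logits.shape == (4, 2)
        for direction in ("left_to_right", "right_to_left"):
            amap = default_model.last_attention[direction]
            assert amap.shape == (4, 35, 35)
            np.testing.assert_allclose(amap.sum(axis=-1), 1.0, atol=1e-6)
            assert (amap >= 0).all()

    def test_token_count_is_35_for_any_batch_size(self, default_model):
        for b in (1, 3):
            x = np.zeros((b, 2, 7500), dtype=np.float32)
            default_model.forward(x)
            assert default_model.last_attention["left_to_right"].shape[1:] == (35, 35)

    def test_same_seed_same_parameters(self):
        a = build_model(ModelConfig(), seed=7)
        b = build_model(ModelConfig(), seed=7)
        assert a.parameter_checksum() == b.parameter_checksum()
        c = build_model(ModelConfig(), seed=8)
        assert a.parameter_checksum() != c.parameter_checksum()

    def test_parameter_count_stable_and_documented(self, default_model):
        # pinned config: ~0.06 M parameters, stable across builds
        n = default_model.num_parameters()
        assert n == build_model(ModelConfig(), seed=3).num_parameters()
        assert 4e4 < n < 1e5
        assert str(n) in describe(ModelConfig())

    def test_eval_mode_is_deterministic_and_batch_invariant(
            self, default_model, ear_batch):
        a = classify(default_model, ear_batch)
        b = classify(default_model, ear_batch)
        np.testing.assert_array_equal(a, b)
        single = classify(default_model, ear_batch[1:2])
        np.testing.assert_allclose(single[0], a[1], atol=1e-5)
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(classify(default_model, ear_batch[perm]),
                                   a[perm], atol=1e-5)

    def test_wrong_input_shape_rejected(self, default_model):
        with pytest.raises(InvalidConfigError):
            default_model.forward(np.zeros((2, 3, 7500), dtype=np.float32))
        with pytest.raises(InvalidConfigError):
            default_model.forward(np.zeros((2, 2, 7000), dtype=np.float32))

    def test_bad_config_rejected_at_build_time(self):
        with pytest.raises(InvalidConfigError):
            ModelConfig(pool=((5, 5), (6, 6), (5, 5)))  # 50 tokens, not 35
        with pytest.raises(InvalidConfigError):
            ModelConfig(kernel_lengths=(125, 63, 63, 20))
        with pytest.raises(UnsupportedVariantError):
            ModelConfig(variant="no_model")


class TestCrossAttention:
    def test_single_token(self):
        out, rec = cross_attention(np.ones((1, 3)), np.ones((1, 3)),
                                   np.array([[2.0, 5.0]]))
        np.testing.assert_allclose(rec.map, [[1.0]])
        np.testing.assert_allclose(out, [[2.0, 5.0]])

    def test_identical_keys_give_uniform_rows(self):
        rng = np.random.default_rng(2)
        Q = rng.standard_normal((4, 3))
        K = np.tile(rng.standard_normal(3), (4, 1))
        V = rng.standard_normal((4, 2))
        out, rec = cross_attention(Q, K, V)
        np.testing.assert_allclose(rec.map, np.full((4, 4), 0.25), atol=1e-12)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)),
                                   atol=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        Q = rng.standard_normal((5, 3))
        K = rng.standard_normal((5, 3))
        V = rng.standard_normal((5, 2))
        out, rec = cross_attention(Q, K, V)
        scores = np.array([[Q[i] @ K[j] / np.sqrt(3) for j in range(5)]
                           for i in range(5)])
        ref_map = np.exp(scores)
        ref_map /= ref_map.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(rec.map, ref_map, atol=1e-6)
        np.testing.assert_allclose(out, ref_map @ V, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidConfigError):
            cross_attention(np.ones((4, 3)), np.ones((4, 2)), np.ones((4, 1)))

    def test_row_stochasticity_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            t, dk = int(rng.integers(1, 8)), int(rng.integers(1, 5))
            _, rec = cross_attention(rng.standard_normal((t, dk)) * 3,
                                     rng.standard_normal((t, dk)) * 3,
                                     rng.standard_normal((t, 2)))
            np.testing.assert_allclose(rec.map.sum(axis=1), 1.0, atol=1e-6)

    def test_attention_record_invariants(self):
        with pytest.raises(InvalidConfigError):
            AttentionRecord("left_to_right", np.array([[0.5, 0.4], [0.5, 0.5]]))
        with pytest.raises(InvalidConfigError):
            AttentionRecord("left_to_right", np.array([[1.5, -0.5], [0.5, 0.5]]))


class TestVariants:
    def test_all_variants_build_and_run(self, ear_batch):
        for variant in VARIANTS:
            model = build_variant(ModelConfig(), variant, seed=1)
            logits = model.forward(ear_batch[:2])
            assert logits.shape == (2, 2)
            assert np.all(np.isfinite(logits))

    def test_no_cross_attention_emits_no_attention_record(self, ear_batch):
        model = build_variant(ModelConfig(), "no_cross_attention", seed=1)
        model.forward(ear_batch[:2])
        assert model.last_attention == {}

    def test_parameter_count_ordering(self):
        full = build_variant(ModelConfig(), "full", seed=1)
        transformer = build_variant(ModelConfig(), "lightweight_transformer",
                                    seed=1)
        assert full.num_parameters() < transformer.num_parameters()

    def test_shared_streams_halve_encoder_parameters(self):
        separate = build_model(ModelConfig(), seed=1)
        shared = build_model(ModelConfig(share_streams=True), seed=1)
        assert shared.num_parameters() < separate.num_parameters()
        x = np.random.default_rng(0).standard_normal((2, 2, 7500)).astype(np.float32)
        assert shared.forward(x).shape == (2, 2)


class TestGradients:
    def test_every_variant_backpropagates_to_all_parameters(
            self, tiny_model_config, rng):
        """One loss backward reaches every parameter (evaluation-mode batch
        statistics, so normalization does not null constant shifts)."""
        x = rng.standard_normal((3, 2, 210))
        y = np.array([0, 1, 1])
        for variant in VARIANTS:
            model = build_variant(ModelConfig(**tiny_model_config), variant,
                                  seed=5)
            model.forward(x.astype(np.float32), training=True)  # set BN stats
            logits = model.forward(x.astype(np.float32), training=False)
            _, dlogits = nn.cross_entropy(logits, y)
            for p in model.parameters():
                p.grad[...] = 0
            model.backward(dlogits)
            dead = [p.name for p in model.parameters()
                    if not np.any(p.grad != 0)]
            assert dead == [], (variant, dead)

    def test_analytic_gradients_match_numerical(self, tiny_model_config, rng):
        """Central-difference check (float64) at the largest-gradient entry
        of every parameter, all variants."""
        old = nn.DTYPE
        nn.DTYPE = np.float64
        try:
            x = rng.standard_normal((3, 2, 210))
            y = np.array([0, 1, 1])
            for variant in VARIANTS:
                model = build_variant(ModelConfig(**tiny_model_config),
                                      variant, seed=5)

                def loss():
                    return nn.cross_entropy(model.forward(x, training=True), y)

                _, dlogits = loss()
                for p in model.parameters():
                    p.grad[...] = 0
                model.backward(dlogits)
                for p in model.parameters():
                    flat = np.abs(p.grad).ravel()
                    if flat.max() < 1e-9:
                        continue  # normalization-invariant direction (grad
                        # is zero up to roundoff, e.g. biases ahead of BN)
                    idx = np.unravel_index(int(flat.argmax()), p.value.shape)
                    eps = 1e-5 * max(1.0, abs(p.value[idx]))
                    orig = p.value[idx]
                    p.value[idx] = orig + eps
                    lp, _ = loss()
                    p.value[idx] = orig - eps
                    lm, _ = loss()
                    p.value[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    rel = abs(num - p.grad[idx]) / max(1e-10,
                                                       abs(num) + abs(p.grad[idx]))
                    assert rel < 1e-4, (variant, p.name, num, p.grad[idx])
        finally:
            nn.DTYPE = old

    def test_conv_matches_naive_direct_convolution(self, rng):
        old = nn.DTYPE
        nn.DTYPE = np.float64
        try:
            B, Ci, L, K, Co = 2, 3, 20, 5, 4
            conv = nn.Conv1d(Ci, Co, K, rng)
            x = rng.standard_normal((B, Ci, L))
            y = conv.forward(x)
            pl = (K - 1) // 2
            ref = np.zeros((B, Co, L))
            for b in range(B):
                for o in range(Co):
                    for t in range(L):
                        acc = conv.b.value[o]
                        for i in range(Ci):
                            for k in range(K):
                                j = t + k - pl
                                if 0 <= j < L:
                                    acc += x[b, i, j] * conv.w.value[o, i, k]
                        ref[b, o, t] = acc
            np.testing.assert_allclose(y, ref, atol=1e-12)
        finally:
            nn.DTYPE = old


def test_checkpoint_round_trip(tmp_path, ear_batch):
    model = build_model(ModelConfig(), seed=11)
    before = classify(model, ear_batch)
    save_checkpoint(model, tmp_path / "ckpt")
    restored = load_checkpoint(tmp_path / "ckpt")
    np.testing.assert_allclose(classify(restored, ear_batch), before, atol=1e-6)
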