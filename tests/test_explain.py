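"""Attention summaries and temporal occlusion, checked against naive-loop
oracles, analytic degenerate cases, and a closed-form linear surrogate."""

import numpy as np
import pandas as pd
import pytest

from earattn.errors import (
    DegenerateDataError,
    InvalidConfigError,
    UnsupportedVariantError,
)
from earattn.explain import (
    attention_summaries,
    capture_attention,
    delta_summaries,
    directional_asymmetry,
    occlusion_summaries,
    row_entropy,
    temporal_occlusion,
)
from earattn.model import ModelConfig, build_model, build_variant


class TestRowEntropy:
    def test_one_hot_rows_have_zero_entropy(self):
        H, mean = row_entropy(np.eye(6))
        np.testing.assert_allclose(H, 0.0)
        assert mean == 0.0

    def test_uniform_map_reaches_ln_t(self):
        H, mean = row_entropy(np.full((35, 35), 1 / 35))
        np.testing.assert_allclose(H, np.log(35))
        assert mean == pytest.approx(np.log(35))
        _, norm_mean = row_entropy(np.full((35, 35), 1 / 35), normalized=True)
        assert norm_mean == pytest.approx(1.0)

    def test_matches_naive_loop_oracle(self, rng):
        A = rng.random((5, 5))
        H, mean = row_entropy(A)
        for i in range(5):
            p = A[i] / A[i].sum()
            h = -sum(pj * np.log(pj) for pj in p if pj > 0)
            assert H[i] == pytest.approx(h, abs=1e-10)
        assert mean == pytest.approx(H.mean())

    def test_entropy_bounds_on_random_maps(self, rng):
        for _ in range(200):
            t = int(rng.integers(2, 12))
            H, mean = row_entropy(rng.random((t, t)) + 1e-9)
            assert np.all(H >= -1e-12)
            assert np.all(H <= np.log(t) + 1e-12)

    def test_zero_row_rejected(self):
        A = np.eye(3)
        A[1] = 0
        with pytest.raises(DegenerateDataError):
            row_entropy(A)


class TestDirectionalAsymmetry:
    def test_symmetric_map_is_exactly_zero(self, rng):
        A = rng.random((6, 6))
        A = (A + A.T) / 2
        assert directional_asymmetry(A) == 0.0
        assert directional_asymmetry(np.full((35, 35), 1 / 35)) == 0.0

    def test_hand_arithmetic_example(self):
        assert directional_asymmetry(np.array([[1.0, 0.0], [1.0, 0.0]])) == 1.0

    def test_matches_elementwise_oracle(self, rng):
        A = rng.random((6, 6))
        num = np.sqrt(sum((A[i, j] - A[j, i]) ** 2
                          for i in range(6) for j in range(6)))
        den = np.sqrt((A ** 2).sum())
        assert directional_asymmetry(A) == pytest.approx(num / den, abs=1e-12)

    def test_bounded_by_two(self, rng):
        for _ in range(200):
            t = int(rng.integers(2, 10))
            assert 0.0 <= directional_asymmetry(rng.random((t, t)) + 1e-9) <= 2.0

    def test_zero_map_rejected(self):
        with pytest.raises(DegenerateDataError):
            directional_asymmetry(np.zeros((4, 4)))


class TestCaptureAttention:
    def test_maps_are_row_stochastic_and_deterministic(self, tiny_model_cfg_obj,
                                                       rng):
        model = build_model(tiny_model_cfg_obj, seed=2)
        x = rng.standard_normal((3, 2, 210)).astype(np.float32)
        maps = capture_attention(model, x)
        for d in ("left_to_right", "right_to_left"):
            assert maps[d].shape == (3, 35, 35)
            np.testing.assert_allclose(maps[d].sum(axis=-1), 1.0, atol=1e-6)
        dup = capture_attention(model, np.concatenate([x[:1], x[:1]]))
        np.testing.assert_array_equal(dup["left_to_right"][0],
                                      dup["left_to_right"][1])

    def test_default_model_yields_35_by_35(self):
        model = build_model(ModelConfig(), seed=2)
        x = np.random.default_rng(0).standard_normal((1, 2, 7500)).astype(np.float32)
        maps = capture_attention(model, x)
        assert maps["left_to_right"].shape == (1, 35, 35)

    def test_attention_free_variant_rejected(self, tiny_model_cfg_obj):
        model = build_variant(tiny_model_cfg_obj, "no_cross_attention", seed=2)
        with pytest.raises(UnsupportedVariantError):
            capture_attention(model, np.zeros((1, 2, 210), dtype=np.float32))


class TestTemporalOcclusion:
    def test_zero_epoch_gives_zero_deltas(self, tiny_model_cfg_obj):
        model = build_model(tiny_model_cfg_obj, seed=2)
        prof = temporal_occlusion(model, np.zeros((2, 210)), window_s=0.5,
                                  step_s=0.1, fs=125.0)
        np.testing.assert_allclose(prof.delta_logit, 0.0, atol=1e-5)

    def test_window_count_at_default_resolution(self):
        """7500 samples, 62-sample window, 12-sample step -> 620 windows."""
        logit = lambda x: np.stack([x.mean(axis=(1, 2))] * 2, axis=1)
        prof = temporal_occlusion(logit, np.ones((2, 7500)), window_s=0.5,
                                  step_s=0.1, fs=125.0)
        assert len(prof.delta_logit) == (7500 - 62) // 12 + 1 == 620

    def test_linear_surrogate_closed_form(self, rng):
        """For a surrogate whose logit is the mean over both channels, the
        delta at a window equals the zeroed mass / total sample count."""
        x = rng.standard_normal((2, 500)).astype(np.float32)

        def logit(batch):
            m = batch.mean(axis=(1, 2))
            return np.stack([np.zeros_like(m), m], axis=1)

        prof = temporal_occlusion(logit, x, class_index=1, window_s=0.2,
                                  step_s=0.1, fs=100.0)
        w, step = 20, 10
        starts = np.arange(0, 500 - w + 1, step)
        expected = np.array([x[:, s:s + w].sum() / (2 * 500) for s in starts])
        np.testing.assert_allclose(prof.delta_logit, expected, atol=1e-6)
        assert prof.positive_area >= 0
        assert prof.negative_area <= 0
        assert prof.peak_time_s == prof.times_s[np.argmax(prof.delta_logit)]

    def test_occluding_a_burst_matters_more_than_silence(self, rng):
        """Localization sanity: zeroing the energetic segment of an epoch
        changes the logit more than zeroing a quiet segment."""
        model = build_model(ModelConfig(), seed=4)
        epoch = 0.01 * rng.standard_normal((2, 7500)).astype(np.float32)
        epoch[:, 3000:3500] += 20.0 * rng.standard_normal((2, 500))
        prof = temporal_occlusion(model, epoch, window_s=0.5, step_s=0.5,
                                  fs=125.0)
        in_burst = (prof.times_s > 24.0) & (prof.times_s < 28.0)
        outside = prof.times_s < 20.0
        assert np.abs(prof.delta_logit[in_burst]).max() > \
            np.abs(prof.delta_logit[outside]).max()

    def test_bad_windows_rejected(self, tiny_model_cfg_obj):
        model = build_model(tiny_model_cfg_obj, seed=2)
        with pytest.raises(InvalidConfigError):
            temporal_occlusion(model, np.zeros((2, 210)), window_s=0.0)
        with pytest.raises(InvalidConfigError):
            temporal_occlusion(model, np.zeros((2, 210)), window_s=10.0,
                               step_s=0.1, fs=125.0)


class TestDeltaSummaries:
    def test_identical_label_statistics_give_zero_deltas(self):
        rows = []
        for fold in range(3):
            for label in ("stress", "relax"):
                rows.append({"fold_id": fold, "direction": "left_to_right",
                             "label": label, "mean_row_entropy": 1.5,
                             "asymmetry": 0.2})
        out = delta_summaries(pd.DataFrame(rows))
        assert np.allclose(out["delta_mean_row_entropy"].astype(float), 0.0)
        assert np.allclose(out["delta_asymmetry"].astype(float), 0.0)

    def test_eight_folds_give_eight_delta_rows_per_direction(self, rng):
        rows = []
        for fold in range(8):
            for direction in ("left_to_right", "right_to_left"):
                for label in ("stress", "relax"):
                    for _ in range(3):
                        rows.append({
                            "fold_id": fold, "direction": direction,
                            "label": label,
                            "mean_row_entropy": float(rng.random()),
                            "asymmetry": float(rng.random()),
                        })
        out = delta_summaries(pd.DataFrame(rows))
        per_fold = out[out["fold_id"] != "mean"]
        assert len(per_fold) == 16  # 8 folds x 2 directions
        means = out[out["fold_id"] == "mean"]
        assert len(means) == 2
        # across-fold mean equals the mean of the per-fold deltas
        for direction in ("left_to_right", "right_to_left"):
            sel = per_fold[per_fold["direction"] == direction]
            m = means[means["direction"] == direction]
            assert m["delta_asymmetry"].iloc[0] == pytest.approx(
                sel["delta_asymmetry"].astype(float).mean())

    def test_single_label_fold_rejected(self):
        rows = [{"fold_id": 0, "direction": "left_to_right", "label": "stress",
                 "mean_row_entropy": 1.0, "asymmetry": 0.1}]
        with pytest.raises(DegenerateDataError):
            delta_summaries(pd.DataFrame(rows))


def test_model_based_summaries_wire_through(tiny_model_cfg_obj, rng):
    model = build_model(tiny_model_cfg_obj, seed=2)
    x = rng.standard_normal((4, 2, 210)).astype(np.float32)
    labels = np.array([1, 0, 1, 0])
    att = attention_summaries(model, x, labels, fold_id=0)
    assert len(att) == 8  # 4 samples x 2 directions
    occ = occlusion_summaries(model, x, labels, fold_id=0, window_s=0.5,
                              step_s=0.5, fs=125.0)
    assert len(occ) == 4
    for table in (att, occ):
        deltas = delta_summaries(table)
        assert (deltas["fold_id"] == "mean").any()
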