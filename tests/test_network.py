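"""3D CNN building blocks, training loop, features, and R^2."""

import numpy as np
import pytest

from headreg import (
    DCNNConfig,
    RegistrationParams,
    Volume,
    build_dcnn,
    concat_pair_features,
    extract_features,
    half_mse_loss,
    make_pair,
    r_squared,
)
from headreg.network import (
    LeakyReLU,
    GlobalAvgPool,
    _half_mse_grad,
    learning_rate_schedule,
    train_model,
    volume_to_input,
)
from headreg.phantom import PhantomSpec

TINY = DCNNConfig(
    input_dims=(8, 8, 4), conv_channels=(4, 128), pool_windows=((2, 2, 2), None), batch_size=2
)


class TestLayers:
    def test_leaky_relu_slope(self):
        layer = LeakyReLU(0.1)
        out = layer.forward(np.array([[-1.0, 2.0]]), train=False)
        np.testing.assert_allclose(out, [[-0.1, 2.0]])

    def test_global_average_pool_of_constant(self):
        layer = GlobalAvgPool()
        x = np.full((2, 3, 4, 4, 2), 1.7)
        np.testing.assert_allclose(layer.forward(x, train=False), np.full((2, 3), 1.7))

    def test_gradients_match_finite_differences(self, rng):
        m = build_dcnn(TINY)
        x = rng.random((2, 1, 8, 8, 4))
        t = rng.random((2, 6))
        out = m.forward(x, train=True)
        m.backward(_half_mse_grad(out, t))
        worst = 0.0
        for p in m.params():
            flat, g = p.value.ravel(), p.grad.ravel()
            for k in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, old = 1e-5, flat[k]
                flat[k] = old + eps
                lp = half_mse_loss(m.forward(x, train=True), t)
                flat[k] = old - eps
                lm = half_mse_loss(m.forward(x, train=True), t)
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                worst = max(worst, abs(num - g[k]) / max(1e-8, abs(num) + abs(g[k])))
        assert worst < 5e-3  # finite-difference noise near activation kinks

    def test_parameter_count_closed_form(self):
        m = build_dcnn(TINY)
        conv1 = 4 * 1 * 27 + 4
        bn1 = 2 * 4
        conv2 = 128 * 4 * 27 + 128
        bn2 = 2 * 128
        head = 128 * 6 + 6
        assert m.n_parameters() == conv1 + bn1 + conv2 + bn2 + head


class TestConfig:
    def test_last_block_must_have_128_channels(self):
        with pytest.raises(ValueError):
            DCNNConfig(conv_channels=(8, 16, 64), pool_windows=((2, 2, 2), (2, 2, 2), None))

    def test_pooling_chain_must_fit_input(self):
        with pytest.raises(ValueError):
            DCNNConfig(input_dims=(8, 8, 2), conv_channels=(8, 128),
                       pool_windows=((2, 2, 2), (2, 2, 2)))

    def test_full_preset_shape(self):
        cfg = DCNNConfig.full_preset()
        assert cfg.input_dims == (256, 256, 26)
        assert cfg.conv_channels[-1] == 128
        assert cfg.lr_initial == 0.001 and cfg.lr_after_drop == 0.0001
        assert cfg.validation_fraction == 0.30 and cfg.max_epochs == 30

    def test_zero_volume_forward_is_finite(self):
        m = build_dcnn(TINY)
        out = m.forward(np.zeros((1, 1, 8, 8, 4)))
        assert out.shape == (1, 6) and np.all(np.isfinite(out))


class TestHalfMSELoss:
    def test_zero_at_equality(self, rng):
        v = rng.random((3, 6))
        assert half_mse_loss(v, v) == 0.0

    def test_unit_residuals_give_half(self):
        assert half_mse_loss(np.ones(6), np.zeros(6)) == pytest.approx(0.5)

    def test_quadratic_homogeneity(self, rng):
        p, t = rng.random(6), rng.random(6)
        assert half_mse_loss(t + 2 * (p - t), t) == pytest.approx(4 * half_mse_loss(p, t))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            half_mse_loss(np.ones(6), np.ones(5))


class TestTraining:
    def test_lr_schedule_is_step_function(self):
        cfg = DCNNConfig(input_dims=(8, 8, 4), conv_channels=(128,), pool_windows=(None,))
        lrs = learning_rate_schedule(cfg)
        assert lrs[:20] == [0.001] * 20
        assert lrs[20:] == [0.0001] * 10
        assert len(lrs) == 30

    def test_validation_split_size(self, rng):
        m = build_dcnn(TINY)
        x = rng.random((10, 1, 8, 8, 4))
        t = rng.random((10, 6))
        cfg = TINY
        history = train_model(m, x, t, cfg)
        assert history["n_val"] == 3  # round(0.3 * 10)
        assert history["n_train"] == 7

    def test_single_pair_overfit(self, rng):
        cfg = DCNNConfig(
            input_dims=(8, 8, 4), conv_channels=(4, 128), pool_windows=((2, 2, 2), None),
            batch_size=1, max_epochs=200, lr_drop_epoch=200, lr_initial=0.01, seed=0,
        )
        m = build_dcnn(cfg)
        x = rng.random((1, 1, 8, 8, 4))
        t = rng.random((1, 6))
        history = train_model(m, x, t, cfg)
        assert history["train_loss"][-1] < 1e-3

    def test_training_is_deterministic(self, rng):
        x = rng.random((4, 1, 8, 8, 4))
        t = rng.random((4, 6))
        cfg = DCNNConfig(
            input_dims=(8, 8, 4), conv_channels=(4, 128), pool_windows=((2, 2, 2), None),
            batch_size=2, max_epochs=3, seed=5,
        )
        outs = []
        for _ in range(2):
            m = build_dcnn(cfg)
            train_model(m, x, t, cfg)
            outs.append(m.forward(x))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_empty_dataset_rejected(self):
        m = build_dcnn(TINY)
        with pytest.raises(ValueError):
            train_model(m, np.zeros((0, 1, 8, 8, 4)), np.zeros((0, 6)), TINY)


class TestFeatures:
    def test_feature_vector_has_128_entries(self):
        m = build_dcnn(TINY)
        v = Volume(np.random.default_rng(0).random((8, 8, 4)))
        f = extract_features(m, v)
        assert f.shape == (128,)
        assert np.all(np.isfinite(f))

    def test_identical_volumes_identical_features(self, rng):
        m = build_dcnn(TINY)
        v = Volume(rng.random((8, 8, 4)))
        np.testing.assert_array_equal(extract_features(m, v), extract_features(m, v.copy()))

    def test_batch_norm_mode_handling(self, rng):
        # extract_features must run batch-norm in inference mode: the
        # features of a volume are a pure function of (weights, volume),
        # independent of whatever else shares the batch. In train mode the
        # batch statistics couple samples, so features would differ.
        m = build_dcnn(TINY)
        x = rng.random((1, 1, 8, 8, 4))
        other = rng.random((1, 1, 8, 8, 4)) * 3.0
        alone = m.features(x)
        in_batch = m.features(np.concatenate([x, other], axis=0))[:1]
        np.testing.assert_array_equal(alone, in_batch)

        def features_train_mode(inp):
            h = inp
            for layer in m.layers[: m.feature_index + 1]:
                h = layer.forward(h, train=True)
            return h

        train_alone = features_train_mode(x)
        train_in_batch = features_train_mode(np.concatenate([x, other], axis=0))[:1]
        assert not np.allclose(train_alone, train_in_batch)

    def test_concat_order_fixed_then_moving(self, rng):
        a, b = rng.random(128), rng.random(128)
        c = concat_pair_features(a, b)
        assert c.shape == (256,)
        np.testing.assert_array_equal(c[:128], a)
        np.testing.assert_array_equal(c[128:], b)
        swapped = concat_pair_features(b, a)
        np.testing.assert_array_equal(swapped[:128], b)

    def test_concat_rejects_wrong_width(self, rng):
        with pytest.raises(ValueError):
            concat_pair_features(rng.random(64), rng.random(128))


class TestRSquared:
    def test_perfect_prediction(self, rng):
        t = rng.random((5, 6))
        pooled, per = r_squared(t, t)
        assert pooled == 1.0
        np.testing.assert_allclose(per, np.ones(6))

    def test_mean_prediction_gives_zero(self, rng):
        t = rng.random((10, 6))
        pred = np.tile(t.mean(axis=0), (10, 1))
        pooled, per = r_squared(pred, t)
        assert pooled == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_point_example(self):
        truth = np.array([[0.0, 2.0], [1.0, 4.0], [2.0, 6.0]])
        pred = np.array([[0.5, 2.0], [1.0, 5.0], [1.5, 6.0]])
        # SS_res = 0.25+0+0.25 = 0.5 (col1) and 0+1+0 = 1 (col2)
        # SS_tot = 2 (col1) and 8 (col2); pooled = 1 - 1.5/10
        pooled, per = r_squared(pred, truth)
        assert pooled == pytest.approx(1 - 1.5 / 10)
        np.testing.assert_allclose(per, [1 - 0.5 / 2, 1 - 1.0 / 8])

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones((3, 2)), np.ones((3, 2)))
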