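"""Adversarial adaptation: scaler, gradient penalty, network contracts."""

import numpy as np
import pytest

from fbadr.adapt import (
    DomainBundle,
    FeatureScaler,
    adapt_features,
    gradient_penalty,
    train_adaptation,
)
from fbadr.autodiff import Tensor
from fbadr.config import AdaptTrainConfig
from fbadr.nn import Adaptor, Critic


class TestFeatureScaler:
    def test_full_range_features_map_identically(self, rng):
        x = np.array([[-1.0, -1.0], [1.0, 1.0], [0.3, -0.2]])
        s = FeatureScaler().fit(x)
        np.testing.assert_allclose(s.transform(x), x, atol=1e-12)

    def test_inverse_pair(self, rng):
        x = rng.standard_normal((20, 5)) * 7 + 3
        s = FeatureScaler().fit(x)
        np.testing.assert_allclose(s.inverse_transform(s.transform(x)), x, atol=1e-10)

    def test_affine_formula(self):
        x = np.array([[-2.0], [2.0]])
        s = FeatureScaler().fit(x)
        assert s.transform(np.array([[1.0]]))[0, 0] == pytest.approx(0.5)

    def test_constant_dimension_guard(self):
        x = np.full((4, 2), 3.0)
        s = FeatureScaler().fit(x)
        np.testing.assert_allclose(s.transform(x), 0.0)
        np.testing.assert_allclose(s.inverse_transform(np.zeros((1, 2))), 3.0)

    def test_transformed_training_data_in_unit_box(self, rng):
        x = rng.standard_normal((50, 4)) * 100
        z = FeatureScaler().fit(x).transform(x)
        assert z.min() >= -1.0 - 1e-12 and z.max() <= 1.0 + 1e-12


class TestGradientPenalty:
    def test_unit_linear_critic_has_zero_penalty(self, rng):
        w = rng.standard_normal((4, 1))
        w /= np.linalg.norm(w)
        critic = lambda x: x @ Tensor(w)
        gp = gradient_penalty(critic, rng.standard_normal((8, 4)),
                              rng.standard_normal((8, 4)), rng)
        assert float(gp.data) == pytest.approx(0.0, abs=1e-7)

    def test_double_slope_critic_penalty_is_one(self, rng):
        w = rng.standard_normal((4, 1))
        w = 2.0 * w / np.linalg.norm(w)
        critic = lambda x: x @ Tensor(w)
        gp = gradient_penalty(critic, rng.standard_normal((8, 4)),
                              rng.standard_normal((8, 4)), rng)
        assert float(gp.data) == pytest.approx(1.0, abs=1e-6)

    def test_constant_critic_penalty_is_one(self, rng):
        critic = lambda x: x.sum(axis=1, keepdims=True) * 0.0
        gp = gradient_penalty(critic, rng.standard_normal((8, 4)),
                              rng.standard_normal((8, 4)), rng)
        assert float(gp.data) == pytest.approx(1.0, abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gradient_penalty(lambda x: x, np.zeros((3, 2)), np.zeros((4, 2)), rng)


class TestNetworkShapes:
    def test_adaptor_matches_published_table(self, rng):
        """961 -> 961x1 -> 961x32 -> 961x8 -> 7688 -> 961 (tanh)."""
        shapes = Adaptor(961, rng).trace_shapes(batch=2)
        assert shapes["reshape"] == (2, 961, 1)
        assert shapes["conv1"] == (2, 961, 32)
        assert shapes["conv2"] == (2, 961, 8)
        assert shapes["flatten"] == (2, 7688)
        assert shapes["dense"] == (2, 961)

    def test_critic_matches_published_table(self, rng):
        """961 -> 32 -> 32x1 -> 32x32 -> 32x64 -> 2048 -> 256 -> 64 -> 1."""
        shapes = Critic(961, rng).trace_shapes(batch=2)
        assert shapes["dense_in"] == (2, 32)
        assert shapes["conv1"] == (2, 32, 32)
        assert shapes["conv2"] == (2, 32, 64)
        assert shapes["flatten"] == (2, 2048)
        assert shapes["fc1"] == (2, 256)
        assert shapes["fc2"] == (2, 64)
        assert shapes["output"] == (2, 1)

    def test_adaptor_output_is_tanh_bounded(self, rng):
        a = Adaptor(10, rng)
        out = a(Tensor(rng.standard_normal((5, 10)) * 100), training=False)
        # tanh bound; equality only through float saturation
        assert np.all(np.abs(out.data) <= 1.0)

    def test_sigmoid_critic_output_in_unit_interval(self, rng):
        c = Critic(10, rng, sigmoid=True)
        out = c(Tensor(rng.standard_normal((5, 10)) * 10), training=False)
        assert np.all((out.data > 0) & (out.data < 1))


def _toy_bundle(rng, n=60, f=4, shift=3.0):
    target = rng.normal(0, 1, (n, f))
    source = rng.normal(0, 1, (n, f))
    source[:, 0] += shift
    y = np.array(["pleasure", "unpleasure"] * (n // 2))
    target[y == "unpleasure", 1] += 0.5
    source[y == "unpleasure", 1] += 0.5
    return DomainBundle(target_train=target, target_train_labels=y,
                        source=source, source_labels=y, band=1)


class TestTraining:
    def test_history_covers_all_epochs_and_classes(self, rng):
        bundle = _toy_bundle(rng, n=20)
        cfg = AdaptTrainConfig(epochs=3, seed=0)
        model = train_adaptation(bundle, cfg)
        assert len(model.history) == 3 * 2  # per epoch and per class
        assert set(model.history["unit"]) == {"pleasure", "unpleasure"}

    def test_missing_target_class_rejected(self, rng):
        bundle = _toy_bundle(rng, n=20)
        bundle.target_train_labels = np.array(["pleasure"] * 20)
        with pytest.raises(ValueError):
            train_adaptation(bundle, AdaptTrainConfig(epochs=1))

    def test_adapted_shape_and_determinism(self, rng):
        bundle = _toy_bundle(rng, n=20)
        cfg = AdaptTrainConfig(epochs=2, seed=4)
        model = train_adaptation(bundle, cfg)
        a1 = adapt_features(model, bundle.source, bundle.source_labels)
        a2 = adapt_features(model, bundle.source, bundle.source_labels)
        assert a1.shape == bundle.source.shape
        np.testing.assert_array_equal(a1, a2)

    def test_scaled_outputs_respect_tanh_bound(self, rng):
        bundle = _toy_bundle(rng, n=20)
        model = train_adaptation(bundle, AdaptTrainConfig(epochs=2, seed=4))
        scaled = adapt_features(model, bundle.source, bundle.source_labels,
                                return_scaled=True)
        assert np.all(np.abs(scaled) <= 1.0)

    def test_training_bitwise_reproducible(self, rng):
        bundle = _toy_bundle(rng, n=16)
        cfg = AdaptTrainConfig(epochs=2, seed=9)
        m1 = train_adaptation(bundle, cfg)
        m2 = train_adaptation(bundle, cfg)
        a1 = adapt_features(m1, bundle.source, bundle.source_labels)
        a2 = adapt_features(m2, bundle.source, bundle.source_labels)
        np.testing.assert_array_equal(a1, a2)

    def test_one_hot_variant_trains_single_model(self, rng):
        bundle = _toy_bundle(rng, n=20)
        cfg = AdaptTrainConfig(epochs=2, seed=1, conditioning="one_hot")
        model = train_adaptation(bundle, cfg)
        assert list(model.adaptors) == ["__all__"]
        out = adapt_features(model, bundle.source, bundle.source_labels)
        assert out.shape == bundle.source.shape

    def test_mean_shift_is_substantially_removed(self):
        """Adaptation closes >=80% of a (+3, 0, ...) source-mean offset."""
        rng = np.random.default_rng(21)
        bundle = _toy_bundle(rng, n=96, f=4, shift=3.0)
        cfg = AdaptTrainConfig(seed=2, epochs=200, critic_steps=3)
        model = train_adaptation(bundle, cfg)
        adapted = adapt_features(model, bundle.source, bundle.source_labels)
        pre = np.linalg.norm(bundle.source.mean(0) - bundle.target_train.mean(0))
        post = np.linalg.norm(adapted.mean(0) - bundle.target_train.mean(0))
        assert post <= 0.2 * pre
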