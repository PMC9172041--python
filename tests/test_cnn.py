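"""Classifier architecture and training-recipe primitives."""

import numpy as np
import pytest

from singlehit.cnn import (
    AugmentConfig,
    ModelConfig,
    TrainConfig,
    augment,
    build_model,
    lr_schedule,
    sample_minibatch,
    stratified_folds,
    train_fold,
)
from singlehit.errors import BoundsError, ConfigurationError, DataError


class TestArchitecture:
    def test_full_scale_network_shapes(self):
        """192x96 input -> 6x6 pre-pooling map with 256 channels -> 2 scores."""
        config = ModelConfig()
        assert config.spatial_after_plan() == (6, 6)
        assert config.channel_plan() == [32, 64, 128, 256, 256, 256, 256, 256]
        model = build_model(config, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 192, 96, 1)).astype(np.float32)
        h = x
        for layer in model.layers[:-2]:  # stop before pooling
            h = layer.forward(h, train=True)
        assert h.shape == (1, 6, 6, 256)
        scores = model.layers[-1].forward(model.layers[-2].forward(h, True), True)
        assert scores.shape == (1, 2)

    def test_batch_output_shape(self):
        config = ModelConfig.scaled((16, 16), base_filters=4, max_filters=8)
        model = build_model(config, np.random.default_rng(0))
        x = np.zeros((5, 1, 16, 16), np.float32)
        assert model.forward(x, train=True).shape == (5, 2)

    def test_inconsistent_downsample_plan_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(downsample_plan=((2, 2),) * 8)  # final map would be 1x1

    def test_channel_doubling_caps_at_max_filters(self):
        config = ModelConfig(max_filters=64)
        assert max(config.channel_plan()) == 64


class TestLRSchedule:
    def test_endpoints(self):
        assert lr_schedule(0, 50_000) == pytest.approx(1e-4)
        assert lr_schedule(50_000, 50_000) == 0.0

    def test_midpoint_value(self):
        # 1e-4 * 0.5^0.9
        assert lr_schedule(25_000, 50_000, 1e-4, 0.9) == pytest.approx(5.3589e-5, rel=1e-4)

    def test_monotone_non_increasing(self):
        lrs = [lr_schedule(i, 1000) for i in range(0, 1001, 10)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range_iteration(self):
        with pytest.raises(BoundsError):
            lr_schedule(1001, 1000)


class TestMinibatchSampling:
    def test_all_single_when_p_is_one(self):
        labels = np.array([0] * 50 + [1] * 5)
        idx = sample_minibatch(labels, 0.999999, 32, np.random.default_rng(0))
        assert np.all(labels[idx] == 1)

    def test_empirical_rate_within_three_sigma(self):
        labels = np.array([0] * 500 + [1] * 10)
        rng = np.random.default_rng(1)
        n, p = 100_000, 0.02
        drawn = np.concatenate(
            [labels[sample_minibatch(labels, p, 1000, rng)] for _ in range(100)])
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(drawn.mean() - p) < 3 * sigma

    def test_empty_class_raises(self):
        with pytest.raises(DataError):
            sample_minibatch(np.zeros(10, int), 0.9999999, 64, np.random.default_rng(7))


class TestAugmentation:
    def test_identity_config_is_identity(self):
        x = np.random.default_rng(0).normal(size=(32, 32)).astype(np.float32)
        out = augment(x, AugmentConfig.identity(), np.random.default_rng(1))
        np.testing.assert_array_equal(out, x)

    def test_double_mirror_restores_patch(self):
        cfg = AugmentConfig.identity()
        cfg.p_mirror = 1.0  # deterministically flips both axes
        x = np.random.default_rng(2).normal(size=(16, 16)).astype(np.float32)
        once = augment(x, cfg, np.random.default_rng(0))
        twice = augment(once, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(twice, x)

    def test_cutout_erases_exactly_one_box(self):
        cfg = AugmentConfig.identity()
        cfg.p_cutout, cfg.cutout_size, cfg.cutout_fill = 1.0, 6, 0.0
        x = np.ones((32, 32), np.float32)
        out = augment(x, cfg, np.random.default_rng(3))
        assert int((out == 0).sum()) == 36

    def test_shape_preserved_under_full_pipeline(self):
        cfg = AugmentConfig()  # every transform enabled with default probabilities
        rng = np.random.default_rng(4)
        x = rng.normal(size=(48, 24)).astype(np.float32)
        for _ in range(10):
            assert augment(x, cfg, rng).shape == (48, 24)


class TestFoldsAndTraining:
    def test_stratified_fold_arithmetic_at_experiment_scale(self):
        """100 singles / 19 900 non-singles -> 20 + 3 980 per validation fold."""
        labels = np.concatenate([np.ones(100, int), np.zeros(19_900, int)])
        folds = stratified_folds(labels, 5, seed=0)
        seen = np.concatenate([va for _, va in folds])
        assert len(np.unique(seen)) == 20_000  # exact partition
        for _, va in folds:
            assert labels[va].sum() == 20
            assert len(va) == 4_000

    def test_too_few_minority_members_raises(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        with pytest.raises(DataError):
            stratified_folds(labels, 5, seed=0)

    def _toy_task(self, n_pos=12, n_neg=48, size=12):
        """Bright-square positives vs noise negatives: linearly separable."""
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.3, size=(n_pos + n_neg, size, size)).astype(np.float32)
        y = np.zeros(n_pos + n_neg, int)
        y[:n_pos] = 1
        X[:n_pos, 3:9, 3:9] += 2.0
        return X, y

    def test_loss_decreases_on_separable_toy_task(self):
        X, y = self._toy_task()
        cfg = TrainConfig(batch_size=8, p_single_in_batch=0.3, lr0=1e-3,
                          augmentation=AugmentConfig.identity(), seed=0)
        mc = ModelConfig(input_size=(12, 12), base_filters=4, max_filters=8,
                         n_residual_blocks=2, downsample_plan=((2, 2), (2, 2)),
                         final_size=(3, 3))
        model, trace = train_fold(X, y, cfg, mc, np.random.default_rng(0),
                                  iterations=150)
        assert np.mean(trace[-2:]) < np.mean(trace[:2]) * 0.7

    def test_training_is_deterministic_for_fixed_seeds(self):
        X, y = self._toy_task()
        cfg = TrainConfig(batch_size=8, p_single_in_batch=0.3,
                          augmentation=AugmentConfig.identity(), seed=0)
        mc = ModelConfig(input_size=(12, 12), base_filters=4, max_filters=8,
                         n_residual_blocks=2, downsample_plan=((2, 2), (2, 2)),
                         final_size=(3, 3))
        traces = []
        for _ in range(2):
            _, trace = train_fold(X, y, cfg, mc, np.random.default_rng(5),
                                  iterations=30)
            traces.append(trace)
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_single_class_partition_rejected(self):
        X = np.zeros((10, 12, 12), np.float32)
        y = np.zeros(10, int)
        cfg = TrainConfig(seed=0)
        mc = ModelConfig(input_size=(12, 12), base_filters=4, max_filters=8,
                         n_residual_blocks=2, downsample_plan=((2, 2), (2, 2)),
                         final_size=(3, 3))
        with pytest.raises(DataError):
            train_fold(X, y, cfg, mc, np.random.default_rng(0), iterations=5)


class TestVariantConfigs:
    def test_high_recall_variant_settings(self):
        cfg = TrainConfig.moresh(seed=1)
        assert cfg.p_single_in_batch == pytest.approx(0.05)
        assert cfg.class_loss_weights == (0.1, 0.9)

    def test_default_recipe_constants(self):
        cfg = TrainConfig.maxf1(seed=1)
        assert (cfg.lr0, cfg.batch_size) == (1e-4, 64)
        assert cfg.total_iterations == 50_000
        assert cfg.p_single_in_batch == pytest.approx(0.02)
        # expected singles per minibatch at the 2% presentation rate
        assert cfg.batch_size * cfg.p_single_in_batch == pytest.approx(1.28)

    def test_invalid_sampling_probability(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(p_single_in_batch=1.5)
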