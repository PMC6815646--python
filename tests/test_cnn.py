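"""CNN architecture arithmetic, LRN, training loop, and prediction."""

import numpy as np
import pytest

from ehgpipe.cnn import (
    CNNArchitecture,
    ConvSpec,
    FCSpec,
    PoolSpec,
    TrainConfig,
    aggregate_segment_prediction,
    build_architecture,
    conv_output_size,
    default_train_config,
    lrn,
    pool_output_size,
    predict,
    train,
)

# narrated feature-map sequence of the reference network on a 482-px input
PAPER_SPATIAL = [92, 31, 30, 15, 13, 13, 13, 6]
PAPER_CHANNELS = [96, 96, 256, 256, 384, 384, 256, 256]


class TestShapeArithmetic:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((482, 27, 5, 0), 92),
            ((31, 2, 1, 0), 30),
            ((15, 3, 1, 0), 13),
            ((13, 3, 1, 1), 13),
            ((7, 1, 1, 0), 7),  # identity convolution
        ],
    )
    def test_conv_output_size(self, args, expected):
        assert conv_output_size(*args) == expected

    @pytest.mark.parametrize(
        "args,expected", [((92, 2, 3), 31), ((30, 2, 2), 15), ((13, 3, 2), 6)]
    )
    def test_pool_output_size(self, args, expected):
        assert pool_output_size(*args) == expected

    def test_oversized_kernels_rejected(self):
        with pytest.raises(ValueError):
            conv_output_size(4, 7, 1, 1)
        with pytest.raises(ValueError):
            pool_output_size(4, 7, 1)


class TestArchitecture:
    def test_reference_variant_reproduces_narrated_trace(self):
        trace = build_architecture("paper").shape_trace()
        assert [s for s, _ in trace] == PAPER_SPATIAL
        assert [c for _, c in trace] == PAPER_CHANNELS

    def test_literal_pad_breaks_the_trace(self):
        trace = build_architecture("paper", pad_literal=True).shape_trace()
        assert [s for s, _ in trace] != PAPER_SPATIAL

    def test_fc_widths_and_softmax_head(self):
        for variant, width in (("paper", 4096), ("scaled", 256)):
            fcs = [
                l for l in build_architecture(variant).layers if isinstance(l, FCSpec)
            ]
            assert [f.num_output for f in fcs] == [width, width, 2]
            assert fcs[-1].relu is False

    def test_parameter_count_is_finite_and_positive(self):
        assert 0 < build_architecture("scaled").parameter_count() < 10**6
        assert build_architecture("paper").parameter_count() > 10**7


class TestLRN:
    def test_alpha_zero_is_identity(self, rng):
        a = rng.standard_normal((2, 6, 4, 4))
        np.testing.assert_array_equal(lrn(a, alpha=0.0, k=1.0), a)

    def test_single_channel_closed_form(self):
        a = np.ones((1, 1, 1, 1))
        expected = 1.0 / (1.0 + 0.0001 / 5.0) ** 0.75
        assert lrn(a)[0, 0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_not_homogeneous(self, rng):
        a = rng.standard_normal((1, 4, 3, 3)) * 50
        assert not np.allclose(lrn(2 * a), 2 * lrn(a))

    def test_matches_per_unit_loop(self, rng):
        """Vectorized LRN equals an explicit per-unit implementation."""
        a = rng.standard_normal((2, 4, 3, 3))
        n, alpha, beta, k = 5, 0.0001, 0.75, 1.0
        expected = np.empty_like(a)
        half = (n - 1) // 2
        for b in range(2):
            for c in range(4):
                for i in range(3):
                    for j in range(3):
                        w = a[b, max(0, c - half) : min(4, c + half + 1), i, j]
                        denom = (k + (alpha / n) * np.sum(w**2)) ** beta
                        expected[b, c, i, j] = a[b, c, i, j] / denom
        np.testing.assert_allclose(lrn(a, n, alpha, beta, k), expected, atol=1e-10)

    def test_even_local_size_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            lrn(rng.standard_normal((1, 4, 2, 2)), local_size=4)


def _tiny_arch() -> CNNArchitecture:
    return CNNArchitecture(
        input_size=24,
        layers=[
            ConvSpec(5, 2, 0, 4, lrn=True),
            PoolSpec(2, 2),
            FCSpec(8, relu=True),
            FCSpec(2, relu=False),
        ],
        name="tiny",
    )


def _separable_images(n_per_class=24, size=24, seed=0):
    """Dark-left vs dark-right images: linearly separable toy task."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            img = np.ones((size, size), dtype=np.float32)
            img += 0.05 * rng.standard_normal((size, size)).astype(np.float32)
            if label:
                img[:, size // 2 :] *= 0.2
            else:
                img[:, : size // 2] *= 0.2
            xs.append(np.clip(img, 0, 1))
            ys.append("UC" if label else "nonUC")
    return np.stack(xs), ys


class TestTraining:
    def test_fixed_seed_reproduces_training_exactly(self):
        x, y = _separable_images()
        cfg = TrainConfig(weight_init_std="he", batch_size=8, epochs=3, seed=11)
        m1 = train(x, y, cfg, _tiny_arch())
        m2 = train(x, y, cfg, _tiny_arch())
        assert m1.log["loss"] == m2.log["loss"]
        assert m1.log["val_accuracy"] == m2.log["val_accuracy"]

    def test_first_iteration_loss_near_chance(self):
        """With near-zero symmetric init, softmax cross-entropy starts at ln 2."""
        x, y = _separable_images()
        cfg = TrainConfig(weight_init_std=0.01, batch_size=16, epochs=1, seed=0)
        model = train(x, y, cfg, _tiny_arch())
        assert abs(model.log["loss"][0] - np.log(2)) < 0.15

    def test_loss_decreases_on_separable_data(self):
        x, y = _separable_images()
        cfg = TrainConfig(weight_init_std="he", batch_size=8, epochs=6, seed=1)
        model = train(x, y, cfg, _tiny_arch())
        losses = np.array(model.log["loss"])
        per_epoch = losses.reshape(model.log["epochs_run"], -1).mean(axis=1)
        assert per_epoch[-1] < per_epoch[0]

    def test_single_class_and_empty_inputs_rejected(self):
        x, y = _separable_images(n_per_class=4)
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError, match="both classes"):
            train(x[:4], y[:4], cfg, _tiny_arch())
        with pytest.raises(ValueError, match="no training images"):
            train(x[:0], [], cfg, _tiny_arch())

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(dropout_ratio=1.0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(bias_init=0.0)


@pytest.fixture(scope="module")
def model():
    x, y = _separable_images()
    cfg = TrainConfig(weight_init_std="he", batch_size=8, epochs=5, seed=2)
    return train(x, y, cfg, _tiny_arch())


class TestPrediction:
    def test_probabilities_sum_to_one(self, model):
        x, _ = _separable_images(seed=9)
        probs = predict(model, x)
        assert probs.shape == (x.shape[0], 2)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batched_equals_one_at_a_time(self, model):
        x, _ = _separable_images(n_per_class=3, seed=9)
        batched = predict(model, x)
        singles = np.vstack([predict(model, x[i : i + 1]) for i in range(x.shape[0])])
        np.testing.assert_allclose(batched, singles, atol=1e-5)

    def test_duplicate_images_get_identical_probabilities(self, model):
        x, _ = _separable_images(n_per_class=1, seed=9)
        probs = predict(model, np.concatenate([x[:1], x[:1]]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_size_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="does not match model input"):
            predict(model, np.ones((1, 32, 32), dtype=np.float32))


class TestAggregation:
    def test_unanimous_channels(self):
        probs = np.tile([0.1, 0.9], (16, 1))
        assert aggregate_segment_prediction(probs, "mean") == "UC"
        assert aggregate_segment_prediction(probs, "majority") == "UC"

    def test_majority_tie_breaks_conservatively(self):
        probs = np.vstack([np.tile([0.4, 0.6], (8, 1)), np.tile([0.6, 0.4], (8, 1))])
        assert aggregate_segment_prediction(probs, "majority") == "nonUC"

    def test_rules_agree_when_all_channels_agree(self, rng):
        probs = np.tile([0.2, 0.8], (16, 1)) + rng.uniform(-0.05, 0.05, (16, 1))
        probs = np.clip(probs, 0, 1)
        probs /= probs.sum(axis=1, keepdims=True)
        assert aggregate_segment_prediction(probs, "mean") == aggregate_segment_prediction(
            probs, "majority"
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_segment_prediction(np.ones((0, 2)))
        with pytest.raises(ValueError):
            aggregate_segment_prediction(np.ones((4, 3)))
        with pytest.raises(ValueError, match="unknown aggregation"):
            aggregate_segment_prediction(np.ones((4, 2)) / 2, rule="median")


def test_default_train_configs_by_variant():
    paper = default_train_config("paper")
    assert paper.weight_init_std == 0.1 and paper.batch_size == 64
    assert paper.learning_rate == 0.001 and paper.weight_decay == 0.0005
    assert paper.momentum == 0.9 and paper.lr_drop_factor == 0.1
    assert paper.lr_drop_period == 10 and paper.max_iterations == 20000
    scaled = default_train_config("scaled", epochs=3)
    assert scaled.weight_init_std == "he" and scaled.epochs == 3
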