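"""CNN architectures and training: shape arithmetic, learning, determinism."""

import numpy as np
import pytest

from emgpix import (
    CnnGestureClassifier,
    ModelSpec,
    TrainConfig,
    build_spectral_cnn,
    build_time_cnn,
    load_model,
    predict,
    save_model,
    train,
)
from emgpix.models import build_model
from emgpix.exceptions import ConfigError, DimensionError, ParameterError

# Hand-computed shape tables from the floor-based conv/pool arithmetic:
#   conv 3x3 pad 1 keeps HxW; conv 3x3 valid removes 2; pool floor-divides.
EXPECTED_TRACES = {
    ("time_cnn", (16, 250)): [
        ("input", (1, 16, 250)),
        ("Conv2D", (32, 16, 250)),
        ("BatchNorm2d", (32, 16, 250)),
        ("ReLU", (32, 16, 250)),
        ("MaxPool2d", (32, 16, 83)),
        ("Conv2D", (64, 14, 81)),
        ("BatchNorm2d", (64, 14, 81)),
        ("ReLU", (64, 14, 81)),
        ("MaxPool2d", (64, 14, 40)),
        ("Flatten", (35840,)),
        ("Linear", (128,)),
        ("Linear", (10,)),
        ("Softmax", (10,)),
    ],
    ("time_cnn", (8, 250)): [
        ("input", (1, 8, 250)),
        ("Conv2D", (32, 8, 250)),
        ("BatchNorm2d", (32, 8, 250)),
        ("ReLU", (32, 8, 250)),
        ("MaxPool2d", (32, 8, 83)),
        ("Conv2D", (64, 6, 81)),
        ("BatchNorm2d", (64, 6, 81)),
        ("ReLU", (64, 6, 81)),
        ("MaxPool2d", (64, 6, 40)),
        ("Flatten", (15360,)),
        ("Linear", (128,)),
        ("Linear", (10,)),
        ("Softmax", (10,)),
    ],
    ("spectral_cnn", (64, 129)): [
        ("input", (1, 64, 129)),
        ("Conv2D", (32, 64, 129)),
        ("BatchNorm2d", (32, 64, 129)),
        ("ReLU", (32, 64, 129)),
        ("MaxPool2d", (32, 32, 64)),
        ("Conv2D", (64, 30, 62)),
        ("BatchNorm2d", (64, 30, 62)),
        ("ReLU", (64, 30, 62)),
        ("MaxPool2d", (64, 15, 31)),
        ("Flatten", (29760,)),
        ("Linear", (128,)),
        ("Linear", (10,)),
        ("Softmax", (10,)),
    ],
    ("spectral_cnn", (32, 129)): [
        ("input", (1, 32, 129)),
        ("Conv2D", (32, 32, 129)),
        ("BatchNorm2d", (32, 32, 129)),
        ("ReLU", (32, 32, 129)),
        ("MaxPool2d", (32, 16, 64)),
        ("Conv2D", (64, 14, 62)),
        ("BatchNorm2d", (64, 14, 62)),
        ("ReLU", (64, 14, 62)),
        ("MaxPool2d", (64, 7, 31)),
        ("Flatten", (13888,)),
        ("Linear", (128,)),
        ("Linear", (10,)),
        ("Softmax", (10,)),
    ],
}


def separable_images(n_per_class, shape, n_classes=2, seed=0):
    """Tiny synthetic image set: each class lights a disjoint region."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    X, y = [], []
    band = rows // n_classes
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = 0.05 * rng.random((rows, cols))
            img[c * band:(c + 1) * band] += 0.9
            X.append(np.clip(img, 0, 1))
            y.append(c)
    return np.asarray(X, dtype=np.float32), np.asarray(y)


class TestArchitectures:
    @pytest.mark.parametrize("key", list(EXPECTED_TRACES))
    def test_layer_shapes_match_hand_computed_arithmetic(self, key):
        arch, shape = key
        net = build_model(ModelSpec(arch=arch, input_shape=shape))
        got = [(name, s) for name, s in net.shape_trace_]
        assert got == EXPECTED_TRACES[key]

    @pytest.mark.parametrize("rows", [32, 36, 64, 68])
    def test_spectral_cnn_accepts_plain_and_enhanced_inputs(self, rows):
        net = build_spectral_cnn(ModelSpec(arch="spectral_cnn", input_shape=(rows, 129)))
        x = np.random.default_rng(0).random((2, rows, 129), dtype=np.float32)
        probs = predict(net, x)
        assert probs.shape == (2, 10)

    def test_architecture_parity_plain_vs_enhanced(self):
        """Parameter-count difference is confined to the first dense layer."""
        plain = build_spectral_cnn(ModelSpec(arch="spectral_cnn", input_shape=(64, 129)))
        enh = build_spectral_cnn(ModelSpec(arch="spectral_cnn", input_shape=(68, 129)))
        counts_p = plain.parameter_counts()
        counts_e = enh.parameter_counts()
        assert [n for n, _ in counts_p] == [n for n, _ in counts_e]
        diffs = [i for i, ((_, a), (_, b)) in enumerate(zip(counts_p, counts_e)) if a != b]
        first_linear = [n for n, _ in counts_p].index("Linear")
        assert diffs == [first_linear]

    @pytest.mark.parametrize(
        "arch,shape",
        [("time_cnn", (16, 250)), ("spectral_cnn", (64, 129))],
    )
    def test_forward_is_a_probability_vector(self, arch, shape):
        net = build_model(ModelSpec(arch=arch, input_shape=shape))
        for img in (np.zeros((1,) + shape), np.ones((1,) + shape)):
            probs = predict(net, img.astype(np.float32))
            assert probs.shape == (1, 10)
            assert np.all(probs >= 0) and np.all(probs <= 1)
            assert probs.sum() == pytest.approx(1.0, abs=1e-5)

    def test_unsupported_input_rows_rejected(self):
        with pytest.raises(DimensionError):
            ModelSpec(arch="time_cnn", input_shape=(12, 250))
        with pytest.raises(DimensionError):
            ModelSpec(arch="spectral_cnn", input_shape=(16, 129))

    def test_unknown_arch_rejected(self):
        with pytest.raises(ParameterError):
            ModelSpec(arch="mlp", input_shape=(16, 250))


class TestTraining:
    def test_overfits_tiny_separable_set(self):
        X, y = separable_images(10, (32, 129))
        net = build_spectral_cnn(
            ModelSpec(arch="spectral_cnn", input_shape=(32, 129), n_classes=2), seed=0
        )
        _, history = train(net, X, TrainConfig(epochs=30, seed=0), labels=y)
        assert history[-1]["accuracy"] == 1.0

    def test_fixed_seed_reproduces_loss_curve(self):
        X, y = separable_images(5, (32, 129))
        cfg = TrainConfig(epochs=3, seed=7)
        spec = ModelSpec(arch="spectral_cnn", input_shape=(32, 129), n_classes=2)
        _, h1 = train(build_spectral_cnn(spec, seed=7), X, cfg, labels=y)
        _, h2 = train(build_spectral_cnn(spec, seed=7), X, cfg, labels=y)
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]

    def test_history_has_one_entry_per_epoch(self):
        X, y = separable_images(3, (32, 129))
        spec = ModelSpec(arch="spectral_cnn", input_shape=(32, 129), n_classes=2)
        _, history = train(build_spectral_cnn(spec), X, TrainConfig(epochs=1), labels=y)
        assert len(history) == 1

    def test_missing_class_rejected(self):
        X, y = separable_images(4, (32, 129))
        spec = ModelSpec(arch="spectral_cnn", input_shape=(32, 129), n_classes=3)
        with pytest.raises(ConfigError):
            train(build_spectral_cnn(spec), X, TrainConfig(epochs=1), labels=y)

    def test_shape_mismatch_rejected(self):
        X, y = separable_images(2, (32, 129))
        spec = ModelSpec(arch="spectral_cnn", input_shape=(64, 129), n_classes=2)
        with pytest.raises(DimensionError):
            train(build_spectral_cnn(spec), X, TrainConfig(epochs=1), labels=y)

    def test_prediction_is_stable_across_calls(self):
        X, y = separable_images(3, (32, 129))
        spec = ModelSpec(arch="spectral_cnn", input_shape=(32, 129), n_classes=2)
        net, _ = train(build_spectral_cnn(spec), X, TrainConfig(epochs=2), labels=y)
        p1 = predict(net, X[0])
        p2 = predict(net, X[0])
        assert np.array_equal(p1, p2)


class TestEstimatorAndSerialization:
    def test_sklearn_estimator_roundtrip(self, tmp_path):
        X, y = separable_images(8, (32, 129))
        clf = CnnGestureClassifier(epochs=10, seed=1)
        clf.fit(X, y)
        assert clf.score(X, y) == 1.0
        assert list(clf.classes_) == [0, 1]
        path = save_model(clf.net_, clf.spec_, tmp_path / "model.npz")
        net, spec = load_model(path)
        np.testing.assert_array_equal(predict(net, X), clf.predict_proba(X))

    def test_estimator_get_set_params(self):
        clf = CnnGestureClassifier(epochs=3)
        params = clf.get_params()
        assert params["epochs"] == 3
        clf.set_params(epochs=5)
        assert clf.epochs == 5

    def test_estimator_accepts_flattened_input_with_shape(self):
        X, y = separable_images(4, (32, 129))
        clf = CnnGestureClassifier(epochs=2, image_shape=(32, 129))
        clf.fit(X.reshape(len(X), -1), y)
        assert clf.predict(X.reshape(len(X), -1)).shape == (len(X),)
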