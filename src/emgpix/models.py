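"""The two gesture-recognition CNNs and their training harness.

Both networks share one template — two conv/batch-norm/ReLU blocks with max
pooling, two fully connected layers and a softmax over the 10 gestures —
and differ only in their pooling geometry, matched to the image type:

``time_cnn``  (channels x time images, 16x250 or 8x250)
    conv(32, 3x3, stride 1, pad 1) -> BN -> ReLU -> maxpool over 3 time
    columns -> conv(64, 3x3, valid) -> BN -> ReLU -> maxpool over 2 time
    columns -> FC(128) -> FC(10) -> softmax.  Pooling spans the time axis
    only: with as few as 8 channel rows, pooling rows would leave the second
    valid 3x3 convolution without output.

``spectral_cnn``  (stacked spectrograms, {32,36,64,68} x 129)
    identical except both pools are 2x2.

Training minimizes cross-entropy with Adam on shuffled mini-batches; all
randomness (weight init, shuffling) derives from one integer seed, so a
fixed seed reproduces loss curves bit-for-bit.

The scikit-learn entry point is :class:`CnnGestureClassifier`; the
module-level :func:`build_time_cnn`, :func:`build_spectral_cnn`,
:func:`train` and :func:`predict` functions are thin wrappers around the
same engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .encode import EncodedImage
from .exceptions import ConfigError, DimensionError, DomainError, ParameterError

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "build_time_cnn",
    "build_spectral_cnn",
    "build_model",
    "train",
    "predict",
    "CnnGestureClassifier",
    "save_model",
    "load_model",
]

_TIME_ROWS = (8, 16)
_SPECTRAL_ROWS = (32, 36, 64, 68)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture selector plus input geometry."""

    arch: str  # "time_cnn" | "spectral_cnn"
    input_shape: tuple[int, int]
    n_classes: int = 10
    fc_hidden: int = 128

    def __post_init__(self) -> None:
        if self.arch not in ("time_cnn", "spectral_cnn"):
            raise ParameterError(f"unknown arch {self.arch!r}")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        rows = self.input_shape[0]
        allowed = _TIME_ROWS if self.arch == "time_cnn" else _SPECTRAL_ROWS
        if rows not in allowed:
            raise DimensionError(
                f"{self.arch} expects input rows in {allowed}, got {rows}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults (Adam, lr 1e-3, batch 32, 3 epochs) are tuned to the package's
    synthetic datasets, which separate within a few epochs; raise ``epochs``
    for harder data.  ``test_size`` is the held-out fraction of
    (subject, repetition) groups used by the comparison harness.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 3
    seed: int = 0
    test_size: float = 0.2

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ParameterError(f"unsupported optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if not (0 < self.test_size < 1):
            raise ParameterError("test_size must be in (0, 1)")


def _build(spec: ModelSpec, pools: tuple[tuple[int, int], tuple[int, int]],
           seed: int) -> _nn.Sequential:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    rows, cols = spec.input_shape
    layers: list[_nn.Layer] = [
        _nn.Conv2D(1, 32, kernel=3, stride=1, pad=1, rng=rng),
        _nn.BatchNorm2d(32),
        _nn.ReLU(),
        _nn.MaxPool2d(pools[0]),
        _nn.Conv2D(32, 64, kernel=3, stride=1, pad=0, rng=rng),
        _nn.BatchNorm2d(64),
        _nn.ReLU(),
        _nn.MaxPool2d(pools[1]),
        _nn.Flatten(),
    ]
    # Probe the conv/pool chain to size the first dense layer.
    probe = _nn.Sequential(layers, (1, rows, cols))
    flat = probe.shape_trace_[-1][1][0]
    layers = layers + [
        _nn.Linear(flat, spec.fc_hidden, rng=rng),
        _nn.Linear(spec.fc_hidden, spec.n_classes, rng=rng),
        _nn.Softmax(),
    ]
    return _nn.Sequential(layers, (1, rows, cols))


def build_time_cnn(spec: ModelSpec, seed: int = 0) -> _nn.Sequential:
    """CNN for channels-x-time images; pools span 3 then 2 time columns."""
    if spec.arch != "time_cnn":
        raise ParameterError("spec.arch must be 'time_cnn'")
    return _build(spec, ((1, 3), (1, 2)), seed)


def build_spectral_cnn(spec: ModelSpec, seed: int = 0) -> _nn.Sequential:
    """CNN for stacked-spectrogram images; both pools are 2x2.

    The same architecture accepts plain (32/64-row) and feature-enhanced
    (36/68-row) inputs; only the first dense layer's fan-in changes.
    """
    if spec.arch != "spectral_cnn":
        raise ParameterError("spec.arch must be 'spectral_cnn'")
    return _build(spec, ((2, 2), (2, 2)), seed)


def build_model(spec: ModelSpec, seed: int = 0) -> _nn.Sequential:
    builder = build_time_cnn if spec.arch == "time_cnn" else build_spectral_cnn
    return builder(spec, seed)


def _as_batch(images) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept a (n, rows, cols) array or a list of EncodedImage."""
    if len(images) and isinstance(images[0], EncodedImage):
        X = np.stack([im.pixels for im in images])
        y = np.asarray([im.label for im in images])
        return X, y
    X = np.asarray(images, dtype=np.float32)
    if X.ndim != 3:
        raise DimensionError(f"expected (n, rows, cols) images, got shape {X.shape}")
    return X, None


def train(model: _nn.Sequential, images, cfg: TrainConfig | None = None,
          labels=None) -> tuple[_nn.Sequential, list[dict]]:
    """Fit a model in place; returns ``(model, history)``.

    ``images`` is either a list of :class:`EncodedImage` (labels embedded)
    or an array ``(n, rows, cols)`` with ``labels`` given separately.
    ``history`` holds one ``{"epoch", "loss", "accuracy"}`` record per epoch
    (training loss/accuracy); a fixed ``cfg.seed`` reproduces it exactly.
    """
    cfg = cfg or TrainConfig()
    X, y_embedded = _as_batch(images)
    if labels is None and y_embedded is None:
        raise DimensionError("labels are required when images carry none")
    y = np.asarray(labels if labels is not None else y_embedded)
    if y.shape[0] != X.shape[0]:
        raise DimensionError("labels must match the number of images")
    n_classes = model.shape_trace_[-1][1][0]
    if y.min() < 0 or y.max() >= n_classes:
        raise DomainError(f"labels must lie in 0..{n_classes - 1}")
    if X.shape[1:] != model.input_shape[1:]:
        raise DimensionError(
            f"images of shape {X.shape[1:]} do not match model input "
            f"{model.input_shape[1:]}"
        )
    missing = set(range(n_classes)) - set(np.unique(y).tolist())
    if missing:
        raise ConfigError(f"classes absent from the training partition: {sorted(missing)}")

    X = X[:, None, :, :].astype(np.float32)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(11,)))
    opt = _nn.Adam(model, lr=cfg.learning_rate)
    history = []
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(X[idx], train=True, logits=True)
            loss, grad = _nn.softmax_cross_entropy(logits, y[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=-1) == y[idx]).sum())
        history.append({
            "epoch": epoch + 1,
            "loss": float(np.sum(losses) / n),
            "accuracy": float(correct / n),
        })
    return model, history


def predict(model: _nn.Sequential, image, batch_size: int = 64) -> np.ndarray:
    """Class-probability vector(s) for one image or a batch.

    Inference runs with batch-norm statistics frozen, so repeated calls on
    the same input return identical probabilities; the argmax is the
    predicted gesture id.  Large batches are evaluated in chunks of
    ``batch_size`` to bound the convolution workspace.
    """
    if isinstance(image, EncodedImage):
        image = image.pixels
    x = np.asarray(image, dtype=np.float32)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3:
        raise DimensionError(f"expected one image or a batch, got shape {x.shape}")
    probs = np.concatenate([
        model.forward(x[i:i + batch_size, None, :, :], train=False)
        for i in range(0, x.shape[0], batch_size)
    ])
    return probs[0] if single else probs


class CnnGestureClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator around the gesture CNNs.

    Parameters
    ----------
    arch : {"spectral_cnn", "time_cnn", "auto"}
        Architecture; ``"auto"`` picks ``time_cnn`` for 8/16-row images and
        ``spectral_cnn`` otherwise.
    fc_hidden, learning_rate, batch_size, epochs, seed
        See :class:`ModelSpec` / :class:`TrainConfig`.

    ``fit`` expects ``X`` of shape ``(n_images, rows, cols)`` (or flattened
    ``(n, rows*cols)`` together with ``image_shape``).  Fitted attributes:
    ``classes_``, ``net_``, ``history_``, ``spec_``.
    """

    def __init__(self, arch: str = "auto", fc_hidden: int = 128,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 epochs: int = 3, seed: int = 0,
                 image_shape: tuple[int, int] | None = None):
        self.arch = arch
        self.fc_hidden = fc_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.image_shape = image_shape

    def _coerce(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2 and self.image_shape is not None:
            X = X.reshape(len(X), *self.image_shape)
        if X.ndim != 3:
            raise DimensionError(
                f"expected (n, rows, cols) images (got {X.shape}); "
                "pass image_shape to accept flattened input"
            )
        return X

    def fit(self, X, y):
        X = self._coerce(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ConfigError("need at least 2 classes to fit")
        rows, cols = X.shape[1:]
        arch = self.arch
        if arch == "auto":
            arch = "time_cnn" if rows in _TIME_ROWS else "spectral_cnn"
        self.spec_ = ModelSpec(arch=arch, input_shape=(rows, cols),
                               n_classes=len(self.classes_), fc_hidden=self.fc_hidden)
        self.net_ = build_model(self.spec_, seed=self.seed)
        cfg = TrainConfig(learning_rate=self.learning_rate,
                          batch_size=self.batch_size, epochs=self.epochs,
                          seed=self.seed)
        _, self.history_ = train(self.net_, X, cfg, labels=y_enc)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._coerce(X)
        return predict(self.net_, X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=-1)]

    def score(self, X, y, sample_weight=None) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def save_model(model: _nn.Sequential, spec: ModelSpec, path) -> Path:
    """Serialize weights plus an embedded architecture manifest (.npz)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    manifest = json.dumps(asdict(spec))
    np.savez(path, __manifest__=np.array(manifest), **model.state_dict())
    return path


def load_model(path) -> tuple[_nn.Sequential, ModelSpec]:
    with np.load(Path(path), allow_pickle=False) as data:
        manifest = json.loads(str(data["__manifest__"]))
        manifest["input_shape"] = tuple(manifest["input_shape"])
        spec = ModelSpec(**manifest)
        model = build_model(spec)
        model.load_state_dict({k: v for k, v in data.items() if k != "__manifest__"})
    return model, spec
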