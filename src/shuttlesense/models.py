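"""Stroke classifier architectures and sklearn-style estimators.

Two fixed architectures are provided, both consuming a raw scaled frame of
shape (L, C) — L samples by C channels — and emitting a 9-way softmax:

* **CNN** — the frame enters as a single-plane L×C image and passes through
  two valid (unpadded, unit-stride) 3×3 convolutions with 16 and 32
  filters, batch normalisation and dropout, then a 64-unit dense layer
  with L2 penalties and the softmax output.  For an 80×6 input the layer
  outputs are 78×4×16 → 76×2×32 → 4864 → 64 → 9, totalling 316,809
  parameters (batch normalisation contributing four vectors per channel:
  scale, shift, running mean, running variance).
* **DNN** — a convolution-free alternative for low-cost deployments: dense
  layers of width 1024 → 512 → 256 → 128 → 32 applied independently at
  every timestep (each followed by 20% dropout), flattened to L·32 and fed
  to the softmax output.

Architectures are described declaratively by :class:`ArchitectureSpec`
(layer kinds, shapes and closed-form parameter counts) and realised as
NumPy networks for training.  :class:`CNNClassifier` and
:class:`DNNClassifier` wrap training and inference in the scikit-learn
estimator protocol, so they compose with sklearn pipelines and model
selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import _nn
from .preprocessing import FrameSet
from .signal_io import CLASSES

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TrainConfig",
    "build_cnn",
    "build_dnn",
    "count_parameters",
    "CNNClassifier",
    "DNNClassifier",
    "TrainedModel",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: Table-2-style DNN hidden widths, applied per timestep.
DNN_HIDDEN_WIDTHS = (1024, 512, 256, 128, 32)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a declarative architecture.

    ``config`` carries the fields needed to realise the layer and to count
    its parameters in closed form (kernel geometry, fan-in/out, rates).
    """

    kind: str  # conv | batchnorm | dropout | flatten | dense
    output_shape: tuple[int, ...]
    config: dict[str, Any] = field(default_factory=dict)

    def n_params(self) -> int:
        c = self.config
        if self.kind == "conv":
            kh, kw = c["kernel"]
            return c["filters"] * (kh * kw * c["c_in"] + 1)
        if self.kind == "batchnorm":
            # scale, shift, running mean, running variance
            return 4 * c["channels"]
        if self.kind == "dense":
            return c["n_in"] * c["n_out"] + c["n_out"]
        return 0


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative network definition: kind, input geometry, layer list."""

    kind: str  # "cnn" | "dnn"
    input_shape: tuple[int, int]  # (L, C)
    n_classes: int
    layers: tuple[LayerSpec, ...]

    @property
    def frame_len(self) -> int:
        return self.input_shape[0]

    @property
    def n_channels(self) -> int:
        return self.input_shape[1]


def build_cnn(frame_len: int, n_channels: int, n_classes: int = len(CLASSES),
              l2: float = 1e-4) -> ArchitectureSpec:
    """CNN spec for an (L, C) frame treated as a single-plane image.

    Both convolutions are valid and unit-stride, so each shrinks the time
    axis by 2.  The channel axis also shrinks by 2 per 3-wide kernel; for
    accelerometer-only input (C = 3) the second kernel narrows to 3×1,
    since a second 3-wide valid convolution would underflow the single
    remaining channel column.
    """
    if frame_len < 5:
        raise ValueError(f"frame_len must be ≥ 5 for two valid 3-tap convolutions, got {frame_len}")
    if n_channels < 3:
        raise ValueError(f"need at least 3 channels, got {n_channels}")
    if n_classes < 2:
        raise ValueError("need at least two classes")

    L, C = frame_len, n_channels
    layers: list[LayerSpec] = []
    h, w = L - 2, C - 2
    layers.append(LayerSpec("conv", (h, w, 16),
                            {"filters": 16, "kernel": (3, 3), "c_in": 1, "relu": True}))
    layers.append(LayerSpec("batchnorm", (h, w, 16), {"channels": 16}))
    layers.append(LayerSpec("dropout", (h, w, 16), {"rate": 0.10}))
    k2 = (3, 3) if w >= 3 else (3, 1)
    h2, w2 = h - k2[0] + 1, w - k2[1] + 1
    layers.append(LayerSpec("conv", (h2, w2, 32),
                            {"filters": 32, "kernel": k2, "c_in": 16, "relu": True}))
    layers.append(LayerSpec("dropout", (h2, w2, 32), {"rate": 0.20}))
    flat = h2 * w2 * 32
    layers.append(LayerSpec("flatten", (flat,), {}))
    layers.append(LayerSpec("dense", (64,),
                            {"n_in": flat, "n_out": 64, "relu": True,
                             "l2_kernel": l2, "l2_bias": l2}))
    layers.append(LayerSpec("dense", (n_classes,),
                            {"n_in": 64, "n_out": n_classes, "relu": False}))
    return ArchitectureSpec("cnn", (L, C), n_classes, tuple(layers))


def build_dnn(frame_len: int, n_channels: int, n_classes: int = len(CLASSES)) -> ArchitectureSpec:
    """Convolution-free spec: per-timestep dense stack, flatten, softmax."""
    if frame_len < 1 or n_channels < 1:
        raise ValueError("frame_len and n_channels must be positive")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    L = frame_len
    layers: list[LayerSpec] = []
    width_in = n_channels
    for width in DNN_HIDDEN_WIDTHS:
        layers.append(LayerSpec("dense", (L, width),
                                {"n_in": width_in, "n_out": width, "relu": True}))
        layers.append(LayerSpec("dropout", (L, width), {"rate": 0.20}))
        width_in = width
    flat = L * width_in
    layers.append(LayerSpec("flatten", (flat,), {}))
    layers.append(LayerSpec("dense", (n_classes,),
                            {"n_in": flat, "n_out": n_classes, "relu": False}))
    return ArchitectureSpec("dnn", (L, n_channels), n_classes, tuple(layers))


def count_parameters(spec: ArchitectureSpec) -> int:
    """Closed-form trainable-parameter total of a spec (batch normalisation
    counted as four vectors per channel)."""
    return sum(layer.n_params() for layer in spec.layers)


def realize(spec: ArchitectureSpec, rng: np.random.Generator) -> _nn.Network:
    """Instantiate a spec as a NumPy network with seeded initial weights."""
    layers: list[_nn.Layer] = []
    for ls in spec.layers:
        c = ls.config
        if ls.kind == "conv":
            layers.append(_nn.Conv2D(c["c_in"], c["filters"], tuple(c["kernel"]), rng))
        elif ls.kind == "batchnorm":
            layers.append(_nn.BatchNorm(c["channels"]))
        elif ls.kind == "dropout":
            layers.append(_nn.Dropout(c["rate"]))
        elif ls.kind == "flatten":
            layers.append(_nn.Flatten())
        elif ls.kind == "dense":
            layers.append(_nn.Dense(c["n_in"], c["n_out"], rng, relu=c["relu"],
                                    l2_kernel=c.get("l2_kernel", 0.0),
                                    l2_bias=c.get("l2_bias", 0.0)))
        else:
            raise ValueError(f"unknown layer kind {ls.kind!r}")
    return _nn.Network(layers)


@dataclass
class TrainConfig:
    """Training hyperparameters; the seed fixes initialisation and shuffling."""

    epochs: int = 50
    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError(f"val_fraction must be in [0, 1), got {self.val_fraction}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


class _BaseStrokeClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery for the two architectures.

    ``X`` is a 3-D array of frames, shape (n_frames, L, C); ``y`` an array
    of class labels.  ``classes`` fixes the output vocabulary (ordered);
    when omitted it is inferred from ``y``.
    """

    _kind = ""

    def __init__(self, epochs: int = 50, batch_size: int = 32,
                 learning_rate: float = 1e-3, l2: float = 1e-4,
                 val_fraction: float = 0.1, classes: tuple[str, ...] | None = None,
                 random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.val_fraction = val_fraction
        self.classes = classes
        self.random_state = random_state

    def _build_spec(self, L: int, C: int, n_classes: int) -> ArchitectureSpec:
        raise NotImplementedError

    def _to_net_input(self, X: np.ndarray) -> np.ndarray:
        return X

    def _validate_X(self, X: np.ndarray, spec: ArchitectureSpec | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_frames, L, C), got shape {X.shape}")
        if spec is not None and X.shape[1:] != spec.input_shape:
            raise ValueError(
                f"frame shape {X.shape[1:]} does not match model input {spec.input_shape}"
            )
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseStrokeClassifier":
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError(f"X has {len(X)} frames but y has {len(y)} labels")
        if len(X) == 0:
            raise ValueError("cannot train on an empty frame set")
        vocab = tuple(self.classes) if self.classes is not None else tuple(np.unique(y))
        if len(set(np.unique(y))) < 2:
            raise ValueError("training data must contain at least two classes")
        unknown = set(np.unique(y)) - set(vocab)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in class vocabulary")
        self.classes_ = np.asarray(vocab, dtype=object)

        n, L, C = X.shape
        self.spec_ = self._build_spec(L, C, len(vocab))
        rng = np.random.default_rng(self.random_state)
        self.network_ = realize(self.spec_, rng)

        class_index = {c: i for i, c in enumerate(vocab)}
        onehot = np.zeros((n, len(vocab)))
        onehot[np.arange(n), [class_index[c] for c in y]] = 1.0

        if self.val_fraction > 0 and n >= 10:
            n_val = max(1, int(round(self.val_fraction * n)))
            order = rng.permutation(n)
            val_idx, tr_idx = order[:n_val], order[n_val:]
        else:
            tr_idx = np.arange(n)
            val_idx = np.array([], dtype=int)

        self.loss_curve_ = _nn.fit_network(
            self.network_,
            self._to_net_input(X[tr_idx]),
            onehot[tr_idx],
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            rng=rng,
        )
        if val_idx.size:
            val_pred = self.predict(X[val_idx])
            self.validation_accuracy_ = float(np.mean(val_pred == y[val_idx]))
        else:
            self.validation_accuracy_ = None
        self.n_features_in_ = L * C
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted yet")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-frame class probabilities (rows sum to 1)."""
        self._check_fitted()
        X = self._validate_X(X, self.spec_)
        return self.network_.forward(self._to_net_input(X), training=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels: the class with the greatest softmax probability."""
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    # frame-set conveniences -------------------------------------------------

    def fit_frameset(self, fs: FrameSet) -> "_BaseStrokeClassifier":
        self.classes = tuple(fs.class_vocab)
        return self.fit(fs.X, fs.y)

    def score_frameset(self, fs: FrameSet) -> float:
        return float(np.mean(self.predict(fs.X) == fs.y))


class CNNClassifier(_BaseStrokeClassifier):
    """Convolutional stroke classifier (two valid 3×3 convolutions)."""

    _kind = "cnn"

    def _build_spec(self, L, C, n_classes):
        return build_cnn(L, C, n_classes, l2=self.l2)

    def _to_net_input(self, X):
        return X[..., None]  # single-plane image


class DNNClassifier(_BaseStrokeClassifier):
    """Convolution-free per-timestep dense stroke classifier."""

    _kind = "dnn"

    def _build_spec(self, L, C, n_classes):
        return build_dnn(L, C, n_classes)


#: A fitted stroke classifier; alias kept for readability in signatures.
TrainedModel = _BaseStrokeClassifier


def train(spec: ArchitectureSpec, train_fs: FrameSet, cfg: TrainConfig = TrainConfig()) -> TrainedModel:
    """Train a classifier realising ``spec`` on a labelled frame set."""
    X = train_fs.X
    if X.shape[1:] != spec.input_shape:
        raise ValueError(
            f"frame set shape {X.shape[1:]} does not match spec input {spec.input_shape}"
        )
    cls = CNNClassifier if spec.kind == "cnn" else DNNClassifier
    model = cls(
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        val_fraction=cfg.val_fraction,
        classes=tuple(train_fs.class_vocab),
        random_state=cfg.seed,
    )
    return model.fit(X, train_fs.y)


def predict_proba(model: TrainedModel, fs: FrameSet) -> np.ndarray:
    """Frame-level class probability matrix, one row per frame."""
    return model.predict_proba(fs.X)


def _net_arrays(net: _nn.Network) -> list[np.ndarray]:
    arrays: list[np.ndarray] = []
    for layer in net.layers:
        arrays.extend(layer.params)
        if isinstance(layer, _nn.BatchNorm):
            arrays.extend([layer.running_mean, layer.running_var])
    return arrays


def save_model(path: str | Path, model: TrainedModel) -> None:
    """Persist a fitted model: .npz weights plus a JSON spec sidecar."""
    model._check_fitted()
    path = Path(path)
    arrays = _net_arrays(model.network_)
    np.savez(Path(str(path) + ".npz"), **{f"arr_{i}": a for i, a in enumerate(arrays)})
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.spec_.kind,
        "input_shape": list(model.spec_.input_shape),
        "n_classes": model.spec_.n_classes,
        "classes": list(model.classes_),
        "params": model.get_params(),
        "loss_curve": list(model.loss_curve_),
    }
    meta["params"]["classes"] = list(meta["params"]["classes"] or [])
    Path(str(path) + ".json").write_text(json.dumps(meta))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    if meta["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {meta['format_version']}")
    params = dict(meta["params"])
    params["classes"] = tuple(params["classes"]) or None
    cls = CNNClassifier if meta["kind"] == "cnn" else DNNClassifier
    model = cls(**params)
    L, C = meta["input_shape"]
    model.classes_ = np.asarray(meta["classes"], dtype=object)
    model.spec_ = model._build_spec(L, C, meta["n_classes"])
    model.network_ = realize(model.spec_, np.random.default_rng(0))
    with np.load(Path(str(path) + ".npz")) as data:
        for i, arr in enumerate(_net_arrays(model.network_)):
            arr[...] = data[f"arr_{i}"]
    model.loss_curve_ = list(meta["loss_curve"])
    model.validation_accuracy_ = None
    model.n_features_in_ = L * C
    return model
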