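"""Training loop, prediction, and per-event aggregation for the waveform CNN.

Optimization is mini-batch stochastic gradient descent with momentum and L2
weight decay, the step-decay learning-rate schedule (multiply by
``lr_drop_factor`` every ``lr_drop_period`` epochs), Gaussian or
fan-in-scaled weight initialization, and constant positive bias
initialization. Class convention: index 0 = nonUC, index 1 = UC (the
positive class throughout the package).

Because one contraction event yields 16 single-channel images (one per
electrode), event-level decisions are obtained by aggregating the 16
per-channel probability vectors with :func:`aggregate_segment_prediction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arch import CNNArchitecture, ConvSpec, FCSpec, PoolSpec, TrainConfig
from .layers import (
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    LRNLayer,
    MaxPool2D,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "TrainedModel",
    "build_network",
    "train",
    "predict",
    "aggregate_segment_prediction",
    "CLASS_NAMES",
]

CLASS_NAMES = ("nonUC", "UC")  # probability vector order


def _as_array(images) -> np.ndarray:
    """Accept SegmentImage lists or arrays; return (N, 1, H, W) float32."""
    if isinstance(images, np.ndarray):
        arr = images
    else:
        arr = np.stack([getattr(im, "pixels", im) for im in images])
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[:, None]
    return arr


def _as_targets(labels) -> np.ndarray:
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            out[i] = 1 if lab == "UC" else 0
        else:
            out[i] = int(lab)
    return out


def build_network(
    architecture: CNNArchitecture, config: TrainConfig, rng: np.random.Generator
) -> list[Layer]:
    layers: list[Layer] = []
    channels = 1
    spatial_done = False
    for spec in architecture.layers:
        if isinstance(spec, ConvSpec):
            layers.append(Conv2D(channels, spec, rng, config.weight_init_std, config.bias_init))
            if spec.lrn:
                layers.append(LRNLayer(spec))
            layers.append(ReLU())
            channels = spec.num_output
        elif isinstance(spec, PoolSpec):
            layers.append(MaxPool2D(spec))
        elif isinstance(spec, FCSpec):
            if not spatial_done:
                layers.append(Flatten())
                in_features = architecture.flattened_size()
                spatial_done = True
            layers.append(Dense(in_features, spec, rng, config.weight_init_std, config.bias_init))
            if spec.relu:
                layers.append(ReLU())
            if spec.dropout_ratio > 0:
                ratio = (
                    config.dropout_ratio
                    if config.dropout_ratio is not None
                    else spec.dropout_ratio
                )
                layers.append(Dropout(ratio, rng))
            in_features = spec.num_output
    return layers


@dataclass
class TrainedModel:
    """A trained network plus its architecture, config, and training log."""

    architecture: CNNArchitecture
    config: TrainConfig
    layers: list[Layer]
    log: dict = field(default_factory=dict)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, images, batch_size: int = 64) -> np.ndarray:
        x = _as_array(images)
        expected = self.architecture.input_size
        if x.shape[2] != expected or x.shape[3] != expected:
            raise ValueError(
                f"image size {x.shape[2]}x{x.shape[3]} does not match model input "
                f"{expected}x{expected}"
            )
        probs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            probs.append(softmax(logits.astype(np.float64)))
        return np.concatenate(probs, axis=0)


def _param_layers(layers: list[Layer]) -> list[Layer]:
    return [l for l in layers if l.params]


def train(
    images,
    labels,
    config: TrainConfig,
    architecture: CNNArchitecture,
    split: np.ndarray | None = None,
) -> TrainedModel:
    """Train the network; returns the model with its per-iteration loss log.

    ``split`` is an optional boolean mask (True = training example, False =
    validation); when omitted a seeded 80/20 split is drawn. Training runs
    until ``config.epochs`` (if set) or ``config.max_iterations``
    mini-batches, whichever is reached first.
    """
    x = _as_array(images)
    y = _as_targets(labels)
    if x.shape[0] == 0:
        raise ValueError("no training images given")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    if split is None:
        order = rng.permutation(x.shape[0])
        n_val = max(1, int(round(0.2 * x.shape[0])))
        val_idx = order[:n_val]
        train_idx = order[n_val:]
    else:
        split = np.asarray(split, dtype=bool)
        train_idx = np.flatnonzero(split)
        val_idx = np.flatnonzero(~split)
    if np.unique(y[train_idx]).size < 2:
        raise ValueError("training split must contain both classes")

    layers = build_network(architecture, config, rng)
    model = TrainedModel(architecture=architecture, config=config, layers=layers)
    velocities = {
        id(l): [np.zeros_like(p) for p, _ in l.params] for l in _param_layers(layers)
    }

    n_train = train_idx.size
    batch = min(config.batch_size, n_train)
    iters_per_epoch = max(1, n_train // batch)
    if config.epochs is not None:
        max_epochs = config.epochs
    else:
        max_epochs = max(1, -(-config.max_iterations // iters_per_epoch))

    loss_log: list[float] = []
    val_log: list[float] = []
    iteration = 0
    for epoch in range(max_epochs):
        lr = config.learning_rate * config.lr_drop_factor ** (
            epoch // config.lr_drop_period
        )
        perm = rng.permutation(n_train)
        for b in range(iters_per_epoch):
            if iteration >= config.max_iterations:
                break
            idx = train_idx[perm[b * batch : (b + 1) * batch]]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            loss_log.append(loss)
            grad = dlogits
            for layer in reversed(layers):
                grad = layer.backward(grad)
            for layer in _param_layers(layers):
                for (p, g), v in zip(layer.params, velocities[id(layer)]):
                    v *= config.momentum
                    v -= lr * (g + config.weight_decay * p)
                    p += v
            iteration += 1
        if val_idx.size:
            probs = model.predict_proba(x[val_idx], batch_size=max(batch, 16))
            val_log.append(float((probs.argmax(axis=1) == y[val_idx]).mean()))
        if iteration >= config.max_iterations:
            break

    model.log = {
        "loss": loss_log,
        "val_accuracy": val_log,
        "iterations": iteration,
        "epochs_run": epoch + 1,
        "n_train": int(n_train),
        "n_val": int(val_idx.size),
        "parameter_count": architecture.parameter_count(),
    }
    return model


def predict(model: TrainedModel, images, batch_size: int = 64) -> np.ndarray:
    """Per-image class probabilities, shape (N, 2), rows sum to 1."""
    return model.predict_proba(images, batch_size=batch_size)


def aggregate_segment_prediction(
    per_channel_probs: np.ndarray, rule: str = "mean"
) -> str:
    """Combine per-channel probability vectors into one event-level class.

    ``mean`` averages probabilities then takes the argmax; ``majority``
    takes the modal per-channel argmax, breaking ties toward nonUC
    (conservative).
    """
    probs = np.asarray(per_channel_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] < 1 or probs.shape[1] != 2:
        raise ValueError("expected an (n_channels, 2) probability array")
    if rule == "mean":
        return CLASS_NAMES[int(probs.mean(axis=0).argmax())]
    if rule == "majority":
        votes = probs.argmax(axis=1)
        n_uc = int((votes == 1).sum())
        n_non = votes.size - n_uc
        return "UC" if n_uc > n_non else "nonUC"
    raise ValueError(f"unknown aggregation rule {rule!r}")
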