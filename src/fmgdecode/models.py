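"""Dual-output model zoo: CNN with/without movement-image augmentation, GRU.

All three architectures share a trunk -> two-parallel-heads structure (K-way
softmax gesture classifier and single-unit linear angle regressor) trained
jointly by minimizing w_c * cross-entropy + w_r * MSE with RMSprop. Default
hyperparameters follow the reference setup: 32 conv filters of 3x3 with 2x2
max pooling (two blocks), a 32-unit dense layer, weight ratio w_r:w_c = 4:1,
batch size 32, 10 epochs; the GRU variant uses one 32-unit layer over
10-step windows of the raw 10-channel signal with input and recurrent
dropout of 0.2 each.

Note on the flatten width: with same padding, the 42x42 augmented input
flattens to 10*10*32 = 3200 features after the two conv/pool blocks, while
the 10x10 non-augmented input flattens to 2*2*32 = 128. The true per-
architecture size is always reported via ``flatten_dim``; no architecture is
forced to a particular width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import nn
from .augment import ImageDataset

__all__ = [
    "DualModelConfig",
    "TrainedModel",
    "DivergenceError",
    "build_model",
    "flatten_dim",
    "layer_output_shapes",
    "train",
    "predict",
    "save_model",
    "load_model",
]

ARCHITECTURES = ("cnn_aug", "cnn_noaug", "gru")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class DualModelConfig:
    """Architecture and training hyperparameters for a dual-output model."""

    architecture: str = "cnn_aug"
    input_side: int = 42  # image side for CNNs; timestep count for the GRU
    n_input_channels: int = 10  # feature count per GRU timestep
    conv_filters: int = 32
    kernel: int = 3
    dense_units: int = 32
    n_classes: int = 5
    w_c: float = 1.0
    w_r: float = 4.0
    optimizer: str = "rmsprop"
    #: chosen so the joint loss converges within the fixed 10-epoch budget
    learning_rate: float = 2e-3
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-7
    batch_size: int = 32
    epochs: int = 10
    gru_units: int = 32
    gru_dropout: float = 0.2
    gru_recurrent_dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.w_c < 0 or self.w_r < 0 or (self.w_c == 0 and self.w_r == 0):
            raise ValueError("loss weights must be non-negative and not both zero")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is supported")

    @classmethod
    def for_architecture(cls, architecture: str, **kwargs) -> "DualModelConfig":
        """Config with the conventional input size for each architecture:
        42 (augmented image side), 10 (raw window side), 10 (GRU timesteps)."""
        side = {"cnn_aug": 42, "cnn_noaug": 10, "gru": 10}[architecture]
        kwargs.setdefault("input_side", side)
        return cls(architecture=architecture, **kwargs)


def flatten_dim(side: int, filters: int) -> int:
    """Flatten width after two same-padding conv + 2x2 floor-pool blocks."""
    s = side // 2 if side >= 2 else side
    s = s // 2 if s >= 2 else s
    return s * s * filters


def build_model(config: DualModelConfig) -> nn.DualHeadNet:
    """Instantiate an untrained dual-output network per the config.

    cnn_aug / cnn_noaug: [conv 3x3 x filters, pool 2x2] x 2 -> flatten ->
    dense(32, rectifier) -> two heads. gru: one GRU layer (32 units, input
    and recurrent dropout 0.2) -> dense(32, rectifier) -> two heads.
    """
    rng = np.random.default_rng(config.seed)
    if config.architecture in ("cnn_aug", "cnn_noaug"):
        f = config.conv_filters
        trunk = [
            nn.Conv2D(1, f, rng, k=config.kernel, input_grad=False),
            nn.MaxPool2(),
            nn.Conv2D(f, f, rng, k=config.kernel),
            nn.MaxPool2(),
            nn.Flatten(),
            nn.Dense(flatten_dim(config.input_side, f), config.dense_units, rng, relu=True),
        ]
    else:
        trunk = [
            nn.GRU(
                config.n_input_channels,
                config.gru_units,
                rng,
                dropout=config.gru_dropout,
                recurrent_dropout=config.gru_recurrent_dropout,
            ),
            nn.Dense(config.gru_units, config.dense_units, rng, relu=True),
        ]
    net = nn.DualHeadNet(trunk, config.dense_units, config.n_classes, rng)
    net._train_rng = rng  # shared generator: init, shuffling and dropout
    return net


def layer_output_shapes(net: nn.DualHeadNet, config: DualModelConfig) -> list[tuple]:
    """Per-layer output shapes (batch axis omitted) for a dry forward pass,
    ending with the two head shapes (K-way probabilities, 1 angle)."""
    if config.architecture == "gru":
        x = np.zeros((1, config.input_side, config.n_input_channels), dtype=np.float32)
    else:
        x = np.zeros((1, config.input_side, config.input_side, 1), dtype=np.float32)
    shapes = []
    h = x
    for layer in net.trunk:
        h = layer.forward(h, train=False)
        shapes.append((type(layer).__name__, h.shape[1:]))
    shapes.append(("Dense[gesture]", (config.n_classes,)))
    shapes.append(("Dense[angle]", (1,)))
    return shapes


@dataclass
class TrainedModel:
    """A fitted dual-output predictor plus its per-epoch loss history
    (columns: epoch, total, ce, mse)."""

    net: nn.DualHeadNet
    config: DualModelConfig
    history: pd.DataFrame


def _as_model_input(images: np.ndarray, config: DualModelConfig) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"expected [n x w x M] windows, got shape {x.shape}")
    if config.architecture == "gru":
        if x.shape[1] != config.input_side or x.shape[2] != config.n_input_channels:
            raise ValueError(
                f"GRU expects [n x {config.input_side} x {config.n_input_channels}], "
                f"got {x.shape}"
            )
        return x
    side = config.input_side
    if x.shape[1] != side or x.shape[2] != side:
        raise ValueError(f"{config.architecture} expects [n x {side} x {side}], got {x.shape}")
    return x[..., None]  # channels-last single-channel image


def train(
    net: nn.DualHeadNet, dataset: ImageDataset, config: DualModelConfig
) -> TrainedModel:
    """Fit a dual-output model on an image dataset.

    Minimizes w_c * cross-entropy + w_r * MSE with RMSprop over seeded
    shuffled minibatches for a fixed number of epochs (no validation split or
    early stopping). Reported per-epoch losses are the means over that
    epoch's minibatches.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    labels = np.asarray(dataset.labels, dtype=int)
    if labels.min() < 0 or labels.max() >= config.n_classes:
        raise ValueError("labels out of range for the configured class count")
    x = _as_model_input(dataset.images, config)
    angles = np.asarray(dataset.angles, dtype=np.float32)
    rng = getattr(net, "_train_rng", None) or np.random.default_rng(config.seed)
    opt = nn.RMSprop(
        net.params, lr=config.learning_rate, rho=config.rmsprop_rho,
        eps=config.rmsprop_eps,
    )
    n = x.shape[0]
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        tot = ce = mse = 0.0
        n_batches = 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            bt, bc, bm = net.loss_and_grads(
                x[idx], labels[idx], angles[idx], config.w_c, config.w_r
            )
            if not np.isfinite(bt):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: lower the learning rate "
                    "or check the input standardization"
                )
            opt.step(net.grads)
            tot += bt
            ce += bc
            mse += bm
            n_batches += 1
        rows.append(
            {"epoch": epoch, "total": tot / n_batches, "ce": ce / n_batches,
             "mse": mse / n_batches}
        )
    return TrainedModel(net=net, config=config, history=pd.DataFrame(rows))


def predict(
    trained: TrainedModel, images: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(class probabilities [n x K], argmax labels [n], angles [n]).

    Angles are on the standardized scale used in training; probability ties
    resolve to the lowest class index (argmax convention).
    """
    x = _as_model_input(images, trained.config)
    probs, angles = trained.net.predict(x)
    return probs, probs.argmax(axis=1), angles


def save_model(trained: TrainedModel, path) -> None:
    """Checkpoint: config as JSON plus flat parameter arrays, in one .npz."""
    arrays = {f"param_{i}": p for i, p in enumerate(trained.net.get_weights())}
    np.savez_compressed(
        path,
        config_json=np.frombuffer(
            json.dumps(asdict(trained.config)).encode(), dtype=np.uint8
        ),
        history=trained.history.to_numpy(),
        **arrays,
    )


def load_model(path) -> TrainedModel:
    """Restore a checkpoint written by :func:`save_model`."""
    with np.load(path) as z:
        config = DualModelConfig(**json.loads(bytes(z["config_json"]).decode()))
        net = build_model(config)
        weights = [z[f"param_{i}"] for i in range(len(net.params))]
        net.set_weights(weights)
        history = pd.DataFrame(z["history"], columns=["epoch", "total", "ce", "mse"])
    return TrainedModel(net=net, config=config, history=history)
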