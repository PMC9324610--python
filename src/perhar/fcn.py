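"""The 1D fully-convolutional embedding/classification core.

Architecture: three blocks of ``conv1d -> batch norm -> ReLU -> dropout``
(unit strides, 'same' padding), global average pooling over time, an
optional dense projection to the embedding dimension (inserted only when it
differs from the last filter count), and row-wise L2 normalization so every
embedding lies on the unit hypersphere. A classifier head is a dense layer
with softmax on top of the normalized embedding.

With the default kernels (7, 5, 3) the receptive field of units in the last
convolutional layer is 13 samples — 260 ms at a 50 Hz sampling rate — so a
single pooled feature sees roughly a quarter second of motion.

Training uses Adam with global gradient-norm clipping (default 1.0). All
randomness (initialization, shuffling, dropout) derives from the config
seed, so identical config + data reproduce identical parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._nn import (
    Adam,
    BatchNorm1d,
    Conv1dSame,
    Dense,
    Dropout,
    GlobalAvgPool,
    L2Normalize,
    ReLU,
    clip_global_norm,
    cross_entropy_with_grad,
    softmax,
)


@dataclass
class FCNConfig:
    """Hyperparameters of the FCN core.

    Defaults follow the reference training schedule: Adam at learning rate
    0.001 for cross-entropy training (reduce to 0.0002 for triplet training),
    150 epochs, gradient-norm clipping at 1.0, margin-agnostic batch size 64.
    """

    n_channels: int = 6
    conv_filters: tuple[int, int, int] = (128, 256, 128)
    kernel_sizes: tuple[int, int, int] = (7, 5, 3)
    dropout_rate: float = 0.2
    embedding_dim: int = 64
    n_classes: int | None = None
    learning_rate: float = 0.001
    epochs: int = 150
    gradient_clip_norm: float = 1.0
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3 or len(self.kernel_sizes) != 3:
            raise ValueError("expected exactly three convolutional layers")
        if any(f <= 0 for f in self.conv_filters) or any(k <= 0 for k in self.kernel_sizes):
            raise ValueError("filter counts and kernel sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if self.n_classes is not None and self.n_classes < 2:
            raise ValueError("a classifier head needs at least 2 classes")


def receptive_field(config: FCNConfig) -> int:
    """Receptive field, in input samples, of the last convolutional layer.

    With unit strides and no dilation this is ``1 + sum(kernel_i - 1)``.
    """
    return 1 + sum(k - 1 for k in config.kernel_sizes)


@dataclass
class EmbeddingMatrix:
    """n x d matrix of embeddings with per-row provenance."""

    rows: np.ndarray
    row_ids: list
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def dim(self) -> int:
        return self.rows.shape[1]


class FCNModel:
    """Trained (or freshly initialized) FCN core, optionally with a head."""

    def __init__(self, config: FCNConfig, with_classifier_head: bool):
        self.config = config
        init_rng = np.random.default_rng(config.seed)
        f = config.conv_filters
        k = config.kernel_sizes
        chans = [config.n_channels, *f]
        self.blocks: list = []
        for i in range(3):
            self.blocks.append(Conv1dSame(chans[i], chans[i + 1], k[i], init_rng))
            self.blocks.append(BatchNorm1d(chans[i + 1]))
            self.blocks.append(ReLU())
            self.blocks.append(Dropout(config.dropout_rate))
        self.gap = GlobalAvgPool()
        self.proj = Dense(f[2], config.embedding_dim, init_rng) if config.embedding_dim != f[2] else None
        self.l2 = L2Normalize()
        self.head = None
        if with_classifier_head:
            if config.n_classes is None:
                raise ValueError("classifier head requires n_classes in the config")
            self.head = Dense(config.embedding_dim, config.n_classes, init_rng)
        self.class_order: np.ndarray | None = None
        self.history: list[dict] = []

    # ---- plumbing -------------------------------------------------------

    def _layers(self) -> list:
        layers = list(self.blocks) + [self.gap]
        if self.proj is not None:
            layers.append(self.proj)
        layers.append(self.l2)
        if self.head is not None:
            layers.append(self.head)
        return layers

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params.values()]

    def gradients(self) -> list[np.ndarray]:
        return [layer.grads[name] for layer in self._layers() for name in layer.params]

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def _set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.blocks:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.n_channels:
            raise ValueError(
                f"expected {self.config.n_channels} channels, got {x.shape[1]}"
            )
        if x.shape[2] < receptive_field(self.config):
            raise ValueError(
                f"input length {x.shape[2]} below receptive field {receptive_field(self.config)}"
            )
        return x

    # ---- forward / backward --------------------------------------------

    def _forward_embedding(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        for layer in self.blocks:
            h = layer.forward(h, train)
        h = self.gap.forward(h, train)
        if self.proj is not None:
            h = self.proj.forward(h, train)
        return self.l2.forward(h, train)

    def _forward_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.head is None:
            raise ValueError("model has no classifier head")
        return self.head.forward(self._forward_embedding(x, train), train)

    def _backward_from_embedding(self, demb: np.ndarray) -> None:
        d = self.l2.backward(demb)
        if self.proj is not None:
            d = self.proj.backward(d)
        d = self.gap.backward(d)
        for layer in reversed(self.blocks):
            d = layer.backward(d)

    def _backward_from_logits(self, dlogits: np.ndarray) -> None:
        self._backward_from_embedding(self.head.backward(dlogits))

    # ---- serialization ---------------------------------------------------

    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._layers()):
            for name, p in layer.params.items():
                arrays[f"p_{i}_{name}"] = p
            if isinstance(layer, BatchNorm1d):
                arrays[f"rm_{i}"] = layer.running_mean
                arrays[f"rv_{i}"] = layer.running_var
        meta = {
            "format_version": 1,
            "config": asdict(self.config),
            "has_head": self.head is not None,
            "class_order": None if self.class_order is None else self.class_order.tolist(),
        }
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "FCNModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
            cfg_dict = meta["config"]
            cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
            cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
            config = FCNConfig(**cfg_dict)
            model = cls(config, with_classifier_head=meta["has_head"])
            for i, layer in enumerate(model._layers()):
                for name in layer.params:
                    layer.params[name][...] = data[f"p_{i}_{name}"]
                if isinstance(layer, BatchNorm1d):
                    layer.running_mean[...] = data[f"rm_{i}"]
                    layer.running_var[...] = data[f"rv_{i}"]
            if meta["class_order"] is not None:
                model.class_order = np.asarray(meta["class_order"])
        return model


def build_fcn(config: FCNConfig, with_classifier_head: bool = True) -> FCNModel:
    """Freshly initialized FCN core (seeded by ``config.seed``)."""
    return FCNModel(config, with_classifier_head=with_classifier_head)


def train_classifier(model: FCNModel, segments, epochs: int | None = None) -> FCNModel:
    """Train the classifier head + core with categorical cross-entropy.

    Adam at ``config.learning_rate`` with global gradient-norm clipping at
    ``config.gradient_clip_norm``. Appends one history record per epoch with
    the mean batch loss and the largest post-clip gradient norm. Training is
    in place; the model is also returned for chaining.
    """
    if model.head is None:
        raise ValueError("train_classifier requires a model with a classifier head")
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    x = model._check_input(segments.windows)
    labels = segments.labels
    class_order = np.unique(labels)
    if class_order.shape[0] < 2:
        raise ValueError("training set must contain at least 2 classes")
    if class_order.shape[0] != cfg.n_classes:
        raise ValueError(
            f"config declares {cfg.n_classes} classes but data has {class_order.shape[0]}"
        )
    model.class_order = class_order
    targets = np.searchsorted(class_order, labels)

    rng = np.random.default_rng(cfg.seed + 1)
    model._set_dropout_rng(rng)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = x.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, norms = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model._forward_logits(x[idx], train=True)
            loss, dlogits = cross_entropy_with_grad(logits, targets[idx])
            model._backward_from_logits(dlogits)
            grads = model.gradients()
            norms.append(clip_global_norm(grads, cfg.gradient_clip_norm))
            opt.step(grads)
            losses.append(loss)
        model.history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "max_post_clip_grad_norm": float(np.max(norms)),
                "objective": "cross_entropy",
            }
        )
    return model


def predict_softmax(model: FCNModel, segments) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) for a segment set."""
    if model.head is None:
        raise ValueError("predict_softmax requires a model with a classifier head")
    x = model._check_input(segments.windows)
    probs = []
    for start in range(0, x.shape[0], model.config.batch_size):
        logits = model._forward_logits(x[start : start + model.config.batch_size], train=False)
        probs.append(softmax(logits))
    return np.concatenate(probs, axis=0)


def predict_labels(model: FCNModel, segments) -> np.ndarray:
    """Argmax class identifiers (in the training label alphabet)."""
    if model.class_order is None:
        raise ValueError("model has not been trained; no class order available")
    return model.class_order[predict_softmax(model, segments).argmax(axis=1)]


def embed(model: FCNModel, segments) -> EmbeddingMatrix:
    """Unit-norm embeddings for a segment set (head presence irrelevant)."""
    x = model._check_input(segments.windows)
    rows = []
    for start in range(0, x.shape[0], model.config.batch_size):
        rows.append(model._forward_embedding(x[start : start + model.config.batch_size], train=False))
    return EmbeddingMatrix(
        rows=np.concatenate(rows, axis=0),
        row_ids=[f"{s.source_id}:{s.interval[0]}" for s in segments],
        labels=segments.labels,
        subject_ids=segments.subject_ids,
    )
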