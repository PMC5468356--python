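"""The patch classifier: five conv blocks, a decision-forest layer, and a
fully connected head.

Full-scale architecture (71x71x3 input; spatial side after each layer in
parentheses):

    conv 90@2x2 (70) - pool 2x2 (35) - conv 180@4x4 (32) - pool (16)
    - conv 360@3x3 (14) - pool (7) - conv 720@2x2 (6) - pool (3)
    - conv 1440@2x2 (2) - decision layer (45 trees, depth 4 -> 720)
    - fc 100 - dropout 0.5 - fc 2

ReLU follows every convolution and FC-1. Convolutions are valid, stride
1; pooling is non-overlapping with floor division on odd sides. The
decision layer runs in embedding mode: its 720 leaf-reach probabilities
are the features the FC head classifies.

A reduced ``small()`` configuration with the same topology but fewer
maps per layer is provided for CPU-scale training runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest import DecisionLayer, ForestState
from .layers import Conv2D, Dense, Dropout, Flatten, Layer, MaxPool2D, ReLU, softmax


@dataclass
class LayerSpec:
    """One structural layer of the classifier."""

    kind: str  # conv | maxpool | relu | decision | fc | dropout
    maps: int | None = None  # conv output channels / fc width
    filter: int | None = None  # conv kernel or pool window side
    stride: int | None = None
    n_trees: int | None = None
    depth: int | None = None
    ratio: float | None = None  # dropout


@dataclass
class NetworkConfig:
    """Ordered layer stack plus global settings."""

    layers: list = field(default_factory=list)
    dropout_ratio: float = 0.5
    n_classes: int = 2
    input_shape: tuple = (3, 71, 71)

    def __post_init__(self):
        if not 0.0 <= self.dropout_ratio < 1.0:
            raise ValueError("dropout_ratio must be in [0, 1)")
        if self.layers:
            fcs = [s for s in self.layers if s.kind == "fc"]
            if fcs and fcs[-1].maps != self.n_classes:
                raise ValueError("final fc width must equal n_classes")

    @staticmethod
    def _stack(conv_maps, conv_kernels, n_trees, depth, fc_width, n_classes, dropout):
        layers = []
        for i, (m, k) in enumerate(zip(conv_maps, conv_kernels)):
            layers.append(LayerSpec("conv", maps=m, filter=k))
            layers.append(LayerSpec("relu"))
            if i < len(conv_maps) - 1:
                layers.append(LayerSpec("maxpool", filter=2))
        layers += [
            LayerSpec("decision", n_trees=n_trees, depth=depth),
            LayerSpec("fc", maps=fc_width),
            LayerSpec("relu"),
            LayerSpec("dropout", ratio=dropout),
            LayerSpec("fc", maps=n_classes),
        ]
        return layers

    @classmethod
    def full(cls) -> "NetworkConfig":
        """The full-scale published architecture (decision width 720)."""
        cfg = cls(dropout_ratio=0.5, n_classes=2)
        cfg.layers = cls._stack(
            conv_maps=(90, 180, 360, 720, 1440),
            conv_kernels=(2, 4, 3, 2, 2),
            n_trees=45, depth=4, fc_width=100, n_classes=2, dropout=0.5,
        )
        return cfg

    @classmethod
    def small(cls, dropout: float = 0.25) -> "NetworkConfig":
        """Same topology at CPU-training scale: fewer maps, a smaller
        forest (8 trees of depth 3 -> 64-wide embedding)."""
        cfg = cls(dropout_ratio=dropout, n_classes=2)
        cfg.layers = cls._stack(
            conv_maps=(8, 16, 32, 64, 128),
            conv_kernels=(2, 4, 3, 2, 2),
            n_trees=8, depth=3, fc_width=32, n_classes=2, dropout=dropout,
        )
        return cfg


class Network:
    """An assembled classifier: ordered layers with shared RNG streams."""

    def __init__(self, config: NetworkConfig, rng_seed: int = 0):
        self.config = config
        init_rng = np.random.default_rng(rng_seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(rng_seed).spawn(1)[0]
        )
        self.layers: list[Layer] = []
        self.forest: ForestState | None = None
        shape = config.input_shape  # (C, H, W)
        flat = None
        for i, spec in enumerate(config.layers):
            if spec.kind == "conv":
                c, h, w = shape
                layer = Conv2D(c, spec.maps, spec.filter, init_rng, name=f"conv-{i}")
                shape = (spec.maps, h - spec.filter + 1, w - spec.filter + 1)
                if shape[1] < 1 or shape[2] < 1:
                    raise ValueError(f"conv-{i}: filter larger than its input")
            elif spec.kind == "maxpool":
                c, h, w = shape
                s = spec.stride or spec.filter
                layer = MaxPool2D(spec.filter, s, name=f"maxpool-{i}")
                shape = (c, (h - spec.filter) // s + 1, (w - spec.filter) // s + 1)
            elif spec.kind == "relu":
                layer = ReLU()
            elif spec.kind == "decision":
                in_dim = int(np.prod(shape)) if flat is None else flat
                self.forest = ForestState.init_random(
                    spec.n_trees, spec.depth, in_dim, init_rng,
                    n_classes=config.n_classes,
                )
                layer = DecisionLayer(self.forest, name=f"decision-{i}")
                flat = self.forest.embedding_width
                shape = None
            elif spec.kind == "fc":
                if flat is None:
                    self.layers.append(Flatten())
                    flat = int(np.prod(shape))
                    shape = None
                layer = Dense(flat, spec.maps, init_rng, name=f"fc-{i}")
                flat = spec.maps
            elif spec.kind == "dropout":
                layer = Dropout(
                    spec.ratio if spec.ratio is not None else config.dropout_ratio,
                    self.dropout_rng, name=f"dropout-{i}",
                )
            else:
                raise ValueError(f"unknown layer kind {spec.kind!r}")
            self.layers.append(layer)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class scores (B, n_classes) for a patch batch (B, 3, H, W)."""
        out = np.asarray(x, dtype=np.float64)
        if out.ndim == 3:
            out = out[None]
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p

    def shape_chain(self, x: np.ndarray | None = None):
        """Spatial side (or vector width) after every layer, for a single
        input; used to check architecture conformance."""
        if x is None:
            C, H, W = self.config.input_shape
            x = np.zeros((1, C, H, W))
        sides = []
        out = np.asarray(x, dtype=np.float64)
        if out.ndim == 3:
            out = out[None]
        for layer in self.layers:
            out = layer.forward(out, train=False)
            sides.append(out.shape[2] if out.ndim == 4 else out.shape[1])
        return sides


def network_forward(
    patch: np.ndarray, network: Network, train_mode: bool = False
) -> np.ndarray:
    """Scores for one patch given as (H, W, 3) uint8 or (3, H, W) float."""
    x = np.asarray(patch, dtype=np.float64)
    if x.ndim == 3 and x.shape[2] == 3:
        x = x.transpose(2, 0, 1) / 255.0
    return network.forward(x[None], train=train_mode)[0]


def save_model(network: Network, path, extra: dict | None = None) -> None:
    """Persist a trained network: a self-describing pickle holding the
    format version, the architecture config and all parameter arrays."""
    import pickle

    payload = {
        "format": 1,
        "config": network.config,
        "params": [
            {name: p.copy() for name, p in layer.params.items()}
            for layer in network.layers
        ],
        "extra": extra or {},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> Network:
    """Rebuild a network saved by :func:`save_model`."""
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != 1:
        raise ValueError(f"{path}: unsupported model format {payload.get('format')!r}")
    net = Network(payload["config"])
    for layer, params in zip(net.layers, payload["params"]):
        for name, value in params.items():
            layer.params[name][...] = value
    return net


def predict_posteriors(network: Network, X: np.ndarray, batch_size: int = 64):
    """Softmax posteriors and argmax labels for a patch array (N,3,H,W)."""
    if len(X) == 0:
        return np.zeros((0, network.config.n_classes)), np.zeros(0, dtype=np.int64)
    probs = []
    for i in range(0, len(X), batch_size):
        probs.append(softmax(network.forward(X[i : i + batch_size], train=False)))
    probs = np.concatenate(probs)
    return probs, probs.argmax(axis=1)
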