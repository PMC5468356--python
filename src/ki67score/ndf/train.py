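"""Mini-batch SGD training of the patch classifier.

Plain stochastic gradient descent with momentum and L2 weight decay,
minimizing softmax cross-entropy. Published operating point: learning
rate 0.01, momentum 0.85, weight decay 0.005, batch 128; every value is
overridable, and CPU-scale runs use far fewer iterations than the
published 450,000 (see the methods note for the reduced profiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .layers import softmax_cross_entropy
from .network import Network, NetworkConfig, predict_posteriors

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.85
    weight_decay: float = 0.005
    batch_size: int = 128
    max_iter: int = 450_000
    test_interval: int = 5000
    loss: str = "cross_entropy"
    rng_seed: int = 0
    #: Global gradient-norm cap. Confident networks occasionally meet a
    #: hard patch whose cross-entropy gradient spikes and kills the ReLU
    #: stack; clipping bounds the update without changing its direction.
    grad_clip: float | None = 5.0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")

    @classmethod
    def desk_scale(cls, max_iter: int = 400, batch_size: int = 32, **kw) -> "TrainConfig":
        """Reduced schedule for single-CPU runs on synthetic data."""
        kw.setdefault("test_interval", 100)
        return cls(max_iter=max_iter, batch_size=batch_size, **kw)


@dataclass
class TrainHistory:
    """Loss per iteration and periodic validation accuracy."""

    loss: list = field(default_factory=list)
    val_iter: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss[-1] if self.loss else float("nan")


class SGD:
    """Momentum SGD with decoupled-from-nothing classic L2 decay:
    v <- m v - lr (g + wd p); p <- p + v. Biases are not decayed."""

    def __init__(self, network: Network, config: TrainConfig):
        self.net = network
        self.cfg = config
        self.velocity = {
            (id(layer), name): np.zeros_like(p)
            for layer, name, p in network.parameters()
        }

    def step(self):
        c = self.cfg
        scale = 1.0
        if c.grad_clip is not None:
            sq = sum(
                float(np.sum(layer.grads[name] ** 2))
                for layer, name, _ in self.net.parameters()
            )
            norm = np.sqrt(sq)
            if norm > c.grad_clip:
                scale = c.grad_clip / norm
        for layer, name, p in self.net.parameters():
            g = layer.grads[name] * scale
            if name != "b" and c.weight_decay:
                g = g + c.weight_decay * p
            v = self.velocity[(id(layer), name)]
            v *= c.momentum
            v -= c.learning_rate * g
            p += v


def train(
    X: np.ndarray,
    y: np.ndarray,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    network: Network | None = None,
) -> tuple[Network, TrainHistory]:
    """Train a classifier on patch arrays.

    Parameters
    ----------
    X, y : (N, 3, H, W) float in [0, 1] and (N,) integer labels.
    net_config, train_config : architecture and optimization settings.
    X_val, y_val : optional held-out set scored every ``test_interval``.
    network : pre-built network to continue training (overrides net_config).

    Returns the trained network and the loss / validation history.
    Reproducible: the same configs and seed give identical results.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    train_config = train_config or TrainConfig.desk_scale()
    net = network or Network(net_config or NetworkConfig.small(), rng_seed=train_config.rng_seed)
    opt = SGD(net, train_config)
    batch_rng = np.random.default_rng(
        np.random.SeedSequence([train_config.rng_seed, 0x5EED]).generate_state(1)[0]
    )
    hist = TrainHistory()
    n = len(X)
    for it in range(train_config.max_iter):
        idx = batch_rng.choice(n, size=min(train_config.batch_size, n), replace=False)
        scores = net.forward(X[idx], train=True)
        loss, dscores = softmax_cross_entropy(scores, y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: non-finite loss at iteration {it}")
        hist.loss.append(loss)
        net.backward(dscores)
        opt.step()
        if X_val is not None and len(X_val) and (it + 1) % train_config.test_interval == 0:
            _, pred = predict_posteriors(net, X_val)
            acc = float((pred == y_val).mean())
            hist.val_iter.append(it + 1)
            hist.val_accuracy.append(acc)
            log.info("iter %d: loss %.4f val acc %.4f", it + 1, loss, acc)
    if X_val is not None and len(X_val) and (
        not hist.val_iter or hist.val_iter[-1] != train_config.max_iter
    ):
        _, pred = predict_posteriors(net, X_val)
        hist.val_iter.append(train_config.max_iter)
        hist.val_accuracy.append(float((pred == y_val).mean()))
    return net, hist


def classify_patches(patches: np.ndarray, network: Network, batch_size: int = 64):
    """Labels and softmax posteriors for a patch array (N, 3, H, W);
    batch order preserved. Empty input gives empty output."""
    probs, labels = predict_posteriors(network, np.asarray(patches, dtype=np.float64), batch_size)
    return labels, probs
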