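"""Differentiable decision forest (the network's decision layer).

Each tree is a full binary tree of fixed depth. Every internal (decision)
node d holds an affine functional f_r of the input features; the node
routes a sample left with probability f_d = sigmoid(f_r(x)) and right
with 1 - f_d. The probability mu_p that a sample reaches leaf p is the
product of the routing probabilities along its root-to-leaf path, so
sum_p mu_p = 1 exactly. Each leaf carries a class distribution pi_p
(parameterized by a softmax over free logits); a tree's posterior is
sum_p pi_p mu_p and the forest averages its trees.

Inside the network the layer runs in *embedding* mode: the concatenated
leaf-reach probabilities of all trees form the feature vector handed to
the fully connected head (z trees x 2^depth leaves = 720 wide at the
default z=45, depth=4). *Probability* mode exposes the per-tree class
posteriors for standalone forest use.

Nodes are indexed in level order (node i's children are 2i+1, 2i+2);
leaf p's path is the binary expansion of p, 0 = left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Layer, softmax


def sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ForestState:
    """Parameters of a decision forest.

    decision_weights : (n_trees, n_nodes, in_dim)
    decision_biases  : (n_trees, n_nodes)
    leaf_logits      : (n_trees, n_leaves, n_classes); pi = softmax(leaf_logits)
    """

    n_trees: int
    depth: int
    decision_weights: np.ndarray
    decision_biases: np.ndarray
    leaf_logits: np.ndarray = None

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        n_nodes, n_leaves = 2**self.depth - 1, 2**self.depth
        if self.decision_weights.shape[:2] != (self.n_trees, n_nodes):
            raise ValueError(
                f"decision_weights shape {self.decision_weights.shape} "
                f"inconsistent with {self.n_trees} trees of depth {self.depth}"
            )
        if self.leaf_logits is None:
            self.leaf_logits = np.zeros((self.n_trees, n_leaves, 2))

    @property
    def n_nodes(self) -> int:
        return 2**self.depth - 1

    @property
    def n_leaves(self) -> int:
        return 2**self.depth

    @property
    def in_dim(self) -> int:
        return self.decision_weights.shape[2]

    @property
    def embedding_width(self) -> int:
        return self.n_trees * self.n_leaves

    @property
    def leaf_distributions(self) -> np.ndarray:
        """pi: (n_trees, n_leaves, n_classes), each row summing to 1."""
        return softmax(self.leaf_logits)

    @classmethod
    def init_random(cls, n_trees, depth, in_dim, rng, n_classes=2, scale=None):
        n_nodes = 2**depth - 1
        scale = scale if scale is not None else np.sqrt(6.0 / in_dim)
        return cls(
            n_trees=n_trees,
            depth=depth,
            decision_weights=rng.uniform(-scale, scale, (n_trees, n_nodes, in_dim)),
            decision_biases=np.zeros((n_trees, n_nodes)),
            leaf_logits=np.zeros((n_trees, 2**depth, n_classes)),
        )

    @classmethod
    def from_leaf_distributions(cls, decision_weights, decision_biases, pi):
        """Build a forest with explicitly given leaf distributions."""
        pi = np.asarray(pi, dtype=np.float64)
        if np.any(pi <= 0):
            raise ValueError("leaf distributions must be strictly positive to invert")
        state = cls(
            n_trees=decision_weights.shape[0],
            depth=int(np.log2(pi.shape[1])),
            decision_weights=np.asarray(decision_weights, dtype=np.float64),
            decision_biases=np.asarray(decision_biases, dtype=np.float64),
            leaf_logits=np.log(pi),
        )
        return state


def _routing_forward(X, forest: ForestState):
    """mu for a batch: X (B, F) -> mu (B, z, n_leaves), plus caches."""
    B = X.shape[0]
    z, n_nodes = forest.n_trees, forest.n_nodes
    if n_nodes == 0:  # depth-0 trees: single leaf, mu = 1
        return np.ones((B, z, 1)), (None, [np.ones((B, z, 1))])
    pre = np.einsum("bf,znf->bzn", X, forest.decision_weights) + forest.decision_biases
    d = sigmoid(pre)
    levels = [np.ones((B, z, 1))]
    for k in range(forest.depth):
        dk = d[:, :, 2**k - 1 : 2 ** (k + 1) - 1]  # (B, z, 2^k)
        P = levels[-1]
        nxt = np.empty((B, z, 2 ** (k + 1)))
        nxt[..., 0::2] = P * dk
        nxt[..., 1::2] = P * (1.0 - dk)
        levels.append(nxt)
    return levels[-1], (d, levels)


def _routing_backward(dmu, X, forest: ForestState, cache):
    """Gradients of sum(loss) w.r.t. X, decision weights and biases."""
    d, levels = cache
    if d is None:
        return np.zeros_like(X), np.zeros_like(forest.decision_weights), np.zeros_like(
            forest.decision_biases
        )
    dd = np.zeros_like(d)
    dP = dmu
    for k in range(forest.depth - 1, -1, -1):
        dk = d[:, :, 2**k - 1 : 2 ** (k + 1) - 1]
        P = levels[k]
        dleft, dright = dP[..., 0::2], dP[..., 1::2]
        dd[:, :, 2**k - 1 : 2 ** (k + 1) - 1] = (dleft - dright) * P
        dP = dleft * dk + dright * (1.0 - dk)
    dpre = dd * d * (1.0 - d)
    dW = np.einsum("bzn,bf->znf", dpre, X)
    db = dpre.sum(axis=0)
    dX = np.einsum("bzn,znf->bf", dpre, forest.decision_weights)
    return dX, dW, db


def decision_routing(features: np.ndarray, forest: ForestState, tree: int = 0) -> np.ndarray:
    """Leaf-reach probabilities mu of one tree for a single feature vector."""
    X = np.asarray(features, dtype=np.float64).reshape(1, -1)
    mu, _ = _routing_forward(X, forest)
    return mu[0, tree]


def forest_predict(features: np.ndarray, forest: ForestState) -> np.ndarray:
    """Forest class posterior: uniform average over trees of
    sum_p pi_p mu_p. Accepts a single vector or a batch."""
    X = np.asarray(features, dtype=np.float64)
    single = X.ndim == 1
    X = X.reshape(1, -1) if single else X
    mu, _ = _routing_forward(X, forest)
    per_tree = np.einsum("bzp,zpc->bzc", mu, forest.leaf_distributions)
    out = per_tree.mean(axis=1)
    return out[0] if single else out


def decision_layer_forward(
    conv_features: np.ndarray, forest: ForestState, mode: str = "embedding"
) -> np.ndarray:
    """Decision-layer output for flattened conv features.

    ``embedding`` (default): concatenated leaf-reach probabilities of all
    trees, width n_trees * 2**depth. ``probability``: per-tree class
    posteriors concatenated.
    """
    X = np.asarray(conv_features, dtype=np.float64)
    single = X.ndim == 1
    X = X.reshape(1, -1) if single else X.reshape(X.shape[0], -1)
    if X.shape[1] != forest.in_dim:
        raise ValueError(
            f"decision layer expects {forest.in_dim} features, got {X.shape[1]}"
        )
    mu, _ = _routing_forward(X, forest)
    if mode == "embedding":
        out = mu.reshape(X.shape[0], -1)
    elif mode == "probability":
        out = np.einsum("bzp,zpc->bzc", mu, forest.leaf_distributions).reshape(
            X.shape[0], -1
        )
    else:
        raise ValueError(f"unknown decision-layer mode {mode!r}")
    return out[0] if single else out


class DecisionLayer(Layer):
    """Network layer wrapping a ForestState in embedding mode.

    Trainable parameters are the decision-node functionals; the leaf
    distributions are untouched in embedding mode (the fully connected
    head consumes the routing probabilities directly).
    """

    def __init__(self, forest: ForestState, name="decision"):
        super().__init__()
        self.name = name
        self.forest = forest
        self.params["W"] = forest.decision_weights
        self.params["b"] = forest.decision_biases

    def forward(self, x, train=False):
        X = x.reshape(x.shape[0], -1)
        if X.shape[1] != self.forest.in_dim:
            raise ValueError(
                f"{self.name}: expects {self.forest.in_dim} features, got {X.shape[1]}"
            )
        mu, cache = _routing_forward(X, self.forest)
        self._cache = (X, cache, x.shape)
        return mu.reshape(X.shape[0], -1)

    def backward(self, dout):
        X, cache, xshape = self._cache
        dmu = dout.reshape(X.shape[0], self.forest.n_trees, self.forest.n_leaves)
        dX, dW, db = _routing_backward(dmu, X, self.forest, cache)
        self.grads["W"] = dW
        self.grads["b"] = db
        return dX.reshape(xshape)
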