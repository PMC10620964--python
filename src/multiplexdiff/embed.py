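"""Phase I — joint node representation learning.

Every node of every layer contributes one training row: its vector of edge
weights to all n nodes of that layer. All rows (real layers and, for the
permutation null, permuted layers too) are stacked and fed through a single
fully connected encoder-decoder network with a k-dimensional bottleneck, so
all node embeddings live in one shared space. The decoder reconstructs
either the raw edge-weight vector ("adjacency" targets) or the distribution
of a fixed-length random walk started at the node ("random_walk" targets);
output units are logistic because targets are in [0, 1], and the loss is
binary cross-entropy.

The between-layer distance of a node's two embedding vectors (cosine by
default) measures how much its neighborhood differs between the layers.

The network is a small multilayer perceptron trained with Adam; it is
implemented directly on NumPy arrays, which keeps training exactly
reproducible from a single integer seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .netio import MultiplexNetwork

logger = logging.getLogger("multiplexdiff")


# ---------------------------------------------------------------------------
# Configuration and result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyper-parameters of the encoder-decoder embedding.

    k : bottleneck (embedding) dimension.
    target_mode : 'adjacency' reconstructs the input weight vector;
        'random_walk' reconstructs the L-step random-walk distribution.
    walk_length : L, number of random-walk steps (target_mode='random_walk').
    bottleneck_activation : activation of the k-unit bottleneck layer.
    hidden_dim : width of the one hidden layer on each side; None means
        max(64, 4k).
    epochs, learning_rate, batch_size : Adam training schedule.
    early_stop_patience/early_stop_tol : stop when the epoch loss has not
        improved by more than tol for patience epochs.
    seed : master seed; all initialization and batching derive from it.
    distance_metric : between-layer node distance.
    """

    k: int = 2
    target_mode: Literal["adjacency", "random_walk"] = "adjacency"
    walk_length: int = 3
    bottleneck_activation: Literal["identity", "tanh", "relu"] = "tanh"
    hidden_dim: int | None = None
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    early_stop_patience: int = 20
    early_stop_tol: float = 1e-6
    seed: int = 0
    distance_metric: Literal["cosine", "euclidean"] = "cosine"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.target_mode == "random_walk" and self.walk_length < 1:
            raise ValueError("walk_length must be >= 1 for random_walk targets")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training schedule")

    def hidden_width(self) -> int:
        return self.hidden_dim if self.hidden_dim is not None else max(64, 4 * self.k)


@dataclass
class NodeEmbedding:
    """k-vectors for every (layer, node) pair, all in one shared space."""

    node_ids: list[str]
    layer_names: list[str]
    vectors: np.ndarray  # (n_layers, n_nodes, k)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[:2] != (len(self.layer_names), len(self.node_ids)):
            raise ValueError("vector array shape does not match layers x nodes")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains NaN/Inf")

    @property
    def k(self) -> int:
        return self.vectors.shape[2]

    def layer_vectors(self, layer: str) -> np.ndarray:
        if layer not in self.layer_names:
            raise KeyError(f"unknown layer '{layer}'; have {self.layer_names}")
        return self.vectors[self.layer_names.index(layer)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for li, layer in enumerate(self.layer_names):
            for ni, node in enumerate(self.node_ids):
                rows.append([layer, node, *self.vectors[li, ni]])
        cols = ["layer", "node"] + [f"v{i + 1}" for i in range(self.k)]
        return pd.DataFrame(rows, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DistanceTable:
    """Per-node between-layer embedding distance d."""

    node_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.node_ids),):
            raise ValueError("one distance per node required")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.node_ids, "distance": self.d})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature and target construction
# ---------------------------------------------------------------------------


def node_features(net: MultiplexNetwork, layer: str) -> np.ndarray:
    """Per-node input vectors for one layer: the adjacency rows.

    Row v holds the edge weights between node v and every node of the
    layer, in ``node_ids`` order.
    """
    return net.layer(layer).copy()


def random_walk_targets(W: np.ndarray, L: int) -> np.ndarray:
    """Exact L-step random-walk distribution matrix P^L.

    P is the row-normalized weight matrix; a zero-strength (isolated) node
    is given a self-loop, P(v, v) = 1, so probability is conserved. Row v
    of the result is the distribution over end nodes of an L-step walk
    started at v.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("random-walk targets need nonnegative weights")
    if L < 0:
        raise ValueError("walk length must be >= 0")
    n = W.shape[0]
    strength = W.sum(axis=1)
    P = np.zeros_like(W, dtype=float)
    nz = strength > 0
    P[nz] = W[nz] / strength[nz, None]
    iso = np.flatnonzero(~nz)
    P[iso, iso] = 1.0
    return np.linalg.matrix_power(P, L)


def build_training_rows(
    layer_matrices: list[np.ndarray], config: EmbeddingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Stack features and targets for a list of layer weight matrices."""
    features = np.vstack(layer_matrices)
    if config.target_mode == "adjacency":
        targets = features.copy()
    elif config.target_mode == "random_walk":
        targets = np.vstack(
            [random_walk_targets(W, config.walk_length) for W in layer_matrices]
        )
    else:
        raise ValueError(f"unknown target_mode '{config.target_mode}'")
    return features, targets


# ---------------------------------------------------------------------------
# The encoder-decoder network
# ---------------------------------------------------------------------------


def _activate(name: str, x: np.ndarray) -> np.ndarray:
    if name == "identity":
        return x
    if name == "tanh":
        return np.tanh(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    raise ValueError(f"unknown activation '{name}'")


def _activate_grad(name: str, x: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "identity":
        return np.ones_like(x)
    if name == "tanh":
        return 1.0 - a * a
    if name == "relu":
        return (x > 0).astype(float)
    raise ValueError(f"unknown activation '{name}'")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _EDNN:
    """Fully connected encoder-decoder: n -> h -> k -> h -> n.

    Hidden activations are ReLU, bottleneck activation is configurable,
    outputs are logistic; trained with Adam on mean binary cross-entropy.
    """

    def __init__(self, n: int, config: EmbeddingConfig, rng: np.random.Generator):
        h, k = config.hidden_width(), config.k
        self.config = config
        dims = [(n, h), (h, k), (k, h), (h, n)]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)) for din, dout in dims]
        self.b = [np.zeros(dout) for _, dout in dims]
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    def forward(self, X: np.ndarray) -> dict[str, np.ndarray]:
        c = self.config
        z1 = X @ self.W[0] + self.b[0]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.W[1] + self.b[1]
        a2 = _activate(c.bottleneck_activation, z2)  # the embedding
        z3 = a2 @ self.W[2] + self.b[2]
        a3 = np.maximum(z3, 0.0)
        z4 = a3 @ self.W[3] + self.b[3]
        out = _sigmoid(z4)
        return {"z1": z1, "a1": a1, "z2": z2, "a2": a2, "z3": z3, "a3": a3, "out": out}

    def embed(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)["a2"]

    @staticmethod
    def bce(out: np.ndarray, T: np.ndarray) -> float:
        eps = 1e-12
        return float(
            -np.mean(T * np.log(out + eps) + (1.0 - T) * np.log(1.0 - out + eps))
        )

    def train_step(self, X: np.ndarray, T: np.ndarray) -> float:
        c = self.config
        f = self.forward(X)
        B = X.shape[0]
        loss = self.bce(f["out"], T)
        # d(BCE)/d(z4) = (sigmoid(z4) - T) / (B * n_out)
        delta = (f["out"] - T) / (B * T.shape[1])
        gW = [np.empty(0)] * 4
        gb = [np.empty(0)] * 4
        gW[3] = f["a3"].T @ delta
        gb[3] = delta.sum(axis=0)
        delta = (delta @ self.W[3].T) * (f["z3"] > 0)
        gW[2] = f["a2"].T @ delta
        gb[2] = delta.sum(axis=0)
        delta = (delta @ self.W[2].T) * _activate_grad(
            c.bottleneck_activation, f["z2"], f["a2"]
        )
        gW[1] = f["a1"].T @ delta
        gb[1] = delta.sum(axis=0)
        delta = (delta @ self.W[1].T) * (f["z1"] > 0)
        gW[0] = X.T @ delta
        gb[0] = delta.sum(axis=0)
        self._adam(gW + gb)
        return loss

    def _adam(self, grads: list[np.ndarray], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        params = self.W + self.b
        lr = self.config.learning_rate
        t = self._adam_t
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedEmbedder:
    """A trained network plus the loss trace, for inspection and re-use."""

    network: _EDNN
    losses: list[float]

    @property
    def initial_loss(self) -> float:
        return self.losses[0]

    @property
    def final_loss(self) -> float:
        return self.losses[-1]

    def embed_rows(self, X: np.ndarray) -> np.ndarray:
        return self.network.embed(np.asarray(X, dtype=float))


def fit_ednn(
    features: np.ndarray, targets: np.ndarray, config: EmbeddingConfig
) -> TrainedEmbedder:
    """Train the encoder-decoder on stacked (layer, node) rows.

    Deterministic given ``config.seed``. Raises if targets leave [0, 1] or
    the loss becomes non-finite (reduce the learning rate).
    """
    X = np.asarray(features, dtype=float)
    T = np.asarray(targets, dtype=float)
    if X.shape[0] != T.shape[0]:
        raise ValueError("features and targets must have equal row counts")
    if T.min() < 0.0 or T.max() > 1.0:
        raise ValueError("targets must lie in [0, 1]")
    n = X.shape[1]
    if config.k >= n:
        raise ValueError(f"bottleneck k={config.k} must be < input dimension n={n}")
    rng = np.random.default_rng(config.seed)
    net = _EDNN(n, config, rng)

    losses = [net.bce(net.forward(X)["out"], T)]
    best = losses[0]
    stall = 0
    n_rows = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n_rows)
        epoch_losses = []
        for start in range(0, n_rows, config.batch_size):
            sel = order[start : start + config.batch_size]
            loss = net.train_step(X[sel], T[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training loss became non-finite; try a smaller learning rate"
                )
            epoch_losses.append(loss)
        epoch_loss = float(np.mean(epoch_losses))
        losses.append(epoch_loss)
        if best - epoch_loss > config.early_stop_tol:
            best = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break
    logger.info(
        "EDNN trained: %d rows, dim %d, %d epochs, loss %.5f -> %.5f",
        n_rows, n, len(losses) - 1, losses[0], losses[-1],
    )
    return TrainedEmbedder(net, losses)


def train_ednn(
    features: np.ndarray,
    targets: np.ndarray,
    config: EmbeddingConfig,
    node_ids: list[str] | None = None,
    layer_names: list[str] | None = None,
) -> NodeEmbedding:
    """Train and return the bottleneck vectors of every (layer, node) row.

    Rows must be ordered layer-by-layer (all nodes of layer 1, then all of
    layer 2, ...). When ``node_ids``/``layer_names`` are omitted, synthetic
    names are generated from the row layout.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[1]
    if X.shape[0] % n != 0:
        raise ValueError(
            "row count must be a multiple of the node count (one block per layer)"
        )
    n_layers = X.shape[0] // n
    if node_ids is None:
        node_ids = [f"node{i}" for i in range(n)]
    if layer_names is None:
        layer_names = [f"layer{i + 1}" for i in range(n_layers)]
    trained = fit_ednn(X, targets, config)
    vectors = trained.embed_rows(X).reshape(n_layers, n, config.k)
    return NodeEmbedding(list(node_ids), list(layer_names), vectors)


def embed_multiplex(net: MultiplexNetwork, config: EmbeddingConfig) -> NodeEmbedding:
    """Jointly embed all layers of one multiplex network."""
    mats = [net.layer(name) for name in net.layer_names]
    features, targets = build_training_rows(mats, config)
    return train_ednn(
        features, targets, config, node_ids=net.node_ids, layer_names=net.layer_names
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def cosine_distance(u: np.ndarray, w: np.ndarray) -> float:
    """1 - cos(u, w); identical vectors give exactly 0, zero-norm gives 1."""
    if np.array_equal(u, w):
        return 0.0
    nu = float(np.linalg.norm(u))
    nw = float(np.linalg.norm(w))
    if nu == 0.0 or nw == 0.0:
        warnings.warn(
            "zero-norm embedding vector: cosine distance set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    cos = float(np.dot(u, w)) / (nu * nw)
    return 1.0 - max(-1.0, min(1.0, cos))


def node_distances(
    emb: NodeEmbedding,
    layer_a: str,
    layer_b: str,
    metric: Literal["cosine", "euclidean"] = "cosine",
) -> DistanceTable:
    """Per-node distance between its two layer embeddings."""
    A = emb.layer_vectors(layer_a)
    B = emb.layer_vectors(layer_b)
    if metric == "cosine":
        d = np.array([cosine_distance(u, w) for u, w in zip(A, B)])
    elif metric == "euclidean":
        d = np.linalg.norm(A - B, axis=1)
    else:
        raise ValueError(f"unknown distance metric '{metric}'")
    return DistanceTable(list(emb.node_ids), d)
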