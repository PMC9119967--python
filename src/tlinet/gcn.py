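"""Deep message-passing graph convolutional module.

One module (used identically for ligands and proteins) is: a linear input
embedding of the concatenated one-hot node/edge features, a stack of
pre-activation residual message-passing blocks, and a permutation-invariant
pooling to a fixed-size graph embedding.

Each block computes, over the bidirected bond edges,

    h        = ReLU(Norm(X))                      (pre-activation ordering)
    M_vu     = ReLU(h_u + e_vu) + eps             (message construction)
    M_v      = sum_u softmax_u(beta * M_vu) M_vu  (learnable softmax aggregation,
                                                   applied feature-wise)
    X <- X + MLP(h_v + M_v)                       (update + residual)

with a scalar learnable inverse temperature ``beta`` per layer (init 1).
``beta = 0`` makes the aggregation an arithmetic mean; large ``beta``
approaches the feature-wise maximum. An optional dilated k-NN rewiring is
available (every d-th of the k*d nearest nodes in the current embedding
space); it is off by default, so message passing follows chemical bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .featurize import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph

MESSAGE_EPS = 1e-7


class ConfigurationError(ValueError):
    """Inconsistent model configuration or parameter shapes."""


@dataclass(frozen=True)
class GCNConfig:
    """Architecture hyperparameters of one GCN module.

    Defaults are the full-scale configuration: 20 message-passing layers and
    128-dimensional embeddings with softmax aggregation and mean pooling.
    ``dilation=(k, d)`` enables dilated k-NN neighborhoods.
    """

    num_layers: int = 20
    hidden_dim: int = 128
    aggregation: str = "softmax"  # or "powermean"
    pooling: str = "mean"  # or "max", "sum"
    dilation: tuple[int, int] | None = None
    mlp_hidden_multiplier: int = 2
    dropout: float = 0.0
    powermean_p: float = 1.0

    def __post_init__(self):
        if self.num_layers < 0 or self.hidden_dim < 1:
            raise ConfigurationError("num_layers >= 0 and hidden_dim >= 1 required")
        if self.aggregation not in ("softmax", "powermean"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        if self.pooling not in ("mean", "max", "sum"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")
        if self.dilation is not None:
            k, d = self.dilation
            if k < 1 or d < 1:
                raise ConfigurationError("dilation (k, d) must both be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")


#: Desk-scale profile used by the synthetic benchmarks and the examples.
DESK_CONFIG = GCNConfig(num_layers=4, hidden_dim=32)


class BatchNorm:
    """Feature-wise batch normalization over the node dimension.

    Training mode uses batch statistics and updates exponential running
    statistics; evaluation mode uses the frozen running statistics, making
    the whole network deterministic.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = ad.parameter(np.ones(dim))
        self.beta = ad.parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.data.shape[0] > 1:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            centered = ad.add(x, ad.constant(-mu))
            xhat = ad.mul(centered, ad.constant(1.0 / np.sqrt(var + self.eps)))
        else:
            centered = ad.add(x, ad.constant(-self.running_mean))
            xhat = ad.mul(centered, ad.constant(1.0 / np.sqrt(self.running_var + self.eps)))
        return ad.add(ad.mul(xhat, self.gamma), self.beta)

    def parameters(self):
        return [self.gamma, self.beta]


class LayerParams:
    """Learnable state of one residual message-passing block."""

    def __init__(self, config: GCNConfig, rng: np.random.Generator):
        h = config.hidden_dim
        m = config.mlp_hidden_multiplier * h
        self.pre_norm = BatchNorm(h)
        self.beta = ad.parameter(1.0)  # aggregation inverse temperature
        self.mlp_w1 = ad.parameter(_glorot(rng, h, m))
        self.mlp_b1 = ad.parameter(np.zeros(m))
        self.mlp_norm = BatchNorm(m)
        self.mlp_w2 = ad.parameter(_glorot(rng, m, h))
        self.mlp_b2 = ad.parameter(np.zeros(h))

    def parameters(self):
        return (
            self.pre_norm.parameters()
            + [self.beta, self.mlp_w1, self.mlp_b1]
            + self.mlp_norm.parameters()
            + [self.mlp_w2, self.mlp_b2]
        )


class ModuleParams:
    """All learnable state of one GCN module (input embedding + layers)."""

    def __init__(self, config: GCNConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.config = config
        h = config.hidden_dim
        self.node_embed_w = ad.parameter(_glorot(rng, ATOM_FEATURE_DIM, h))
        self.node_embed_b = ad.parameter(np.zeros(h))
        self.edge_embed_w = ad.parameter(_glorot(rng, BOND_FEATURE_DIM, h))
        self.edge_embed_b = ad.parameter(np.zeros(h))
        self.layers = [LayerParams(config, rng) for _ in range(config.num_layers)]

    def parameters(self) -> list[Tensor]:
        params = [
            self.node_embed_w,
            self.node_embed_b,
            self.edge_embed_w,
            self.edge_embed_b,
        ]
        for layer in self.layers:
            params.extend(layer.parameters())
        return params


def _glorot(rng, fan_in, fan_out):
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


# --------------------------------------------------------------------------
# batching


@dataclass
class GraphBatch:
    """Several molecular graphs packed into one disjoint graph.

    Nodes of graph ``g`` occupy the contiguous index range
    ``node_ranges[g]``; directed edges likewise (``edge_ranges``), in the
    same order as in each source graph (two consecutive rows per bond).
    """

    node_features: np.ndarray  # (N, ATOM_FEATURE_DIM)
    edges: np.ndarray  # (E, 2) global indices; row (v, u): message u -> v
    edge_features: np.ndarray  # (E, BOND_FEATURE_DIM)
    node_ranges: list[tuple[int, int]]
    edge_ranges: list[tuple[int, int]]
    node_graph_ids: np.ndarray
    graphs: list[MolecularGraph] = field(default_factory=list)

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_graphs(self) -> int:
        return len(self.node_ranges)

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        node_feats, edge_feats, edges = [], [], []
        node_ranges, edge_ranges, gids = [], [], []
        n_off = e_off = 0
        for g, graph in enumerate(graphs):
            node_feats.append(graph.node_features.astype(np.float64))
            edge_feats.append(graph.edge_features.astype(np.float64))
            edges.append(graph.directed_edges + n_off)
            node_ranges.append((n_off, n_off + graph.node_count))
            e = graph.directed_edges.shape[0]
            edge_ranges.append((e_off, e_off + e))
            gids.append(np.full(graph.node_count, g))
            n_off += graph.node_count
            e_off += e
        return cls(
            node_features=np.concatenate(node_feats),
            edges=np.concatenate(edges) if edges else np.zeros((0, 2), dtype=np.int64),
            edge_features=(
                np.concatenate(edge_feats)
                if edge_feats
                else np.zeros((0, BOND_FEATURE_DIM))
            ),
            node_ranges=node_ranges,
            edge_ranges=edge_ranges,
            node_graph_ids=np.concatenate(gids),
            graphs=list(graphs),
        )


# --------------------------------------------------------------------------
# elementary operations (the spec surface; also used by the batched forward)


def embed_inputs(
    batch: GraphBatch,
    params: ModuleParams,
    edge_coeffs: Tensor | None = None,
) -> tuple[Tensor, Tensor]:
    """Linear projection of the one-hot features to hidden_dim.

    ``edge_coeffs`` (shape (E, 1)), when given, multiplies each directed
    edge's one-hot feature row before projection — the instrumentation hook
    for adversarial edge-gradient analysis. At value 1 it changes nothing.
    """
    if batch.node_features.shape[1] != params.node_embed_w.data.shape[0]:
        raise ConfigurationError("node feature width does not match parameters")
    x = ad.linear(ad.constant(batch.node_features), params.node_embed_w, params.node_embed_b)
    raw_edges = ad.constant(batch.edge_features)
    if edge_coeffs is not None:
        raw_edges = ad.mul(raw_edges, edge_coeffs)
    e = ad.linear(raw_edges, params.edge_embed_w, params.edge_embed_b)
    return x, e


def message_construct(x_v: Tensor, x_u: Tensor, x_e: Tensor) -> Tensor:
    """Per-edge message ReLU(X_u + X_e) + eps (x_v enters only the contract)."""
    return ad.add(ad.relu(ad.add(x_u, x_e)), ad.constant(MESSAGE_EPS))


def aggregate_softmax(messages: Tensor, beta: Tensor | float) -> Tensor:
    """Aggregate a (k, H) stack of messages for one node, feature-wise.

    ``M[j] = sum_u softmax_u(beta * M_u[j]) * M_u[j]``. With ``beta = 0``
    this is the arithmetic mean; as ``beta`` grows it approaches the
    feature-wise maximum. An empty stack aggregates to zeros.
    """
    k = messages.data.shape[0]
    if k == 0:
        return ad.constant(np.zeros(messages.data.shape[1:]))
    beta_t = beta if isinstance(beta, Tensor) else ad.constant(beta)
    seg = np.zeros(k, dtype=np.int64)
    weights = ad.segment_softmax(ad.mul(messages, beta_t), seg, 1)
    return ad.reshape(ad.segment_sum(ad.mul(weights, messages), seg, 1), messages.data.shape[1:])


def aggregate_powermean(messages: Tensor, p: float) -> Tensor:
    """Power-mean aggregation ``(mean_u M_u^p)^(1/p)`` (reference variant)."""
    if messages.data.shape[0] == 0:
        return ad.constant(np.zeros(messages.data.shape[1:]))
    powed = ad.exp(ad.mul(ad.log(messages), ad.constant(p)))
    return ad.exp(ad.mul(ad.log(ad.mean(powed, axis=0)), ad.constant(1.0 / p)))


def node_update(x_v: Tensor, m_v: Tensor, layer: LayerParams, training: bool = False) -> Tensor:
    """MLP(X_v + M_v): linear -> norm -> ReLU -> linear."""
    h = ad.add(x_v, m_v)
    h = ad.linear(h, layer.mlp_w1, layer.mlp_b1)
    h = layer.mlp_norm(h, training)
    h = ad.relu(h)
    return ad.linear(h, layer.mlp_w2, layer.mlp_b2)


def _aggregate_batched(
    messages: Tensor, dest: np.ndarray, num_nodes: int, layer: LayerParams, config: GCNConfig
) -> Tensor:
    if config.aggregation == "softmax":
        scores = ad.mul(messages, layer.beta)
        weights = ad.segment_softmax(scores, dest, num_nodes)
        return ad.segment_sum(ad.mul(weights, messages), dest, num_nodes)
    # powermean over positive messages (messages are >= eps by construction)
    p = config.powermean_p
    powed = ad.exp(ad.mul(ad.log(messages), ad.constant(p)))
    total = ad.segment_sum(powed, dest, num_nodes)
    counts = np.zeros(num_nodes)
    np.add.at(counts, dest, 1.0)
    nonzero = counts > 0
    inv = np.where(nonzero, 1.0 / np.maximum(counts, 1.0), 0.0)
    meaned = ad.mul(total, ad.constant(inv[:, None]))
    # avoid log(0) on isolated nodes: substitute 1, then mask the result
    safe = ad.add(meaned, ad.constant((~nonzero).astype(float)[:, None]))
    root = ad.exp(ad.mul(ad.log(safe), ad.constant(1.0 / p)))
    return ad.mul(root, ad.constant(nonzero.astype(float)[:, None]))


def graph_conv(
    h: Tensor,
    edge_emb: Tensor,
    edges: np.ndarray,
    num_nodes: int,
    layer: LayerParams,
    config: GCNConfig,
    training: bool = False,
) -> Tensor:
    """One graph convolution (Eqs. of message passing) over a flat edge list."""
    if edges.shape[0] == 0:
        m_v = ad.constant(np.zeros((num_nodes, h.data.shape[1])))
    else:
        dest, src = edges[:, 0], edges[:, 1]
        h_u = ad.gather_rows(h, src)
        messages = message_construct(None, h_u, edge_emb)
        m_v = _aggregate_batched(messages, dest, num_nodes, layer, config)
    return node_update(h, m_v, layer, training)


def residual_block(
    x: Tensor,
    edge_emb: Tensor,
    edges: np.ndarray,
    layer: LayerParams,
    config: GCNConfig,
    training: bool = False,
) -> Tensor:
    """Pre-activation residual block: X + GraphConv(ReLU(Norm(X)))."""
    h = ad.relu(layer.pre_norm(x, training))
    return ad.add(x, graph_conv(h, edge_emb, edges, x.data.shape[0], layer, config, training))


def dilated_knn(embeddings: np.ndarray, k: int, d: int) -> list[list[int]]:
    """Dilated k-nearest-neighbor sets in the current embedding space.

    For each node, all other nodes are ranked by ascending Euclidean
    distance (ties broken by node index) and every d-th of the first k*d is
    kept, giving k neighbors. ``d = 1`` is ordinary k-NN.
    """
    n = embeddings.shape[0]
    if k * d > n - 1:
        raise ConfigurationError(f"k*d = {k * d} exceeds available nodes ({n - 1})")
    diffs = embeddings[:, None, :] - embeddings[None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=-1))
    neighbors = []
    for v in range(n):
        order = [u for u in np.lexsort((np.arange(n), dist[v])) if u != v]
        neighbors.append([int(order[i]) for i in range(d - 1, k * d, d)])
    return neighbors


def pool(node_embeddings: Tensor, method: str = "mean") -> Tensor:
    """Pool a (N, H) node-embedding block to one graph embedding."""
    if node_embeddings.data.shape[0] == 0:
        raise ConfigurationError("cannot pool an empty graph")
    if method == "mean":
        return ad.mean(node_embeddings, axis=0)
    if method == "sum":
        return ad.tensor_sum(node_embeddings, axis=0)
    if method == "max":
        return ad.amax(node_embeddings, axis=0)
    raise ConfigurationError(f"unknown pooling {method!r}")


# --------------------------------------------------------------------------
# full forward pass


@dataclass
class ForwardResult:
    """Output of a module forward pass with the hooks gradient analyses need."""

    graph_embeddings: Tensor  # (B, hidden_dim)
    node_input: Tensor  # (N, hidden_dim) post input-projection node embeddings
    edge_input: Tensor  # (E, hidden_dim)
    edge_coeffs: Tensor | None = None


def forward(
    batch: GraphBatch | MolecularGraph,
    params: ModuleParams,
    config: GCNConfig | None = None,
    training: bool = False,
    edge_coeffs: Tensor | None = None,
    rng: np.random.Generator | None = None,
) -> ForwardResult:
    """Full module forward: embed, num_layers residual blocks, pool.

    Deterministic in evaluation mode for fixed parameters. When
    ``config.dilation`` is set, each block's edge list is rebuilt per graph
    from the current node embeddings by :func:`dilated_knn` (with zero edge
    features for the rewired edges); otherwise message passing follows the
    chemical bonds.
    """
    if isinstance(batch, MolecularGraph):
        batch = GraphBatch.from_graphs([batch])
    config = config or params.config
    x, edge_emb = embed_inputs(batch, params, edge_coeffs=edge_coeffs)
    node_input = x
    for layer in params.layers:
        if config.dilation is not None:
            k, d = config.dilation
            edges = _knn_edges(batch, x.data, k, d)
            e_emb = ad.constant(np.zeros((edges.shape[0], config.hidden_dim)))
        else:
            edges, e_emb = batch.edges, edge_emb
        x = residual_block(x, e_emb, edges, layer, config, training)
        if training and config.dropout > 0.0:
            rng = rng or np.random.default_rng()
            mask = (rng.random(x.data.shape) >= config.dropout) / (1.0 - config.dropout)
            x = ad.mul(x, ad.constant(mask))
    pooled = [
        ad.reshape(pool(_rows(x, lo, hi), config.pooling), (1, config.hidden_dim))
        for lo, hi in batch.node_ranges
    ]
    graph_emb = pooled[0] if len(pooled) == 1 else ad.concat(pooled, axis=0)
    return ForwardResult(
        graph_embeddings=graph_emb,
        node_input=node_input,
        edge_input=edge_emb,
        edge_coeffs=edge_coeffs,
    )


def _rows(x: Tensor, lo: int, hi: int) -> Tensor:
    return ad.gather_rows(x, np.arange(lo, hi))


def _knn_edges(batch: GraphBatch, embeddings: np.ndarray, k: int, d: int) -> np.ndarray:
    rows = []
    for lo, hi in batch.node_ranges:
        neigh = dilated_knn(embeddings[lo:hi], k, d)
        for v, us in enumerate(neigh):
            rows.extend((lo + v, lo + u) for u in us)
    return np.asarray(rows, dtype=np.int64) if rows else np.zeros((0, 2), dtype=np.int64)
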