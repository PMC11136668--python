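"""Baseline graph-network models for QM properties, per-atom adaptability
and pairwise relative binding affinity.

Three learners share one compact message-passing toolkit built on a minimal
reverse-mode automatic-differentiation engine (numpy only):

* **QM property model** — a dense embedding followed by three
  edge-conditioned message-passing blocks with a gated recurrent state
  update, graph-sum pooling and two dense layers emitting two outputs
  (electron affinity and chemical hardness, trained jointly by MSE on
  standardized targets).
* **Node adaptability model** — five graph-convolution layers followed by
  two linear layers, with *no* node-to-graph aggregation: the output is one
  scalar per atom.
* **Pair affinity model** — a twin (shared-weight) five-layer
  graph-convolution encoder; each complex is scored by pooling ligand and
  protein nodes separately, concatenating, and applying three linear
  layers with ReLU nonlinearities.  The pair prediction is
  score(target) − score(base), trained by MSE against the log10 affinity
  ratio.  Antisymmetry under pair swap and exact zero on identical pairs
  hold by construction.

All training is deterministic for a fixed seed and single-threaded BLAS.
"""

from __future__ import annotations

import dataclasses
import pickle
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .config import SchemaError, ValidationError
from .featurization import Graph, PairSample

# ---------------------------------------------------------------------------
# Minimal reverse-mode autodiff engine
# ---------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_prev", "_backward")

    def __init__(self, data, prev: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self._prev = prev
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward():
            self.grad += _unbroadcast(out.grad, self.data.shape)
            other.grad += _unbroadcast(out.grad, other.data.shape)

        out._backward = backward
        return out

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward():
            self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out._backward = backward
        return out

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, (self, other))

        def backward():
            self.grad += out.grad @ other.data.T
            other.grad += self.data.T @ out.grad

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def backward():
            self.grad += out.grad * (self.data > 0)

        out._backward = backward
        return out

    def tanh(self) -> "Tensor":
        value = np.tanh(self.data)
        out = Tensor(value, (self,))

        def backward():
            self.grad += out.grad * (1.0 - value**2)

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        value = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(value, (self,))

        def backward():
            self.grad += out.grad * value * (1.0 - value)

        out._backward = backward
        return out

    def square(self) -> "Tensor":
        out = Tensor(self.data**2, (self,))

        def backward():
            self.grad += out.grad * 2.0 * self.data

        out._backward = backward
        return out

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean(), (self,))

        def backward():
            self.grad += out.grad * np.ones_like(self.data) / self.data.size

        out._backward = backward
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        index = np.asarray(index, dtype=int)
        out = Tensor(self.data[index], (self,))

        def backward():
            np.add.at(self.grad, index, out.grad)

        out._backward = backward
        return out

    def segment_sum(self, index: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows into ``n_segments`` bins given per-row bin indices."""
        index = np.asarray(index, dtype=int)
        value = np.zeros((n_segments,) + self.data.shape[1:])
        np.add.at(value, index, self.data)
        out = Tensor(value, (self,))

        def backward():
            self.grad += out.grad[index]

        out._backward = backward
        return out

    @staticmethod
    def concat(tensors: Sequence["Tensor"], axis: int = 1) -> "Tensor":
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                t.grad += np.take(out.grad, range(lo, hi), axis=axis)

        out._backward = backward
        return out

    # -- reverse pass ----------------------------------------------------

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent in node._prev:
                visit(parent)
            order.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward()


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * p.grad
            v[:] = self.b2 * v + (1 - self.b2) * p.grad**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Graph batching
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GraphBatch:
    """Several graphs merged into one disjoint graph.

    ``src``/``dst`` list every directed edge twice (both orientations) plus
    one self-loop per node; ``norm`` carries the symmetric normalization
    coefficients w_ij / sqrt(d_i d_j) with weighted degrees d including the
    self-loop.  ``graph_index`` maps nodes to their source graph.
    """

    features: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    edge_weight: np.ndarray
    norm: np.ndarray
    graph_index: np.ndarray
    n_graphs: int
    node_origin: np.ndarray
    n_nodes_per_graph: np.ndarray


def make_batch(graphs: Sequence[Graph]) -> GraphBatch:
    feats, srcs, dsts, weights, gidx, origins, sizes = [], [], [], [], [], [], []
    offset = 0
    for g_number, graph in enumerate(graphs):
        n = graph.n_nodes
        feats.append(graph.node_features)
        if graph.n_edges:
            e = graph.edges + offset
            w = graph.edge_weights
            srcs.append(np.concatenate([e[:, 0], e[:, 1]]))
            dsts.append(np.concatenate([e[:, 1], e[:, 0]]))
            weights.append(np.concatenate([w, w]))
        loop = np.arange(offset, offset + n)
        srcs.append(loop)
        dsts.append(loop)
        weights.append(np.ones(n))
        gidx.append(np.full(n, g_number))
        origins.append(graph.node_origin)
        sizes.append(n)
        offset += n
    features = np.vstack(feats)
    src = np.concatenate(srcs)
    dst = np.concatenate(dsts)
    edge_weight = np.concatenate(weights)
    degree = np.zeros(offset)
    np.add.at(degree, dst, edge_weight)
    norm = edge_weight / np.sqrt(degree[src] * degree[dst])
    return GraphBatch(
        features=features,
        src=src,
        dst=dst,
        edge_weight=edge_weight,
        norm=norm,
        graph_index=np.concatenate(gidx),
        n_graphs=len(graphs),
        node_origin=np.concatenate(origins),
        n_nodes_per_graph=np.array(sizes),
    )


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


def _dense_init(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
    scale = np.sqrt(2.0 / n_in)
    return Tensor(rng.normal(0.0, scale, (n_in, n_out))), Tensor(np.zeros(n_out))


class GCNConv:
    """Graph convolution: H' = act(Â H W + b) with weighted symmetric
    normalization Â (self-loops included)."""

    def __init__(self, rng, n_in: int, n_out: int):
        self.W, self.b = _dense_init(rng, n_in, n_out)

    def params(self):
        return [self.W, self.b]

    def __call__(self, h: Tensor, batch: GraphBatch, activate: bool = True) -> Tensor:
        n = batch.features.shape[0]
        projected = h.matmul(self.W)
        messages = projected.gather_rows(batch.src) * batch.norm[:, None]
        aggregated = messages.segment_sum(batch.dst, n)
        out = aggregated + self.b
        return out.relu() if activate else out


class EdgeConditionedConv:
    """Message passing with messages gated by a function of the edge weight.

    A two-layer perceptron maps each edge's scalar weight (1/distance) to a
    per-channel gate; the message from j to i is h_j elementwise-scaled by
    that gate, summed over neighbours.
    """

    def __init__(self, rng, dim: int, edge_hidden: int = 16):
        self.W1, self.b1 = _dense_init(rng, 1, edge_hidden)
        self.W2, self.b2 = _dense_init(rng, edge_hidden, dim)

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        n = batch.features.shape[0]
        ew = Tensor(batch.edge_weight[:, None])
        gate = ew.matmul(self.W1) + self.b1
        gate = gate.tanh().matmul(self.W2) + self.b2
        messages = h.gather_rows(batch.src) * gate
        # normalize by weighted degree so message scale is size-independent
        return messages.segment_sum(batch.dst, n) * (
            1.0 / np.maximum(np.bincount(batch.dst, minlength=n), 1.0)[:, None]
        )


class GRUCell:
    """Gated recurrent state update between message-passing rounds."""

    def __init__(self, rng, dim: int):
        self.Wz, self.bz = _dense_init(rng, 2 * dim, dim)
        self.Wr, self.br = _dense_init(rng, 2 * dim, dim)
        self.Wn, self.bn = _dense_init(rng, 2 * dim, dim)

    def params(self):
        return [self.Wz, self.bz, self.Wr, self.br, self.Wn, self.bn]

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        xh = Tensor.concat([x, h], axis=1)
        z = (xh.matmul(self.Wz) + self.bz).sigmoid()
        r = (xh.matmul(self.Wr) + self.br).sigmoid()
        xrh = Tensor.concat([x, r * h], axis=1)
        n = (xrh.matmul(self.Wn) + self.bn).tanh()
        return (1.0 - z) * n + z * h


def _mean_pool(h: Tensor, batch: GraphBatch, mask: np.ndarray | None = None) -> Tensor:
    """Mean-pool node embeddings per graph, optionally over a node mask."""
    weights = np.ones(batch.features.shape[0]) if mask is None else mask.astype(float)
    counts = np.zeros(batch.n_graphs)
    np.add.at(counts, batch.graph_index, weights)
    pooled = (h * weights[:, None]).segment_sum(batch.graph_index, batch.n_graphs)
    return pooled * (1.0 / np.maximum(counts, 1.0))[:, None]


def _sum_pool(h: Tensor, batch: GraphBatch) -> Tensor:
    return h.segment_sum(batch.graph_index, batch.n_graphs)


# ---------------------------------------------------------------------------
# Model configuration / container
# ---------------------------------------------------------------------------

TASKS = ("qm_property", "node_adaptability", "pair_affinity")


@dataclasses.dataclass
class ModelConfig:
    """Hyper-parameters for one training run.

    Defaults are desk scale (about 10^4 parameters, minutes on one CPU).
    The published-scale settings for reference: QM task 3 conv blocks /
    batch 128 / 200 epochs; node task 5 conv / batch 8 / 15 epochs; pair
    task 5 conv / batch 50 / 50 epochs.
    """

    task: str = "qm_property"
    n_conv_layers: int = 3
    hidden_dim: int = 32
    n_dense_layers: int = 2
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    augment_amplitude: float = 0.0   # Å; 0 disables train-time jitter
    device: str = "cpu"

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        for field in ("n_conv_layers", "hidden_dim", "n_dense_layers",
                      "epochs", "batch_size"):
            if getattr(self, field) < 1:
                raise ValidationError(f"{field} must be >= 1")


@dataclasses.dataclass
class TrainedModel:
    config: ModelConfig
    network: object                      # one of the model classes below
    training_log: list[float]
    feature_schema: tuple[str, ...]
    target_mean: np.ndarray | None = None
    target_std: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.network.params()))

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _check_schema(model: TrainedModel, graphs: Sequence[Graph]) -> None:
    for graph in graphs:
        if tuple(graph.feature_blocks) != tuple(model.feature_schema):
            missing = set(model.feature_schema) - set(graph.feature_blocks)
            raise SchemaError(
                f"feature schema mismatch: model expects "
                f"{model.feature_schema}, graph {graph.entry_id!r} has "
                f"{graph.feature_blocks}"
                + (f" (missing blocks: {sorted(missing)})" if missing else "")
            )


def _common_schema(graphs: Sequence[Graph]) -> tuple[str, ...]:
    schemas = {tuple(g.feature_blocks) for g in graphs}
    if len(schemas) != 1:
        raise SchemaError(f"graphs carry inconsistent feature schemas: {schemas}")
    return schemas.pop()


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


class QMPropertyNetwork:
    """Dense embed -> n x (edge-conditioned conv + GRU) -> sum pool -> dense."""

    def __init__(self, rng, n_features: int, hidden: int, n_blocks: int):
        self.embed_W, self.embed_b = _dense_init(rng, n_features, hidden)
        self.convs = [EdgeConditionedConv(rng, hidden) for _ in range(n_blocks)]
        self.grus = [GRUCell(rng, hidden) for _ in range(n_blocks)]
        self.head1_W, self.head1_b = _dense_init(rng, hidden, hidden)
        self.head2_W, self.head2_b = _dense_init(rng, hidden, 2)

    def params(self):
        out = [self.embed_W, self.embed_b, self.head1_W, self.head1_b,
               self.head2_W, self.head2_b]
        for conv in self.convs:
            out.extend(conv.params())
        for gru in self.grus:
            out.extend(gru.params())
        return out

    def __call__(self, batch: GraphBatch) -> Tensor:
        h = (Tensor(batch.features).matmul(self.embed_W) + self.embed_b).relu()
        for conv, gru in zip(self.convs, self.grus):
            h = gru(conv(h, batch), h)
        pooled = _sum_pool(h, batch)
        hidden = (pooled.matmul(self.head1_W) + self.head1_b).relu()
        return hidden.matmul(self.head2_W) + self.head2_b


class NodeAdaptabilityNetwork:
    """n graph convolutions then two per-node linear layers; no pooling."""

    def __init__(self, rng, n_features: int, hidden: int, n_conv: int):
        dims = [n_features] + [hidden] * n_conv
        self.convs = [GCNConv(rng, dims[i], dims[i + 1]) for i in range(n_conv)]
        self.lin1_W, self.lin1_b = _dense_init(rng, hidden, hidden)
        self.lin2_W, self.lin2_b = _dense_init(rng, hidden, 1)

    def params(self):
        out = [self.lin1_W, self.lin1_b, self.lin2_W, self.lin2_b]
        for conv in self.convs:
            out.extend(conv.params())
        return out

    def __call__(self, batch: GraphBatch) -> Tensor:
        h = Tensor(batch.features)
        for conv in self.convs:
            h = conv(h, batch)
        h = (h.matmul(self.lin1_W) + self.lin1_b).relu()
        return h.matmul(self.lin2_W) + self.lin2_b


class PairAffinityNetwork:
    """Shared encoder; separate ligand/protein pooling; 3-layer head.

    ``score`` embeds one batch of complexes into per-complex scalars; the
    pair prediction is the difference of the two twin scores, so identical
    inputs give exactly zero and swapping the pair negates the output.
    """

    def __init__(self, rng, n_features: int, hidden: int, n_conv: int):
        dims = [n_features] + [hidden] * n_conv
        self.convs = [GCNConv(rng, dims[i], dims[i + 1]) for i in range(n_conv)]
        self.head1_W, self.head1_b = _dense_init(rng, 2 * hidden, hidden)
        self.head2_W, self.head2_b = _dense_init(rng, hidden, hidden)
        self.head3_W, self.head3_b = _dense_init(rng, hidden, 1)

    def params(self):
        out = [self.head1_W, self.head1_b, self.head2_W, self.head2_b,
               self.head3_W, self.head3_b]
        for conv in self.convs:
            out.extend(conv.params())
        return out

    def score(self, batch: GraphBatch) -> Tensor:
        h = Tensor(batch.features)
        for conv in self.convs:
            h = conv(h, batch)
        ligand = _mean_pool(h, batch, mask=batch.node_origin == 1)
        protein = _mean_pool(h, batch, mask=batch.node_origin == 0)
        z = Tensor.concat([ligand, protein], axis=1)
        z = (z.matmul(self.head1_W) + self.head1_b).relu()
        z = (z.matmul(self.head2_W) + self.head2_b).relu()
        return z.matmul(self.head3_W) + self.head3_b

    def __call__(self, target: GraphBatch, base: GraphBatch) -> Tensor:
        return self.score(target) - self.score(base)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_qm_model(
    graphs: Sequence[Graph],
    targets: np.ndarray,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Train the graph-level two-output regressor (MSE, standardized)."""
    config = config or ModelConfig(task="qm_property")
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 2 or targets.shape != (len(graphs), 2):
        raise ValidationError("targets must be [n_graphs, 2]")
    schema = _common_schema(graphs)
    rng = np.random.default_rng(config.seed)
    network = QMPropertyNetwork(
        rng, graphs[0].node_features.shape[1], config.hidden_dim,
        config.n_conv_layers,
    )
    mean = targets.mean(axis=0)
    std = np.where(targets.std(axis=0) > 1e-12, targets.std(axis=0), 1.0)
    standardized = (targets - mean) / std
    optimizer = Adam(network.params(), lr=config.learning_rate)
    log = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for idx in _batches(len(graphs), config.batch_size, rng):
            batch = make_batch([graphs[i] for i in idx])
            prediction = network(batch)
            loss = (prediction - standardized[idx]).square().mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        log.append(epoch_loss / len(graphs))
    return TrainedModel(
        config=config, network=network, training_log=log,
        feature_schema=schema, target_mean=mean, target_std=std,
    )


def train_node_model(
    graphs: Sequence[Graph],
    node_targets: Sequence[np.ndarray],
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Train the per-node regressor (no graph aggregation)."""
    config = config or ModelConfig(task="node_adaptability", n_conv_layers=5)
    for graph, y in zip(graphs, node_targets):
        if len(np.asarray(y)) != graph.n_nodes:
            raise ValidationError(
                f"{graph.entry_id}: node target length mismatch"
            )
    schema = _common_schema(graphs)
    rng = np.random.default_rng(config.seed)
    network = NodeAdaptabilityNetwork(
        rng, graphs[0].node_features.shape[1], config.hidden_dim,
        config.n_conv_layers,
    )
    flat = np.concatenate([np.asarray(y, dtype=float) for y in node_targets])
    mean, std = flat.mean(), flat.std() or 1.0
    optimizer = Adam(network.params(), lr=config.learning_rate)
    log = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for idx in _batches(len(graphs), config.batch_size, rng):
            batch = make_batch([graphs[i] for i in idx])
            y = np.concatenate(
                [np.asarray(node_targets[i], dtype=float) for i in idx]
            )
            prediction = network(batch)
            loss = (prediction - ((y - mean) / std)[:, None]).square().mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        log.append(epoch_loss / len(graphs))
    return TrainedModel(
        config=config, network=network, training_log=log,
        feature_schema=schema,
        target_mean=np.array([mean]), target_std=np.array([std]),
    )


def train_pair_model(
    pairs: Sequence[PairSample],
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Train the twin relative-affinity regressor on log10-ratio labels."""
    config = config or ModelConfig(task="pair_affinity", n_conv_layers=5)
    graphs = [p.target_graph for p in pairs] + [p.base_graph for p in pairs]
    schema = _common_schema(graphs)
    labels = np.array([p.label for p in pairs])
    if not np.all(np.isfinite(labels)):
        raise ValidationError("pair labels must be finite")
    rng = np.random.default_rng(config.seed)
    network = PairAffinityNetwork(
        rng, pairs[0].target_graph.node_features.shape[1], config.hidden_dim,
        config.n_conv_layers,
    )
    optimizer = Adam(network.params(), lr=config.learning_rate)
    log = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for idx in _batches(len(pairs), config.batch_size, rng):
            target_batch = make_batch([pairs[i].target_graph for i in idx])
            base_batch = make_batch([pairs[i].base_graph for i in idx])
            prediction = network(target_batch, base_batch)
            loss = (prediction - labels[idx][:, None]).square().mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        log.append(epoch_loss / len(pairs))
    return TrainedModel(
        config=config, network=network, training_log=log, feature_schema=schema,
    )


# ---------------------------------------------------------------------------
# Inference & evaluation
# ---------------------------------------------------------------------------


def predict(
    model: TrainedModel,
    inputs: Sequence[Graph] | Sequence[PairSample],
    batch_size: int = 64,
):
    """Deterministic inference (no augmentation).

    Returns [n, 2] for the QM task, a list of per-node vectors for the node
    task, and [n] pair predictions for the affinity task.
    """
    if len(inputs) == 0:
        return np.zeros((0,))
    task = model.config.task
    if task == "pair_affinity":
        pairs = list(inputs)
        _check_schema(model, [p.target_graph for p in pairs])
        _check_schema(model, [p.base_graph for p in pairs])
        out = []
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start : start + batch_size]
            prediction = model.network(
                make_batch([p.target_graph for p in chunk]),
                make_batch([p.base_graph for p in chunk]),
            )
            out.append(prediction.data[:, 0])
        return np.concatenate(out)
    graphs = list(inputs)
    _check_schema(model, graphs)
    if task == "qm_property":
        out = []
        for start in range(0, len(graphs), batch_size):
            chunk = graphs[start : start + batch_size]
            prediction = model.network(make_batch(chunk)).data
            out.append(prediction * model.target_std + model.target_mean)
        return np.vstack(out)
    # node task: return one vector per graph
    results = []
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start : start + batch_size]
        batch = make_batch(chunk)
        values = model.network(batch).data[:, 0]
        values = values * model.target_std[0] + model.target_mean[0]
        offsets = np.cumsum([0] + [g.n_nodes for g in chunk])
        results.extend(
            values[lo:hi] for lo, hi in zip(offsets[:-1], offsets[1:])
        )
    return results


def top_k_overlap(
    predicted: np.ndarray, actual: np.ndarray, k: int = 100
) -> float:
    """|top-k(pred) ∩ top-k(true)| / k with deterministic tie-breaking
    (descending value, then ascending index)."""
    def top(values):
        values = np.asarray(values, dtype=float)
        kk = min(k, values.size)
        order = np.lexsort((np.arange(values.size), -values))
        return set(order[:kk].tolist())

    kk = min(k, np.asarray(predicted).size)
    return len(top(predicted) & top(actual)) / kk


def evaluate(
    predictions,
    targets,
    metrics: Sequence[str] = ("pearson",),
    k: int = 100,
) -> dict[str, float]:
    """Named evaluation metrics.

    ``pearson``/``spearman``/``mae`` act on flat vectors; ``top_k_overlap``
    expects per-structure vectors (lists of arrays) and averages the
    per-structure overlap of the k most flexible atoms.
    """
    out: dict[str, float] = {}
    for metric in metrics:
        if metric == "top_k_overlap":
            overlaps = [
                top_k_overlap(p, t, k) for p, t in zip(predictions, targets)
            ]
            out[metric] = float(np.mean(overlaps))
            continue
        p = np.asarray(predictions, dtype=float).reshape(-1)
        t = np.asarray(targets, dtype=float).reshape(-1)
        if metric in ("pearson", "spearman") and p.size < 2:
            raise ValidationError(f"{metric} undefined for n < 2")
        if metric == "pearson":
            out[metric] = float(stats.pearsonr(p, t)[0])
        elif metric == "spearman":
            out[metric] = float(stats.spearmanr(p, t)[0])
        elif metric == "mae":
            out[metric] = float(np.abs(p - t).mean())
        else:
            raise ValidationError(f"unknown metric {metric!r}")
    return out
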