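"""Model definition: two generalized-aggregation graph convolutional
modules, jumping-knowledge concatenation, max+mean readout, MLP head."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from synergnet.gnn.autodiff import Tensor, concat, gather, segment_max, segment_sum
from synergnet.reduce import ReducedGraph

__all__ = [
    "ModelConfig",
    "GraphBatch",
    "PredictionOutput",
    "SynerGNet",
    "build_model",
]


@dataclass(frozen=True)
class ModelConfig:
    in_dim: int = 218
    hidden_dim: int = 64
    n_conv_modules: int = 2
    conv_aggregator: str = "softmax"
    jk_mode: str = "cat"
    pool: str = "max+mean"
    head_hidden: int = 64
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if min(self.in_dim, self.hidden_dim, self.head_hidden) <= 0:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_conv_modules != 2:
            raise ValueError("the architecture fixes two convolutional modules")
        if self.n_classes != 2:
            raise ValueError("binary classifier: n_classes must be 2")
        if self.jk_mode != "cat":
            raise ValueError("only jumping-knowledge concatenation is supported")
        if self.pool != "max+mean":
            raise ValueError("only max+mean dual pooling is supported")
        if self.conv_aggregator != "softmax":
            raise ValueError("only softmax aggregation is supported")


def _edge_arrays(g: ReducedGraph) -> tuple[np.ndarray, np.ndarray]:
    """Local directed edge index arrays for a graph, cached on the graph."""
    cached = getattr(g, "_edge_index_cache", None)
    if cached is not None:
        return cached
    index = {node: i for i, node in enumerate(g.node_order)}
    src, dst = [], []
    for u, v in sorted(g.edges):
        iu, iv = index[u], index[v]
        src.extend((iu, iv))
        dst.extend((iv, iu))
    arrays = (np.asarray(src, dtype=np.intp), np.asarray(dst, dtype=np.intp))
    g._edge_index_cache = arrays
    return arrays


@dataclass
class GraphBatch:
    """A disjoint union of graphs flattened into arrays.

    ``edge_src``/``edge_dst`` hold both directions of every undirected
    edge; ``graph_index`` maps each node row to its graph.
    """

    x: np.ndarray                 # (n_nodes, in_dim)
    edge_src: np.ndarray          # (n_directed_edges,)
    edge_dst: np.ndarray          # (n_directed_edges,)
    graph_index: np.ndarray       # (n_nodes,)
    n_graphs: int
    labels: np.ndarray | None = None  # (n_graphs,) in {0, 1}

    @classmethod
    def from_graphs(
        cls,
        graphs: Sequence[ReducedGraph],
        labels: Sequence[int] | None = None,
    ) -> "GraphBatch":
        xs, srcs, dsts, gidx = [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            xs.append(g.node_features)
            src, dst = _edge_arrays(g)
            srcs.append(src + offset)
            dsts.append(dst + offset)
            gidx.append(np.full(len(g.node_order), gi, dtype=np.intp))
            offset += len(g.node_order)
        return cls(
            x=np.vstack(xs),
            edge_src=np.concatenate(srcs),
            edge_dst=np.concatenate(dsts),
            graph_index=np.concatenate(gidx),
            n_graphs=len(graphs),
            labels=None if labels is None else np.asarray(labels, dtype=np.intp),
        )


@dataclass(frozen=True)
class PredictionOutput:
    """Per-instance class probabilities and thresholded labels.

    Column 0 is the synergy probability, column 1 antagonism.
    """

    probabilities: np.ndarray  # (n, 2), rows sum to 1
    labels: np.ndarray         # (n,) 0 = synergy, 1 = antagonism

    @property
    def synergy_scores(self) -> np.ndarray:
        return self.probabilities[:, 0]


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class BatchNorm:
    """1-d batch normalization with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mean = x.mean(axis=0, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mean.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * unbiased
            )
            inv = (var + self.eps).sqrt().pow(-1.0)
            return centered * inv * self.gamma + self.beta
        norm = (x - self.running_mean) * (
            1.0 / np.sqrt(self.running_var + self.eps)
        )
        return norm * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class GENConvModule:
    """Generalized graph convolution with per-channel softmax aggregation
    (learnable inverse temperature), followed by batch norm and ReLU."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.lin_in = Linear(in_dim, out_dim, rng)
        self.lin_out = Linear(out_dim, out_dim, rng)
        self.temperature = Tensor(np.array(1.0), requires_grad=True)
        self.bn = BatchNorm(out_dim)
        self._msg_eps = 1e-7

    def __call__(self, x: Tensor, batch: GraphBatch, training: bool) -> Tensor:
        n_nodes = batch.x.shape[0]
        h = self.lin_in(x)
        if len(batch.edge_src):
            msg = gather(h, batch.edge_src).relu() + self._msg_eps
            logits = msg * self.temperature
            # per-destination max subtracted as a constant for stability
            shift = np.full((n_nodes, logits.shape[1]), -np.inf)
            np.maximum.at(shift, batch.edge_dst, logits.data)
            shift[~np.isfinite(shift)] = 0.0
            ex = (logits - shift[batch.edge_dst]).exp()
            denom = gather(
                segment_sum(ex, batch.edge_dst, n_nodes), batch.edge_dst
            )
            weights = ex / denom
            agg = segment_sum(weights * msg, batch.edge_dst, n_nodes)
            h = h + agg
        out = self.lin_out(h)
        return self.bn(out, training).relu()

    def parameters(self) -> list[Tensor]:
        return (
            self.lin_in.parameters()
            + self.lin_out.parameters()
            + [self.temperature]
            + self.bn.parameters()
        )


class SynerGNet:
    """The full graph classifier; see the module docstring."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.conv1 = GENConvModule(cfg.in_dim, cfg.hidden_dim, rng)
        self.conv2 = GENConvModule(cfg.hidden_dim, cfg.hidden_dim, rng)
        jk_width = 2 * cfg.hidden_dim          # concatenated depths
        self.readout_width = 2 * jk_width      # max + mean concatenated
        self.fc1 = Linear(self.readout_width, cfg.head_hidden, rng)
        self.bn_head = BatchNorm(cfg.head_hidden)
        self.fc2 = Linear(cfg.head_hidden, cfg.n_classes, rng)
        self.training = True
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- mode ------------------------------------------------------------
    def train_mode(self) -> None:
        self.training = True

    def eval_mode(self) -> None:
        self.training = False

    def parameters(self) -> list[Tensor]:
        return (
            self.conv1.parameters()
            + self.conv2.parameters()
            + self.fc1.parameters()
            + self.bn_head.parameters()
            + self.fc2.parameters()
        )

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- forward ---------------------------------------------------------
    def logits(self, batch: GraphBatch) -> Tensor:
        if batch.x.shape[1] != self.cfg.in_dim:
            raise ValueError(
                f"feature length {batch.x.shape[1]} != in_dim {self.cfg.in_dim}"
            )
        x = Tensor(batch.x)
        h1 = self.conv1(x, batch, self.training)
        h2 = self.conv2(h1, batch, self.training)
        jk = concat([h1, h2], axis=1)
        pooled = concat(
            [
                segment_max(jk, batch.graph_index, batch.n_graphs),
                segment_sum(jk, batch.graph_index, batch.n_graphs)
                * (1.0 / np.bincount(
                    batch.graph_index, minlength=batch.n_graphs
                ))[:, None],
            ],
            axis=1,
        )
        z = self.bn_head(self.fc1(pooled), self.training).relu()
        if self.training and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (
                self._dropout_rng.random(z.shape) < keep
            ).astype(float) / keep
            z = z * mask
        return self.fc2(z)

    def forward(self, batch: GraphBatch) -> PredictionOutput:
        """Class probabilities for a batch (uses the current mode)."""
        logits = self.logits(batch).data
        shifted = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(shifted)
        probs = ex / ex.sum(axis=1, keepdims=True)
        return PredictionOutput(
            probabilities=probs, labels=(probs[:, 0] < 0.5).astype(np.intp)
        )


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> SynerGNet:
    """Construct a model from a config (defaults applied when omitted)."""
    return SynerGNet(cfg or ModelConfig(), seed=seed)
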