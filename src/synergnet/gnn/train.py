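"""Training loop: Adam optimizer, class-weighted cross-entropy."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from synergnet.gnn.autodiff import Tensor
from synergnet.gnn.model import GraphBatch, PredictionOutput, SynerGNet
from synergnet.reduce import ReducedGraph

__all__ = ["TrainConfig", "TrainHistory", "Adam", "train", "predict",
           "save_model", "load_model"]

#: Label encoding used throughout: class 0 = synergy, class 1 = antagonism.
LABEL_TO_CLASS = {"synergy": 0, "antagonism": 1}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    class_weighting: bool = True
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainHistory:
    """Per-epoch mean training loss, plus the seed for provenance."""

    seed: int
    losses: list[float] = field(default_factory=list)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def cross_entropy(
    logits: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Mean (optionally class-weighted) cross-entropy from raw logits."""
    n = logits.shape[0]
    shift = logits.data.max(axis=1, keepdims=True)  # constant for stability
    shifted = logits - shift
    log_norm = shifted.exp().sum(axis=1, keepdims=True).log()
    log_probs = shifted - log_norm
    one_hot = np.zeros(logits.shape)
    one_hot[np.arange(n), labels] = 1.0
    if class_weights is None:
        weights = np.ones(n)
    else:
        weights = class_weights[labels]
    picked = (log_probs * one_hot).sum(axis=1) * weights
    return -picked.sum() * (1.0 / weights.sum())


def _class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights normalized to mean 1 over classes."""
    counts = np.bincount(labels, minlength=2).astype(float)
    counts[counts == 0] = 1.0
    w = len(labels) / (2.0 * counts)
    return w


def train(
    model: SynerGNet,
    graphs: Sequence[ReducedGraph],
    labels: Sequence[str],
    cfg: TrainConfig | None = None,
) -> TrainHistory:
    """Train in place on reduced graphs with string labels
    ('synergy'/'antagonism'); returns the loss history."""
    cfg = cfg or TrainConfig()
    if len(graphs) == 0:
        raise ValueError("empty training set")
    if len(graphs) != len(labels):
        raise ValueError("graphs and labels length mismatch")
    y = np.array([LABEL_TO_CLASS[lbl] for lbl in labels], dtype=np.intp)
    class_weights = _class_weights(y) if cfg.class_weighting else None

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory(seed=cfg.seed)
    model.train_mode()
    n = len(graphs)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = GraphBatch.from_graphs(
                [graphs[i] for i in idx], labels=y[idx]
            )
            model.zero_grad()
            logits = model.logits(batch)
            loss = cross_entropy(logits, y[idx], class_weights)
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        history.losses.append(float(np.mean(epoch_losses)))
    model.eval_mode()
    return history


def save_model(
    model: SynerGNet,
    path,
    train_cfg: TrainConfig | None = None,
    history: TrainHistory | None = None,
) -> None:
    """Checkpoint: parameter arrays, batch-norm running stats, and the
    full model/train config (json inside the archive)."""
    import dataclasses
    import json

    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    for name, bn in (("conv1", model.conv1.bn), ("conv2", model.conv2.bn),
                     ("head", model.bn_head)):
        arrays[f"bn_{name}_mean"] = bn.running_mean
        arrays[f"bn_{name}_var"] = bn.running_var
    meta = {
        "model_config": dataclasses.asdict(model.cfg),
        "train_config": (
            dataclasses.asdict(train_cfg) if train_cfg else None
        ),
        "losses": history.losses if history else None,
        "seed": train_cfg.seed if train_cfg else None,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> SynerGNet:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import json

    from synergnet.gnn.model import ModelConfig, SynerGNet

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta_json"]).decode())
        model = SynerGNet(ModelConfig(**meta["model_config"]))
        for i, p in enumerate(model.parameters()):
            p.data = archive[f"param_{i}"].copy()
        for name, bn in (("conv1", model.conv1.bn),
                         ("conv2", model.conv2.bn),
                         ("head", model.bn_head)):
            bn.running_mean = archive[f"bn_{name}_mean"].copy()
            bn.running_var = archive[f"bn_{name}_var"].copy()
    model.eval_mode()
    return model


def predict(
    model: SynerGNet,
    graphs: Sequence[ReducedGraph],
    batch_size: int = 64,
) -> PredictionOutput:
    """Probabilities + thresholded labels in input order (eval mode)."""
    if len(graphs) == 0:
        return PredictionOutput(
            probabilities=np.zeros((0, 2)), labels=np.zeros(0, dtype=np.intp)
        )
    was_training = model.training
    model.eval_mode()
    probs = []
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start : start + batch_size]
        probs.append(model.forward(GraphBatch.from_graphs(chunk)).probabilities)
    if was_training:
        model.train_mode()
    all_probs = np.vstack(probs)
    return PredictionOutput(
        probabilities=all_probs,
        labels=(all_probs[:, 0] < 0.5).astype(np.intp),
    )
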