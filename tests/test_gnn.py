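"""Tests for the autodiff engine and the graph classifier."""

import numpy as np
import pytest

from synergnet.gnn import (
    GraphBatch,
    ModelConfig,
    TrainConfig,
    build_model,
    predict,
    train,
)
from synergnet.gnn.autodiff import Tensor, concat, gather, segment_max, segment_sum
from synergnet.reduce import ReducedGraph


# ---------------------------------------------------------------------------
# Autodiff
# ---------------------------------------------------------------------------

def numeric_grad(fn, param, eps=1e-6):
    g = np.zeros_like(param.data)
    it = np.nditer(param.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = param.data[i]
        param.data[i] = old + eps
        hi = fn().data
        param.data[i] = old - eps
        lo = fn().data
        param.data[i] = old
        g[i] = (hi - lo) / (2 * eps)
    return g


class TestAutodiff:
    def test_gradcheck_composite(self):
        rng = np.random.default_rng(0)
        W = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=3), requires_grad=True)
        t = Tensor(np.array(0.7), requires_grad=True)
        X = np.abs(rng.normal(size=(6, 4))) + 0.1
        seg = np.array([0, 0, 1, 1, 2, 2])

        def f():
            h = Tensor(X) @ W + b
            m = gather(h, np.array([0, 1, 2, 3, 4, 5])).relu() + 1e-3
            ex = (m * t).exp()
            den = gather(segment_sum(ex, seg, 3), seg)
            agg = segment_sum((ex / den) * m, seg, 3)
            z = concat([agg, segment_max(h, seg, 3)], axis=1)
            mean = z.mean(axis=0, keepdims=True)
            var = ((z - mean) * (z - mean)).mean(axis=0, keepdims=True)
            zn = (z - mean) * (var + 1e-5).sqrt().pow(-1.0)
            return (zn * zn).sum().log()

        out = f()
        out.backward()
        for p in (W, b, t):
            num = numeric_grad(f, p)
            scale = max(1.0, np.abs(num).max())
            np.testing.assert_allclose(p.grad, num, atol=1e-5 * scale)

    def test_segment_max_empty_segment(self):
        t = Tensor(np.array([[1.0, 2.0]]))
        out = segment_max(t, np.array([0]), 3)
        assert out.data.tolist() == [[1.0, 2.0], [0.0, 0.0], [0.0, 0.0]]

    def test_broadcast_add_gradient(self):
        x = Tensor(np.ones((3, 2)), requires_grad=True)
        b = Tensor(np.zeros(2), requires_grad=True)
        (x + b).sum().backward()
        assert b.grad.tolist() == [3.0, 3.0]
        assert x.grad.shape == (3, 2)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def make_reduced(n_nodes, edges, seed=0, in_dim=218, label=None,
                 node_prefix="n"):
    from synergnet.reduce import MergePartition

    rng = np.random.default_rng(seed)
    names = [f"{node_prefix}{i:02d}" for i in range(n_nodes)]
    return ReducedGraph(
        node_order=names,
        edges={tuple(sorted((names[u], names[v]))) for u, v in edges},
        node_features=rng.normal(size=(n_nodes, in_dim)),
        partition=MergePartition(
            assignment={n: n for n in names},
            members={n: [n] for n in names},
        ),
        targets_a=frozenset(),
        targets_b=frozenset(),
        drug_a="A",
        drug_b="B",
        cell_line="c",
        label=label,
    )


class TestModelConfig:
    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=0)

    def test_fixed_module_count(self):
        with pytest.raises(ValueError):
            ModelConfig(n_conv_modules=3)


class TestForward:
    def test_probabilities_sum_to_one(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8), seed=0)
        model.eval_mode()
        g = make_reduced(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        out = model.forward(GraphBatch.from_graphs([g]))
        assert out.probabilities.shape == (1, 2)
        assert out.probabilities.sum() == pytest.approx(1.0)
        assert np.all(out.probabilities >= 0)

    def test_readout_width_doubles_jk_width(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8))
        assert model.readout_width == 2 * (2 * 8)

    def test_parameter_count_hand_tally(self):
        cfg = ModelConfig(in_dim=218, hidden_dim=8, head_hidden=4)
        model = build_model(cfg)
        conv1 = (218 * 8 + 8) + (8 * 8 + 8) + 1 + 2 * 8
        conv2 = (8 * 8 + 8) + (8 * 8 + 8) + 1 + 2 * 8
        readout = 2 * (2 * 8)
        head = (readout * 4 + 4) + 2 * 4 + (4 * 2 + 2)
        assert model.parameter_count() == conv1 + conv2 + head

    def test_permutation_invariance(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8), seed=1)
        model.eval_mode()
        g = make_reduced(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)],
                         seed=3)
        out1 = model.forward(GraphBatch.from_graphs([g]))
        # same graph, different node storage order
        perm = [3, 1, 4, 0, 5, 2]
        g2 = ReducedGraph(
            node_order=[g.node_order[i] for i in perm],
            edges=g.edges,
            node_features=g.node_features[perm],
            partition=g.partition,
            targets_a=g.targets_a, targets_b=g.targets_b,
            drug_a=g.drug_a, drug_b=g.drug_b, cell_line=g.cell_line,
        )
        out2 = model.forward(GraphBatch.from_graphs([g2]))
        np.testing.assert_allclose(
            out1.probabilities, out2.probabilities, atol=1e-8
        )

    def test_batch_of_n_graphs(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8))
        model.eval_mode()
        graphs = [make_reduced(4 + i, [(0, 1), (1, 2)], seed=i)
                  for i in range(5)]
        out = model.forward(GraphBatch.from_graphs(graphs))
        assert out.probabilities.shape == (5, 2)
        np.testing.assert_allclose(out.probabilities.sum(axis=1), 1.0)

    def test_single_node_graph(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8))
        model.eval_mode()
        out = model.forward(GraphBatch.from_graphs([make_reduced(1, [])]))
        assert out.probabilities.shape == (1, 2)
        assert np.isfinite(out.probabilities).all()

    def test_feature_length_mismatch_rejected(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8))
        g = make_reduced(3, [(0, 1)], in_dim=10)
        with pytest.raises(ValueError, match="in_dim"):
            model.forward(GraphBatch.from_graphs([g]))


def planted_graphs(n, seed=0):
    """Tiny binary task: label depends on the mean of feature 0."""
    rng = np.random.default_rng(seed)
    graphs, labels = [], []
    for i in range(n):
        label = "synergy" if i % 2 == 0 else "antagonism"
        g = make_reduced(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)],
                         seed=seed * 1000 + i)
        shiftf = 2.0 if label == "synergy" else -2.0
        g.node_features[:, 0] += shiftf
        graphs.append(g)
        labels.append(label)
    return graphs, labels


class TestTrain:
    def test_loss_decreases(self):
        graphs, labels = planted_graphs(30)
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8), seed=0)
        hist = train(model, graphs, labels,
                     TrainConfig(epochs=15, seed=0, batch_size=10))
        assert hist.losses[-1] < hist.losses[0]

    def test_seed_reproducibility(self):
        graphs, labels = planted_graphs(20)
        outs = []
        for _ in range(2):
            model = build_model(
                ModelConfig(hidden_dim=8, head_hidden=8), seed=5
            )
            hist = train(model, graphs, labels,
                         TrainConfig(epochs=5, seed=5, batch_size=10))
            outs.append((hist.losses, predict(model, graphs).probabilities))
        assert outs[0][0] == outs[1][0]
        np.testing.assert_array_equal(outs[0][1], outs[1][1])

    def test_empty_training_set_rejected(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8))
        with pytest.raises(ValueError, match="empty"):
            train(model, [], [], TrainConfig(epochs=1))

    def test_learns_separable_signal(self):
        graphs, labels = planted_graphs(40, seed=2)
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8), seed=0)
        train(model, graphs, labels,
              TrainConfig(epochs=30, seed=0, batch_size=10))
        out = predict(model, graphs)
        y = np.array([0 if l == "synergy" else 1 for l in labels])
        acc = np.mean(out.labels == y)
        assert acc >= 0.9


class TestPredict:
    def test_empty_input(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8))
        out = predict(model, [])
        assert out.probabilities.shape == (0, 2)
        assert out.labels.shape == (0,)

    def test_matches_forward(self):
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8), seed=2)
        model.eval_mode()
        graphs = [make_reduced(5, [(0, 1), (2, 3)], seed=i) for i in range(3)]
        out1 = predict(model, graphs)
        out2 = model.forward(GraphBatch.from_graphs(graphs))
        np.testing.assert_allclose(
            out1.probabilities, out2.probabilities, atol=1e-12
        )

    def test_checkpoint_round_trip(self, tmp_path):
        from synergnet.gnn import load_model, save_model

        graphs, labels = planted_graphs(20)
        model = build_model(ModelConfig(hidden_dim=8, head_hidden=8), seed=4)
        cfg = TrainConfig(epochs=3, seed=4, batch_size=10)
        history = train(model, graphs, labels, cfg)
        path = tmp_path / "model.npz"
        save_model(model, path, train_cfg=cfg, history=history)
        restored = load_model(path)
        np.testing.assert_array_equal(
            predict(model, graphs).probabilities,
            predict(restored, graphs).probabilities,
        )

    def test_untrained_model_reproducible(self):
        g = [make_reduced(4, [(0, 1)], seed=9)]
        p1 = predict(build_model(
            ModelConfig(hidden_dim=8, head_hidden=8), seed=3), g)
        p2 = predict(build_model(
            ModelConfig(hidden_dim=8, head_hidden=8), seed=3), g)
        np.testing.assert_array_equal(p1.probabilities, p2.probabilities)
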