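"""Shared fixtures: toy graphs and small synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest

from synergnet.features import (
    CellLineProfile,
    DrugRecord,
    GOEmbeddingTable,
    build_featured_graph,
)
from synergnet.graphio import PPINetwork
from synergnet.synthdata import SynthConfig, make_dataset


def make_network(druggable: dict[str, bool], edges) -> PPINetwork:
    from synergnet.graphio import canonical_edge

    return PPINetwork(
        druggable=druggable,
        edges={canonical_edge(u, v) for u, v in edges},
    )


@pytest.fixture
def toy_featured_graph():
    """A 9-node toy instance with one target node.

    Druggable: b, c, g, h; non-druggable: a, d, e, f, i.  Expression:
    a=0, b=0, c=0, d=e=+1, f=i=0, g=h=-1.  Drug X targets c.  Under the
    pruning rules the persisting edges are exactly d-e, f-i, g-h, so
    contraction yields the partition {a},{b},{c},{d,e},{f,i},{g,h}.
    """
    ppi = make_network(
        druggable={
            "a": False, "b": True, "c": True, "d": False, "e": False,
            "f": False, "g": True, "h": True, "i": False,
        },
        edges=[
            ("a", "b"), ("a", "d"), ("b", "c"), ("b", "g"), ("c", "d"),
            ("c", "g"), ("d", "e"), ("e", "f"), ("f", "i"), ("g", "h"),
            ("h", "i"),
        ],
    )
    profile = CellLineProfile(
        cell_line_id="toy-cell",
        expression={"d": 1, "e": 1, "g": -1, "h": -1},
    )
    drug_x = DrugRecord(drug_id="X", associations={"c": 500.0})
    drug_y = DrugRecord(drug_id="Y", associations={})
    go_table = GOEmbeddingTable({})
    return build_featured_graph(
        ppi, profile, drug_x, drug_y, go_table, label="synergy"
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small deterministic bundle shared across tests (seed pinned).

    High substitution fidelity (target retention 0.95, at most one extra
    target) keeps transferred labels consistent with the planted rule, so
    augmented training data carries signal rather than noise.
    """
    return make_dataset(
        SynthConfig(seed=3, n_pairs=150, n_drugs=18, n_cell_lines=5,
                    family_target_keep=0.95, extra_targets_max=1)
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The default-config bundle at the pinned seed (larger; built once)."""
    return make_dataset(SynthConfig(seed=1))


def random_featured_graph(n_nodes: int, edge_prob: float, seed: int):
    """A random featured graph for reduction property tests."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, edge_prob, seed=seed)
    names = [f"n{i:03d}" for i in range(n_nodes)]
    druggable = {names[i]: bool(rng.random() < 0.6) for i in range(n_nodes)}
    ppi = make_network(
        druggable, [(names[u], names[v]) for u, v in g.edges()]
    )
    expression = {
        names[i]: int(rng.integers(-1, 2)) for i in range(n_nodes)
    }
    profile = CellLineProfile(cell_line_id="rand-cell", expression=expression)
    druggable_nodes = [n for n, f in druggable.items() if f]
    targets_a = rng.choice(
        druggable_nodes, size=min(2, len(druggable_nodes)), replace=False
    ) if druggable_nodes else []
    drug_a = DrugRecord(
        drug_id="A", associations={str(t): 600.0 for t in targets_a}
    )
    drug_b = DrugRecord(drug_id="B", associations={})
    return build_featured_graph(
        ppi, profile, drug_a, drug_b, GOEmbeddingTable({}), label="synergy"
    )
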