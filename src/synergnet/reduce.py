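"""Knowledge-based graph reduction through constrained edge contraction.

Nodes that are similar in both their potential drug interaction and their
activity level are merged.  The procedure:

1. *Prune* — remove every edge that joins a druggable node to a
   non-druggable node, every edge incident to a target node of either
   instance drug, and every edge whose endpoints have different expression
   values.  Only edges joining same-class, same-expression, non-target
   nodes persist.
2. *Contract* — the connected components of the persisting-edge subgraph
   become super-nodes (component closure is the canonical, order-
   independent result of contracting every persisting edge).
3. *Merge features* — member features are combined per block (shared
   expression; element-wise max for CNV/mutation indicators and the
   association score; element-wise mean for the GO embedding, by default).
4. *Restore* — every removed edge is put back as an edge between the
   super-nodes of its endpoints (quotient graph; self-loops dropped,
   parallel edges collapsed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np

from synergnet.features import (
    ASSOCIATION_INDEX,
    CNV_SLICE,
    EXPRESSION_SLICE,
    GO_SLICE,
    MUTATION_SLICE,
    N_FEATURES,
    FeaturedGraph,
)

__all__ = [
    "MergePartition",
    "ReducedGraph",
    "MergePolicy",
    "prune_edges",
    "contract",
    "merge_features",
    "restore_edges",
    "reduce_graph",
]


@dataclass
class MergePartition:
    """Partition of original nodes into super-nodes.

    Each super-node is identified by the lexicographically smallest member
    node.  ``assignment`` maps every original node to its super-node id;
    ``members`` maps each super-node id to its (sorted) member list.
    """

    assignment: dict[str, str]
    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        covered = [m for ms in self.members.values() for m in ms]
        if len(covered) != len(set(covered)):
            raise ValueError("a node appears in more than one super-node")
        if set(covered) != set(self.assignment):
            raise ValueError("assignment and member sets disagree")
        for sid, ms in self.members.items():
            if sid != min(ms):
                raise ValueError(
                    f"super-node id {sid!r} is not the minimum member"
                )

    @property
    def n_super_nodes(self) -> int:
        return len(self.members)

    def member_sets(self) -> set[frozenset[str]]:
        return {frozenset(ms) for ms in self.members.values()}


@dataclass
class ReducedGraph:
    """Quotient graph after edge contraction, with merged node features."""

    node_order: list[str]
    edges: set[tuple[str, str]]
    node_features: np.ndarray
    partition: MergePartition
    targets_a: frozenset[str]
    targets_b: frozenset[str]
    drug_a: str
    drug_b: str
    cell_line: str
    label: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_order)
        g.add_edges_from(self.edges)
        return g


@dataclass
class MergePolicy:
    """Per-block feature combination rules for merged nodes.

    Defaults: CNV and mutation indicator blocks take the element-wise max
    (union of alterations), the association score takes the max, and the
    GO block takes the element-wise mean.  Expression is the members'
    shared value by construction.
    """

    indicator_reduce: Callable[[np.ndarray], np.ndarray] = field(
        default=lambda block: block.max(axis=0)
    )
    association_reduce: Callable[[np.ndarray], float] = field(
        default=lambda col: float(col.max())
    )
    go_reduce: Callable[[np.ndarray], np.ndarray] = field(
        default=lambda block: block.mean(axis=0)
    )


def prune_edges(g: FeaturedGraph) -> set[tuple[str, str]]:
    """Return the persisting edges: endpoints share druggability class,
    neither endpoint is a target of either instance drug, and both have
    equal expression values."""
    druggable = g.topology.druggable
    targets = g.target_nodes
    index = {node: i for i, node in enumerate(g.node_order)}
    expr = g.node_features[:, 0]
    persisting = set()
    for u, v in g.topology.edges:
        if u in targets or v in targets:
            continue
        if druggable[u] != druggable[v]:
            continue
        if expr[index[u]] != expr[index[v]]:
            continue
        persisting.add((u, v))
    return persisting


def contract(
    g: FeaturedGraph, persisting_edges: set[tuple[str, str]]
) -> MergePartition:
    """Contract all persisting edges at once: super-nodes are the
    connected components of the persisting-edge subgraph (nodes untouched
    by any persisting edge stay singletons)."""
    unknown = persisting_edges - g.topology.edges
    if unknown:
        raise ValueError(f"persisting edges not in graph: {sorted(unknown)[:5]}")
    sub = nx.Graph()
    sub.add_nodes_from(g.node_order)
    sub.add_edges_from(persisting_edges)
    assignment: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for component in nx.connected_components(sub):
        sid = min(component)
        members[sid] = sorted(component)
        for node in component:
            assignment[node] = sid
    return MergePartition(assignment=assignment, members=members)


def merge_features(
    partition: MergePartition,
    g: FeaturedGraph,
    policy: MergePolicy | None = None,
) -> tuple[list[str], np.ndarray]:
    """Combine member feature vectors per super-node.

    Returns the sorted super-node order and the merged feature matrix.
    Raises if a super-node mixes expression values (partition invariant).
    """
    policy = policy or MergePolicy()
    index = {node: i for i, node in enumerate(g.node_order)}
    order = sorted(partition.members)
    merged = np.zeros((len(order), N_FEATURES))
    for row, sid in enumerate(order):
        rows = g.node_features[[index[m] for m in partition.members[sid]]]
        expr_values = np.unique(rows[:, 0])
        if len(expr_values) != 1:
            raise RuntimeError(
                f"super-node {sid!r} mixes expression values {expr_values}"
            )
        merged[row, EXPRESSION_SLICE] = expr_values[0]
        merged[row, CNV_SLICE] = policy.indicator_reduce(rows[:, CNV_SLICE])
        merged[row, MUTATION_SLICE] = policy.indicator_reduce(
            rows[:, MUTATION_SLICE]
        )
        merged[row, ASSOCIATION_INDEX] = policy.association_reduce(
            rows[:, ASSOCIATION_INDEX]
        )
        merged[row, GO_SLICE] = policy.go_reduce(rows[:, GO_SLICE])
    return order, merged


def restore_edges(
    partition: MergePartition, g: FeaturedGraph
) -> set[tuple[str, str]]:
    """Map every original edge to super-node space: quotient edges with
    self-loops dropped and parallel edges collapsed."""
    edges: set[tuple[str, str]] = set()
    assign = partition.assignment
    for u, v in g.topology.edges:
        su, sv = assign[u], assign[v]
        if su == sv:
            continue
        edges.add((su, sv) if su <= sv else (sv, su))
    return edges


def reduce_graph(
    g: FeaturedGraph, policy: MergePolicy | None = None
) -> ReducedGraph:
    """Full reduction: prune -> contract -> merge features -> restore."""
    persisting = prune_edges(g)
    partition = contract(g, persisting)
    order, merged = merge_features(partition, g, policy)
    edges = restore_edges(partition, g)
    assign = partition.assignment
    return ReducedGraph(
        node_order=order,
        edges=edges,
        node_features=merged,
        partition=partition,
        targets_a=frozenset(assign[t] for t in g.targets_a),
        targets_b=frozenset(assign[t] for t in g.targets_b),
        drug_a=g.drug_a,
        drug_b=g.drug_b,
        cell_line=g.cell_line,
        label=g.label,
    )
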