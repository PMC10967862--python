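"""Protein–protein interaction network I/O and graph statistics.

The network is an undirected simple graph: edges are stored once in
canonical (lexicographically sorted) order, self-loops are forbidden, and
every edge endpoint must be a declared node.  Each node carries a boolean
druggability flag and each edge optionally carries a confidence score in
[0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "PPINetwork",
    "GraphStats",
    "NetworkParseError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "avg_degree",
    "density",
    "diameter",
    "graph_stats",
]


class NetworkParseError(ValueError):
    """A row of an edge-list or node-table file could not be parsed."""


class NetworkValidationError(ValueError):
    """The parsed network violates a structural invariant."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the edge (u, v) with endpoints in lexicographic order."""
    return (u, v) if u <= v else (v, u)


@dataclass
class PPINetwork:
    """Undirected druggability-annotated protein graph.

    Parameters
    ----------
    druggable
        Mapping of every node to its druggability flag; the key set *is*
        the node set.
    edges
        Canonicalized, deduplicated unordered pairs of node identifiers.
    confidence
        Optional per-edge confidence score in [0, 1], keyed by canonical
        edge.
    """

    druggable: dict[str, bool]
    edges: set[tuple[str, str]]
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise NetworkValidationError(f"self-loop on node {u!r}")
            if (u, v) != canonical_edge(u, v):
                raise NetworkValidationError(
                    f"edge {(u, v)!r} not in canonical order"
                )
            for endpoint in (u, v):
                if endpoint not in self.druggable:
                    raise NetworkValidationError(
                        f"edge endpoint {endpoint!r} is not a declared node"
                    )
        for edge, score in self.confidence.items():
            if not 0.0 <= score <= 1.0:
                raise NetworkValidationError(
                    f"confidence {score} for edge {edge!r} outside [0, 1]"
                )

    # -- views ----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.druggable)

    @property
    def n_nodes(self) -> int:
        return len(self.druggable)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for u, v in self.edges if node in (u, v))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(
            (n, {"druggable": flag}) for n, flag in self.druggable.items()
        )
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class GraphStats:
    """Summary statistics of a :class:`PPINetwork` or reduced graph."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    diameter: int
    druggable_ratio: float


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_network(
    edge_path: str | Path,
    node_path: str | Path,
    min_confidence: float = 0.0,
    on_self_loop: str = "drop",
) -> PPINetwork:
    """Read a network from an edge-list TSV plus a node-annotation TSV.

    The edge list has one edge per row, ``protein_a<TAB>protein_b`` with an
    optional third confidence column; the node table is
    ``protein<TAB>druggable{0,1}``.  Edges below ``min_confidence`` are
    dropped; duplicates are merged (keeping the maximum confidence).

    Parameters
    ----------
    on_self_loop
        ``"drop"`` removes self-loop rows with a warning; ``"error"``
        raises :class:`NetworkValidationError`.
    """
    if on_self_loop not in ("drop", "error"):
        raise ValueError("on_self_loop must be 'drop' or 'error'")

    druggable: dict[str, bool] = {}
    for lineno, row in _tsv_rows(node_path):
        if len(row) != 2 or row[1] not in ("0", "1"):
            raise NetworkParseError(
                f"{node_path}:{lineno}: expected 'protein<TAB>druggable{{0,1}}', "
                f"got {row!r}"
            )
        druggable[row[0]] = row[1] == "1"

    edges: set[tuple[str, str]] = set()
    confidence: dict[tuple[str, str], float] = {}
    for lineno, row in _tsv_rows(edge_path):
        if len(row) not in (2, 3):
            raise NetworkParseError(
                f"{edge_path}:{lineno}: expected 2 or 3 columns, got {len(row)}"
            )
        u, v = row[0], row[1]
        score: float | None = None
        if len(row) == 3:
            try:
                score = float(row[2])
            except ValueError as exc:
                raise NetworkParseError(
                    f"{edge_path}:{lineno}: bad confidence {row[2]!r}"
                ) from exc
        if u == v:
            if on_self_loop == "error":
                raise NetworkValidationError(
                    f"{edge_path}:{lineno}: self-loop on {u!r}"
                )
            warnings.warn(f"dropping self-loop on {u!r} (line {lineno})")
            continue
        for endpoint in (u, v):
            if endpoint not in druggable:
                raise NetworkValidationError(
                    f"{edge_path}:{lineno}: edge references unannotated "
                    f"node {endpoint!r}"
                )
        if score is not None and score < min_confidence:
            continue
        edge = canonical_edge(u, v)
        edges.add(edge)
        if score is not None:
            confidence[edge] = max(score, confidence.get(edge, score))

    return PPINetwork(druggable=druggable, edges=edges, confidence=confidence)


def write_network(
    g: PPINetwork, edge_path: str | Path, node_path: str | Path
) -> None:
    """Serialize a network to the edge-list + node-table TSV pair."""
    with open(node_path, "w") as fh:
        for node in sorted(g.druggable):
            fh.write(f"{node}\t{int(g.druggable[node])}\n")
    with open(edge_path, "w") as fh:
        for u, v in sorted(g.edges):
            if (u, v) in g.confidence:
                fh.write(f"{u}\t{v}\t{g.confidence[(u, v)]:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def _tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# Graph statistics
# ---------------------------------------------------------------------------

def _counts(
    g_or_v: PPINetwork | int, n_edges: int | None
) -> tuple[int, int]:
    if isinstance(g_or_v, PPINetwork):
        return g_or_v.n_nodes, g_or_v.n_edges
    if n_edges is None:
        raise TypeError("n_edges required when passing raw counts")
    return int(g_or_v), int(n_edges)


def avg_degree(g: PPINetwork | int, n_edges: int | None = None) -> float:
    """Average number of connections per node, 2E/V.

    Accepts either a :class:`PPINetwork` or raw ``(n_nodes, n_edges)``
    counts.
    """
    v, e = _counts(g, n_edges)
    if v <= 0:
        raise ValueError("average degree undefined for an empty graph")
    return 2.0 * e / v


def density(g: PPINetwork | int, n_edges: int | None = None) -> float:
    """Edge count over the maximum possible for a simple undirected graph,
    2E / (V(V-1)).  Accepts a network or raw counts."""
    v, e = _counts(g, n_edges)
    if v < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return 2.0 * e / (v * (v - 1))


def diameter(g: PPINetwork | nx.Graph) -> int:
    """Maximum shortest-path length between any two nodes.

    Disconnected graphs are handled by computing the diameter of the
    largest connected component (the count of components is logged via a
    warning).  An edgeless graph returns 0 with a warning.
    """
    nxg = g.to_networkx() if isinstance(g, PPINetwork) else g
    if nxg.number_of_nodes() == 0:
        raise ValueError("diameter undefined for an empty graph")
    if nxg.number_of_edges() == 0:
        warnings.warn("edgeless graph: diameter reported as 0")
        return 0
    components = list(nx.connected_components(nxg))
    if len(components) > 1:
        warnings.warn(
            f"graph has {len(components)} connected components; diameter "
            "computed on the largest"
        )
    largest = max(components, key=len)
    return nx.diameter(nxg.subgraph(largest))


def graph_stats(g: PPINetwork) -> GraphStats:
    """Populate a :class:`GraphStats` record for a network."""
    n_druggable = sum(g.druggable.values())
    n_non = g.n_nodes - n_druggable
    ratio = n_druggable / n_non if n_non else float("inf")
    return GraphStats(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        avg_degree=avg_degree(g),
        density=density(g),
        diameter=diameter(g),
        druggable_ratio=ratio,
    )


def stats_from_counts(
    n_nodes: int, n_edges: int, diameter_value: int = 0,
    druggable_ratio: float = float("nan"),
) -> GraphStats:
    """Analytic statistics record from known node/edge counts alone."""
    return GraphStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        avg_degree=avg_degree(n_nodes, n_edges),
        density=density(n_nodes, n_edges),
        diameter=diameter_value,
        druggable_ratio=druggable_ratio,
    )
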