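"""Per-node feature assembly for (drug pair, cell line) instances.

Every node of the interaction network receives a 218-dimensional vector
with a fixed block layout::

    [ expression (1) | CNV one-hot (3) | mutation indicators (13) |
      association score (1) | GO embedding (200) ]

Expression is trinary (-1/0/+1), CNV is one of wild-type / amplification /
deletion, mutations are binary indicators over thirteen fixed types, the
association score is the stronger of the two drugs' association scores for
that protein (min-max rescaled from [150, 999] to [0, 1] by default), and
the GO block is a precomputed 200-dimensional functional embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from synergnet.graphio import PPINetwork

__all__ = [
    "EXPRESSION_SLICE",
    "CNV_SLICE",
    "MUTATION_SLICE",
    "ASSOCIATION_INDEX",
    "GO_SLICE",
    "N_FEATURES",
    "GO_DIM",
    "CNV_CATEGORIES",
    "MUTATION_TYPES",
    "SCORE_MIN",
    "SCORE_MAX",
    "CellLineProfile",
    "DrugRecord",
    "GOEmbeddingTable",
    "FeaturedGraph",
    "encode_expression",
    "encode_cnv",
    "encode_mutations",
    "embed_go",
    "node_association",
    "build_featured_graph",
]

GO_DIM = 200

#: Fixed block layout of the 218-dimensional node feature vector.
EXPRESSION_SLICE = slice(0, 1)
CNV_SLICE = slice(1, 4)
MUTATION_SLICE = slice(4, 17)
ASSOCIATION_INDEX = 17
GO_SLICE = slice(18, 18 + GO_DIM)
N_FEATURES = 18 + GO_DIM

CNV_CATEGORIES = ("wild-type", "amplification", "deletion")

#: The thirteen recognized mutation types, in fixed order.
MUTATION_TYPES = (
    "complex compound substitution",
    "complex in-frame deletion",
    "complex frameshift",
    "complex in-frame insertion",
    "frameshift deletion",
    "in-frame deletion",
    "frameshift insertion",
    "in-frame insertion",
    "nonstop extension",
    "silent coding substitution",
    "missense substitution",
    "nonsense substitution",
    "unknown",
)
_MUTATION_INDEX = {name: i for i, name in enumerate(MUTATION_TYPES)}

#: Drug–protein association confidence score bounds (STITCH-style).
SCORE_MIN = 150.0
SCORE_MAX = 999.0


# ---------------------------------------------------------------------------
# Input tables
# ---------------------------------------------------------------------------

@dataclass
class CellLineProfile:
    """Trinary expression, CNV category, and mutation-type sets per gene.

    Genes absent from a map default to the neutral category: expression 0,
    CNV wild-type, no mutations.
    """

    cell_line_id: str
    expression: dict[str, int] = field(default_factory=dict)
    cnv: dict[str, str] = field(default_factory=dict)
    mutations: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.expression.items():
            if value not in (-1, 0, 1):
                raise ValueError(
                    f"expression for {gene!r} must be -1, 0 or +1, got {value!r}"
                )
        for gene, cat in self.cnv.items():
            if cat not in CNV_CATEGORIES:
                raise ValueError(f"unknown CNV category {cat!r} for {gene!r}")
        for gene, types in self.mutations.items():
            unknown = set(types) - set(MUTATION_TYPES)
            if unknown:
                raise ValueError(
                    f"unknown mutation type(s) {sorted(unknown)} for {gene!r}"
                )


@dataclass
class DrugRecord:
    """A drug: identifier, optional SMILES, and per-protein association
    scores in [150, 999]."""

    drug_id: str
    smiles: str | None = None
    associations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for protein, score in self.associations.items():
            if not SCORE_MIN <= score <= SCORE_MAX:
                raise ValueError(
                    f"association score {score} for ({self.drug_id!r}, "
                    f"{protein!r}) outside [{SCORE_MIN:g}, {SCORE_MAX:g}]"
                )

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self.associations)


class GOEmbeddingTable:
    """gene -> 200-dimensional embedding; missing genes map to zeros."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        self._vectors: dict[str, np.ndarray] = {}
        for gene, vec in vectors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (GO_DIM,):
                raise ValueError(
                    f"embedding for {gene!r} has shape {vec.shape}, "
                    f"expected ({GO_DIM},)"
                )
            self._vectors[gene] = vec

    def __contains__(self, gene: str) -> bool:
        return gene in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def get(self, gene: str) -> np.ndarray:
        return self._vectors.get(gene, np.zeros(GO_DIM)).copy()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GOEmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != GO_DIM + 1:
                    raise ValueError(
                        f"{path}:{lineno}: expected gene + {GO_DIM} values, "
                        f"got {len(parts)} columns"
                    )
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        return cls(vectors)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self._vectors):
                vals = "\t".join(f"{x:.6g}" for x in self._vectors[gene])
                fh.write(f"{gene}\t{vals}\n")


# ---------------------------------------------------------------------------
# Block encoders
# ---------------------------------------------------------------------------

def encode_expression(value: int) -> np.ndarray:
    if value not in (-1, 0, 1):
        raise ValueError(f"expression must be -1, 0 or +1, got {value!r}")
    return np.array([float(value)])


def encode_cnv(category: str) -> np.ndarray:
    """One-hot encode a CNV category in (wild-type, amplification,
    deletion) order."""
    if category not in CNV_CATEGORIES:
        raise ValueError(f"unknown CNV category {category!r}")
    vec = np.zeros(len(CNV_CATEGORIES))
    vec[CNV_CATEGORIES.index(category)] = 1.0
    return vec


def encode_mutations(types: frozenset[str] | set[str]) -> np.ndarray:
    """Binary indicator vector over the 13 mutation types."""
    vec = np.zeros(len(MUTATION_TYPES))
    for t in types:
        if t not in _MUTATION_INDEX:
            raise ValueError(f"unknown mutation type {t!r}")
        vec[_MUTATION_INDEX[t]] = 1.0
    return vec


def embed_go(gene: str, table: GOEmbeddingTable) -> np.ndarray:
    """The gene's (precomputed summation) GO embedding; zeros if absent."""
    return table.get(gene)


def rescale_score(score: float) -> float:
    """Min-max rescale an association score from [150, 999] to [0, 1]."""
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(f"score {score} outside [{SCORE_MIN:g}, {SCORE_MAX:g}]")
    return (score - SCORE_MIN) / (SCORE_MAX - SCORE_MIN)


def node_association(
    protein: str,
    drug_a: DrugRecord,
    drug_b: DrugRecord,
    rescale: bool = True,
) -> float:
    """Combined association value for a protein under a drug pair.

    The stronger of the two drugs' scores is kept (symmetric in drug
    order); 0 when neither drug associates with the protein.  With
    ``rescale`` (default) scores are mapped to [0, 1] by
    ``(s - 150) / 849``.
    """
    scores = [
        rec.associations[protein]
        for rec in (drug_a, drug_b)
        if protein in rec.associations
    ]
    if not scores:
        return 0.0
    best = max(scores)
    return rescale_score(best) if rescale else best


# ---------------------------------------------------------------------------
# Featured graph
# ---------------------------------------------------------------------------

@dataclass
class FeaturedGraph:
    """Network topology plus per-node 218-dim features for one instance.

    ``node_order`` fixes the row order of ``node_features``; ``targets_a``
    and ``targets_b`` are the proteins with a recorded association for each
    drug (the sets may intersect).
    """

    topology: PPINetwork
    node_order: list[str]
    node_features: np.ndarray
    targets_a: frozenset[str]
    targets_b: frozenset[str]
    drug_a: str
    drug_b: str
    cell_line: str
    label: str | None = None

    def __post_init__(self) -> None:
        n = len(self.node_order)
        if self.node_features.shape != (n, N_FEATURES):
            raise ValueError(
                f"feature matrix shape {self.node_features.shape} != "
                f"({n}, {N_FEATURES})"
            )
        if set(self.node_order) != set(self.topology.druggable):
            raise ValueError("node_order does not match topology node set")

    @property
    def target_nodes(self) -> frozenset[str]:
        """Targets of either drug in this instance."""
        return self.targets_a | self.targets_b

    def feature_of(self, node: str) -> np.ndarray:
        return self.node_features[self.node_order.index(node)]

    def expression_of(self, node: str) -> float:
        return float(self.feature_of(node)[0])


def build_featured_graph(
    ppi: PPINetwork,
    profile: CellLineProfile,
    drug_a: DrugRecord,
    drug_b: DrugRecord,
    go_table: GOEmbeddingTable,
    label: str | None = None,
    rescale_associations: bool = True,
) -> FeaturedGraph:
    """Assemble the featured graph for one (drug pair, cell line) instance.

    Every node receives a 218-vector in the fixed block order; two
    instances on the same cell line share everything but the association
    block.
    """
    if drug_a.drug_id == drug_b.drug_id:
        raise ValueError("the two drugs of an instance must be distinct")
    node_order = sorted(ppi.druggable)
    features = np.zeros((len(node_order), N_FEATURES))
    for i, node in enumerate(node_order):
        features[i, EXPRESSION_SLICE] = encode_expression(
            profile.expression.get(node, 0)
        )
        features[i, CNV_SLICE] = encode_cnv(profile.cnv.get(node, "wild-type"))
        features[i, MUTATION_SLICE] = encode_mutations(
            profile.mutations.get(node, frozenset())
        )
        features[i, ASSOCIATION_INDEX] = node_association(
            node, drug_a, drug_b, rescale=rescale_associations
        )
        features[i, GO_SLICE] = embed_go(node, go_table)
    node_set = set(node_order)
    return FeaturedGraph(
        topology=ppi,
        node_order=node_order,
        node_features=features,
        targets_a=drug_a.targets & node_set,
        targets_b=drug_b.targets & node_set,
        drug_a=drug_a.drug_id,
        drug_b=drug_b.drug_id,
        cell_line=profile.cell_line_id,
        label=label,
    )
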