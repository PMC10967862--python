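"""Graph vectorization + random-forest baseline.

A graph is turned into a fixed-length vector by (1) sorting nodes by
descending degree (ties by node id), (2) standardizing node features with
training-set statistics, (3) projecting to 32 principal components fitted
on training-set node features, (4) flattening row-major in sorted order,
and (5) padding with zeros / truncating to a configured node count.  The
flattened vectors feed a random-forest classifier.

The standardizer and the PCA are fitted on training graphs only; a strict
guard raises if a forbidden (held-out) instance leaks into fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from synergnet.reduce import ReducedGraph

__all__ = [
    "N_COMPONENTS",
    "StandardizerParams",
    "LeakageError",
    "sort_nodes",
    "fit_standardizer",
    "standardize",
    "fit_pca",
    "vectorize_graph",
    "flat_vector_length",
    "BaselineVectorizer",
    "train_rf",
    "predict_rf",
]

#: Number of principal components retained for the baseline.
N_COMPONENTS = 32


class LeakageError(RuntimeError):
    """A fitting call touched graphs reserved for evaluation."""


@dataclass(frozen=True)
class StandardizerParams:
    """Per-feature mean and standard deviation fitted on training data.

    Zero-variance features get a standard deviation of 1 so they collapse
    to 0 after centering instead of dividing by zero.
    """

    mean: np.ndarray
    std: np.ndarray


def sort_nodes(g: ReducedGraph) -> list[str]:
    """Node ids sorted by descending degree, ties broken by id ascending."""
    if not g.node_order:
        raise ValueError("graph has no nodes")
    degree = {n: 0 for n in g.node_order}
    for u, v in g.edges:
        degree[u] += 1
        degree[v] += 1
    return sorted(g.node_order, key=lambda n: (-degree[n], n))


def fit_standardizer(node_features: np.ndarray) -> StandardizerParams:
    mean = node_features.mean(axis=0)
    std = node_features.std(axis=0)
    std = np.where(std == 0.0, 1.0, std)
    return StandardizerParams(mean=mean, std=std)


def standardize(x: np.ndarray, params: StandardizerParams) -> np.ndarray:
    """x_hat = (x - mean) / std, elementwise."""
    return (np.asarray(x, dtype=float) - params.mean) / params.std


def fit_pca(node_features: np.ndarray, n_components: int = N_COMPONENTS) -> PCA:
    """Top-``n_components`` principal components of (standardized)
    training node features."""
    if np.linalg.matrix_rank(node_features - node_features.mean(axis=0)) < (
        n_components
    ):
        raise ValueError(
            f"feature matrix rank below {n_components}; request fewer "
            "components or supply more data"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(node_features)
    return pca


def flat_vector_length(n_fix: int, n_components: int = N_COMPONENTS) -> int:
    """Length of the flattened vector: components per node x node count."""
    return n_components * n_fix


def vectorize_graph(
    g: ReducedGraph,
    params: StandardizerParams,
    pca: PCA,
    n_fix: int,
) -> np.ndarray:
    """sort -> standardize -> project -> flatten -> pad/truncate."""
    order = sort_nodes(g)
    index = {n: i for i, n in enumerate(g.node_order)}
    features = g.node_features[[index[n] for n in order]]
    projected = pca.transform(standardize(features, params))
    n_components = projected.shape[1]
    out = np.zeros(flat_vector_length(n_fix, n_components))
    n_keep = min(len(order), n_fix)
    out[: n_keep * n_components] = projected[:n_keep].ravel()
    return out


class BaselineVectorizer:
    """Fit-once, transform-many vectorization pipeline with a leakage
    guard: fitting raises if any graph belongs to the forbidden set."""

    def __init__(self, n_components: int = N_COMPONENTS,
                 n_fix: int | None = None):
        self.n_components = n_components
        self.n_fix = n_fix
        self.params: StandardizerParams | None = None
        self.pca: PCA | None = None

    @staticmethod
    def _graph_key(g: ReducedGraph) -> tuple[str, str, str]:
        a, b = sorted((g.drug_a, g.drug_b))
        return (a, b, g.cell_line)

    def fit(
        self,
        graphs: Sequence[ReducedGraph],
        forbidden: Sequence[ReducedGraph] = (),
    ) -> "BaselineVectorizer":
        forbidden_keys = {self._graph_key(g) for g in forbidden}
        leaked = [
            g for g in graphs if self._graph_key(g) in forbidden_keys
        ]
        if leaked:
            raise LeakageError(
                f"{len(leaked)} held-out graph(s) passed to fit(); the "
                "standardizer and PCA must see training graphs only"
            )
        stacked = np.vstack([g.node_features for g in graphs])
        self.params = fit_standardizer(stacked)
        self.pca = fit_pca(standardize(stacked, self.params),
                           self.n_components)
        if self.n_fix is None:
            self.n_fix = max(g.n_nodes for g in graphs)
        return self

    def transform(self, graphs: Sequence[ReducedGraph]) -> np.ndarray:
        if self.params is None or self.pca is None:
            raise RuntimeError("vectorizer not fitted")
        return np.vstack(
            [vectorize_graph(g, self.params, self.pca, self.n_fix)
             for g in graphs]
        )


def train_rf(
    vectors: np.ndarray,
    labels: Sequence[int],
    seed: int = 0,
    n_estimators: int = 200,
    class_weight: str | None = "balanced",
) -> RandomForestClassifier:
    """Random forest on flattened graph vectors; deterministic per seed."""
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        class_weight=class_weight,
        n_jobs=1,
    )
    clf.fit(np.asarray(vectors), np.asarray(labels))
    return clf


def predict_rf(
    clf: RandomForestClassifier, vectors: np.ndarray
) -> np.ndarray:
    """Probability of class 1 for each vector."""
    proba = clf.predict_proba(np.asarray(vectors))
    if proba.shape[1] == 1:  # degenerate single-class training set
        return np.full(len(vectors), float(clf.classes_[0]))
    return proba[:, list(clf.classes_).index(1)]
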