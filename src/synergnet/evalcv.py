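"""Metrics and leakage-safe stratified cross-validation.

The positive class throughout is *synergy* (encoded 1 in label arrays).
Augmented instances never enter a test set, and an augmented instance is
admitted to a fold's training set only when its parent original instance
is in that fold's training portion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from synergnet.augment import SynergyInstance

__all__ = [
    "Metrics",
    "FoldPlan",
    "SynergyClassifier",
    "CVResult",
    "label_array",
    "compute_metrics",
    "make_folds",
    "leakage_safe_train_set",
    "cross_validate",
    "independent_validate",
    "GNNSynergyClassifier",
    "RFSynergyClassifier",
]

REPORT_COLUMNS = [
    "Classifier", "Dataset", "AUC", "BAC", "PPV", "FPR", "MCC", "ΔBAC",
]


@dataclass(frozen=True)
class Metrics:
    """Binary-classification metrics (positive class = synergy).

    ``delta_bac`` is training BAC minus testing BAC when available, else
    NaN.  ``degenerate`` flags that at least one confusion-matrix ratio
    had a zero denominator and was reported as 0.
    """

    auc: float
    bac: float
    ppv: float
    fpr: float
    mcc: float
    delta_bac: float = float("nan")
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of original instances to k folds."""

    k: int
    assignment: tuple[int, ...]
    seed: int
    stratified: bool

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one fold."""
        a = np.asarray(self.assignment)
        return np.where(a != fold)[0], np.where(a == fold)[0]


class SynergyClassifier(Protocol):
    """Anything that can be trained on instances and score new ones."""

    def fit(self, instances: Sequence[SynergyInstance]) -> None: ...

    def score(self, instances: Sequence[SynergyInstance]) -> np.ndarray:
        """Synergy probability per instance, in order."""
        ...


def label_array(instances: Sequence[SynergyInstance]) -> np.ndarray:
    """1 for synergy, 0 for antagonism."""
    return np.array(
        [1 if inst.label == "synergy" else 0 for inst in instances],
        dtype=np.intp,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _auc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with mid-rank tie handling."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for a single-class label vector")
    order = np.argsort(scores, kind="mergesort")
    sorted_scores = scores[order]
    ranks = np.empty(len(scores))
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # mid-rank, 1-based
        i = j + 1
    rank_sum_pos = ranks[pos].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> Metrics:
    """AUC (rank statistic, ties mid-ranked) plus thresholded
    confusion-matrix metrics.

    Ratios with a zero denominator are reported as 0 and the result is
    flagged ``degenerate`` with a warning.  A single-class label vector
    makes the AUC undefined and raises.
    """
    y = np.asarray(labels, dtype=np.intp)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores length mismatch")
    if not np.all((s >= 0) & (s <= 1)):
        raise ValueError("scores must lie in [0, 1]")
    auc = _auc_rank(y, s)

    pred = (s >= threshold).astype(np.intp)
    tp = int(np.sum((y == 1) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))

    degenerate = False

    def ratio(num: int, denom: int) -> float:
        nonlocal degenerate
        if denom == 0:
            degenerate = True
            return 0.0
        return num / denom

    tpr = ratio(tp, tp + fn)
    tnr = ratio(tn, tn + fp)
    bac = 0.5 * (tpr + tnr)
    ppv = ratio(tp, tp + fp)
    fpr = ratio(fp, fp + tn)
    mcc_denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if mcc_denom == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_denom
    if degenerate:
        warnings.warn("zero-denominator ratio(s) reported as 0")
    return Metrics(
        auc=auc, bac=bac, ppv=ppv, fpr=fpr, mcc=mcc,
        tp=tp, fn=fn, fp=fp, tn=tn, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Fold construction and leakage-safe training sets
# ---------------------------------------------------------------------------

def make_folds(
    originals: Sequence[SynergyInstance],
    seed: int,
    k: int = 5,
    stratified: bool = True,
) -> FoldPlan:
    """Deterministic (per seed) k-fold assignment of original instances,
    stratified by class so per-fold sizes differ by at most one."""
    n = len(originals)
    if n < k:
        raise ValueError(f"need at least {k} instances, got {n}")
    if any(inst.provenance != "original" for inst in originals):
        raise ValueError("folds are planned over original instances only")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=np.intp)
    if stratified:
        y = label_array(originals)
        cursor = 0
        for cls in (1, 0):
            idx = np.where(y == cls)[0]
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                assignment[i] = (cursor + j) % k
            cursor += len(idx)
    else:
        idx = rng.permutation(n)
        for j, i in enumerate(idx):
            assignment[i] = j % k
    return FoldPlan(
        k=k, assignment=tuple(int(a) for a in assignment),
        seed=seed, stratified=stratified,
    )


def leakage_safe_train_set(
    fold: int,
    plan: FoldPlan,
    originals: Sequence[SynergyInstance],
    augmented: Sequence[SynergyInstance] | None = None,
) -> tuple[list[SynergyInstance], list[SynergyInstance]]:
    """(train, test) for one fold.

    Training = the fold's original training instances plus augmented
    instances whose parent lies in that training portion.  Test = the
    fold's held-out originals only.
    """
    train_idx, test_idx = plan.fold_indices(fold)
    train = [originals[i] for i in train_idx]
    test = [originals[i] for i in test_idx]
    if augmented:
        original_ids = {inst.instance_id for inst in originals}
        train_ids = {inst.instance_id for inst in train}
        for aug in augmented:
            if aug.provenance != "augmented":
                raise ValueError(
                    f"non-augmented instance {aug.instance_id} in augmented set"
                )
            if aug.parent_id not in original_ids:
                raise ValueError(
                    f"augmented instance {aug.instance_id} has unresolvable "
                    f"parent {aug.parent_id!r}"
                )
            if aug.parent_id in train_ids:
                train.append(aug)
    return train, test


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold metrics plus pooled test predictions."""

    fold_metrics: list[Metrics]
    pooled_labels: np.ndarray
    pooled_scores: np.ndarray
    pooled_instances: list[SynergyInstance]
    plan: FoldPlan

    def mean_metrics(self) -> dict[str, float]:
        out = {}
        for name in ("auc", "bac", "ppv", "fpr", "mcc", "delta_bac"):
            values = [getattr(m, name) for m in self.fold_metrics]
            out[name] = float(np.mean(values))
            out[name + "_sd"] = float(np.std(values, ddof=1))
        return out

    def report_row(self, classifier: str, dataset: str) -> pd.DataFrame:
        m = self.mean_metrics()
        return pd.DataFrame(
            [[classifier, dataset, m["auc"], m["bac"], m["ppv"],
              m["fpr"], m["mcc"], m["delta_bac"]]],
            columns=REPORT_COLUMNS,
        )

    def group_report(
        self, group_fn: Callable[[SynergyInstance], str]
    ) -> pd.DataFrame:
        """Pooled-prediction metrics per instance group (tissue-style)."""
        rows = []
        tags = np.array([group_fn(i) for i in self.pooled_instances])
        for tag in sorted(set(tags)):
            mask = tags == tag
            try:
                m = compute_metrics(
                    self.pooled_labels[mask], self.pooled_scores[mask]
                )
            except ValueError:
                continue  # single-class group: AUC undefined
            rows.append([tag, m.auc, m.bac, m.ppv, m.fpr, m.mcc])
        return pd.DataFrame(
            rows, columns=["Group", "AUC", "BAC", "PPV", "FPR", "MCC"]
        )


def cross_validate(
    make_classifier: Callable[[int], SynergyClassifier],
    originals: Sequence[SynergyInstance],
    augmented: Sequence[SynergyInstance] | None = None,
    seed: int = 0,
    k: int = 5,
    stratified: bool = True,
    threshold: float = 0.5,
) -> CVResult:
    """k-fold cross-validation with leakage-safe augmentation.

    ``make_classifier`` receives a per-fold seed and must return a fresh
    classifier.  Test folds contain held-out originals only; ``delta_bac``
    is the per-fold training BAC minus testing BAC.
    """
    plan = make_folds(originals, seed=seed, k=k, stratified=stratified)
    fold_metrics: list[Metrics] = []
    pooled_labels, pooled_scores, pooled_instances = [], [], []
    for fold in range(k):
        train, test = leakage_safe_train_set(fold, plan, originals, augmented)
        clf = make_classifier(seed * 1000 + fold)
        clf.fit(train)
        test_scores = np.asarray(clf.score(test), dtype=float)
        test_labels = label_array(test)
        m = compute_metrics(test_labels, test_scores, threshold=threshold)
        train_scores = np.asarray(clf.score(train), dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train_m = compute_metrics(
                label_array(train), train_scores, threshold=threshold
            )
        fold_metrics.append(replace(m, delta_bac=train_m.bac - m.bac))
        pooled_labels.append(test_labels)
        pooled_scores.append(test_scores)
        pooled_instances.extend(test)
    return CVResult(
        fold_metrics=fold_metrics,
        pooled_labels=np.concatenate(pooled_labels),
        pooled_scores=np.concatenate(pooled_scores),
        pooled_instances=pooled_instances,
        plan=plan,
    )


def independent_validate(
    classifier: SynergyClassifier,
    external: Sequence[SynergyInstance],
    threshold: float = 0.5,
) -> Metrics:
    """Single-pass evaluation of a trained classifier on an external set
    (no refitting)."""
    scores = np.asarray(classifier.score(external), dtype=float)
    return compute_metrics(label_array(external), scores, threshold=threshold)


# ---------------------------------------------------------------------------
# Classifier adapters
# ---------------------------------------------------------------------------

class GNNSynergyClassifier:
    """Adapter training the graph network on reduced graphs.

    ``graph_provider`` maps an instance to its :class:`ReducedGraph`
    (e.g. ``bundle.reduced_graph``).
    """

    def __init__(self, graph_provider, model_cfg=None, train_cfg=None,
                 seed: int = 0):
        from synergnet.gnn import ModelConfig, TrainConfig, build_model

        self.graph_provider = graph_provider
        self.model_cfg = model_cfg or ModelConfig()
        base = train_cfg or TrainConfig()
        self.train_cfg = replace(base, seed=seed)
        self.seed = seed
        self.model = build_model(self.model_cfg, seed=seed)
        self.history = None

    def fit(self, instances: Sequence[SynergyInstance]) -> None:
        from synergnet.gnn import train as gnn_train

        graphs = [self.graph_provider(i) for i in instances]
        labels = [i.label for i in instances]
        self.history = gnn_train(self.model, graphs, labels, self.train_cfg)

    def score(self, instances: Sequence[SynergyInstance]) -> np.ndarray:
        from synergnet.gnn import predict as gnn_predict

        graphs = [self.graph_provider(i) for i in instances]
        return gnn_predict(self.model, graphs).synergy_scores


class RFSynergyClassifier:
    """Adapter: vectorization pipeline + random forest.

    The standardizer and PCA are fitted inside :meth:`fit`, i.e. on the
    training fold only.
    """

    def __init__(self, graph_provider, seed: int = 0, n_components: int = 32,
                 n_fix: int | None = None, n_estimators: int = 200):
        from synergnet.baseline import BaselineVectorizer

        self.graph_provider = graph_provider
        self.seed = seed
        self.n_estimators = n_estimators
        self.vectorizer = BaselineVectorizer(
            n_components=n_components, n_fix=n_fix
        )
        self.clf = None

    def fit(self, instances: Sequence[SynergyInstance]) -> None:
        from synergnet.baseline import train_rf

        graphs = [self.graph_provider(i) for i in instances]
        self.vectorizer.fit(graphs)
        vectors = self.vectorizer.transform(graphs)
        self.clf = train_rf(
            vectors, label_array(instances), seed=self.seed,
            n_estimators=self.n_estimators,
        )

    def score(self, instances: Sequence[SynergyInstance]) -> np.ndarray:
        from synergnet.baseline import predict_rf

        if self.clf is None:
            raise RuntimeError("classifier not fitted")
        graphs = [self.graph_provider(i) for i in instances]
        return predict_rf(self.clf, self.vectorizer.transform(graphs))
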