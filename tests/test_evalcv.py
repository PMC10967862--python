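"""Tests for metrics and the leakage-safe cross-validation harness."""

import warnings

import numpy as np
import pytest

from synergnet.augment import SynergyInstance
from synergnet.evalcv import (
    REPORT_COLUMNS,
    compute_metrics,
    cross_validate,
    independent_validate,
    label_array,
    leakage_safe_train_set,
    make_folds,
)


def make_instances(n_pos, n_neg, cell="c1", prefix="D"):
    out = []
    for i in range(n_pos + n_neg):
        label = "synergy" if i < n_pos else "antagonism"
        out.append(SynergyInstance(
            drug_a=f"{prefix}{2 * i}", drug_b=f"{prefix}{2 * i + 1}",
            cell_line=cell, label=label,
        ))
    return out


def child_of(parent: SynergyInstance, new_drug: str) -> SynergyInstance:
    return SynergyInstance(
        drug_a=parent.drug_a, drug_b=new_drug, cell_line=parent.cell_line,
        label=parent.label, provenance="augmented",
        parent_id=parent.instance_id, replaced_slot="b",
    )


class TestComputeMetrics:
    def test_perfect_scores(self):
        y = [1, 1, 0, 0]
        m = compute_metrics(y, [0.9, 0.8, 0.2, 0.1])
        assert (m.auc, m.bac, m.fpr, m.mcc) == (1.0, 1.0, 0.0, 1.0)

    def test_flipped_scores(self):
        y = [1, 1, 0, 0]
        m = compute_metrics(y, [0.1, 0.2, 0.8, 0.9])
        assert m.auc == 0.0
        assert m.mcc == -1.0

    def test_contingency_oracle(self):
        # TP=40, FN=10, FP=20, TN=30
        y = [1] * 50 + [0] * 50
        s = [0.9] * 40 + [0.1] * 10 + [0.9] * 20 + [0.1] * 30
        m = compute_metrics(y, s)
        assert m.bac == pytest.approx((0.8 + 0.6) / 2)
        assert m.fpr == pytest.approx(0.4)
        assert m.ppv == pytest.approx(2 / 3)
        expected_mcc = (40 * 30 - 20 * 10) / np.sqrt(60 * 50 * 50 * 40)
        assert m.mcc == pytest.approx(expected_mcc)
        assert (m.tp, m.fn, m.fp, m.tn) == (40, 10, 20, 30)

    def test_brute_force_oracle_many_draws(self):
        """Exact agreement with an independent confusion-matrix
        implementation (and sklearn AUC) on 1,000 random draws."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(10, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)  # ties likely
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_metrics(y, s)
            pred = (s >= 0.5).astype(int)
            tp = np.sum((y == 1) & (pred == 1))
            fn = np.sum((y == 1) & (pred == 0))
            fp = np.sum((y == 0) & (pred == 1))
            tn = np.sum((y == 0) & (pred == 0))
            tpr = tp / (tp + fn) if tp + fn else 0.0
            tnr = tn / (tn + fp) if tn + fp else 0.0
            assert m.bac == pytest.approx(0.5 * (tpr + tnr), abs=1e-12)
            assert m.ppv == pytest.approx(
                tp / (tp + fp) if tp + fp else 0.0, abs=1e-12)
            assert m.fpr == pytest.approx(
                fp / (fp + tn) if fp + tn else 0.0, abs=1e-12)
            denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
            assert m.mcc == pytest.approx(mcc, abs=1e-12)
            assert m.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics([1, 1, 1], [0.1, 0.5, 0.9])

    def test_degenerate_flagged(self):
        y = [1, 1, 0, 0]
        with pytest.warns(UserWarning, match="zero-denominator"):
            m = compute_metrics(y, [0.1, 0.2, 0.3, 0.4])  # nothing predicted +
        assert m.degenerate
        assert m.ppv == 0.0

    def test_score_range_checked(self):
        with pytest.raises(ValueError, match="scores"):
            compute_metrics([1, 0], [1.5, 0.2])


class TestMakeFolds:
    def test_sizes_and_class_representation(self):
        plan = make_folds(make_instances(8, 2), seed=0)
        sizes = np.bincount(plan.assignment, minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_deterministic_per_seed(self):
        insts = make_instances(40, 12)
        assert make_folds(insts, seed=3) == make_folds(insts, seed=3)
        assert make_folds(insts, seed=3) != make_folds(insts, seed=4)

    def test_too_few_instances_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds(make_instances(2, 1), seed=0)

    def test_augmented_instances_rejected(self):
        insts = make_instances(4, 4)
        bad = insts[:-1] + [child_of(insts[0], "Z")]
        with pytest.raises(ValueError, match="original"):
            make_folds(bad, seed=0)

    def test_stratification_chi2_nonsignificant(self):
        from scipy.stats import chi2_contingency

        insts = make_instances(380, 120)
        for seed in range(20):
            plan = make_folds(insts, seed=seed)
            y = label_array(insts)
            table = np.zeros((2, 5))
            for cls in (0, 1):
                for fold in range(5):
                    table[cls, fold] = np.sum(
                        (y == cls) & (np.asarray(plan.assignment) == fold)
                    )
            _, p, _, _ = chi2_contingency(table)
            assert p > 0.05


class TestLeakageSafeTrainSet:
    def setup_method(self):
        self.originals = make_instances(8, 4)
        self.plan = make_folds(self.originals, seed=0)
        self.augmented = [
            child_of(inst, f"X{i}") for i, inst in enumerate(self.originals)
        ]

    def test_test_fold_children_excluded(self):
        for fold in range(5):
            train, test = leakage_safe_train_set(
                fold, self.plan, self.originals, self.augmented
            )
            test_ids = {t.instance_id for t in test}
            for inst in train:
                if inst.provenance == "augmented":
                    assert inst.parent_id not in test_ids

    def test_train_fold_children_included(self):
        train, _ = leakage_safe_train_set(
            0, self.plan, self.originals, self.augmented
        )
        train_original_ids = {
            t.instance_id for t in train if t.provenance == "original"
        }
        included_parents = {
            t.parent_id for t in train if t.provenance == "augmented"
        }
        assert included_parents == train_original_ids

    def test_without_augmentation(self):
        train, test = leakage_safe_train_set(0, self.plan, self.originals)
        assert all(t.provenance == "original" for t in train + test)
        assert len(train) + len(test) == len(self.originals)

    def test_test_set_originals_only(self):
        for fold in range(5):
            _, test = leakage_safe_train_set(
                fold, self.plan, self.originals, self.augmented
            )
            assert all(t.provenance == "original" for t in test)

    def test_unresolvable_parent_rejected(self):
        orphan = SynergyInstance(
            drug_a="Q1", drug_b="Q2", cell_line="c1", label="synergy",
            provenance="augmented", parent_id="nope:x@c1",
            replaced_slot="b",
        )
        with pytest.raises(ValueError, match="unresolvable"):
            leakage_safe_train_set(
                0, self.plan, self.originals, [orphan]
            )


class ConstantClassifier:
    """Always predicts the majority class with full confidence."""

    def fit(self, instances):
        y = label_array(instances)
        self.constant = 1.0 if y.mean() >= 0.5 else 0.0

    def score(self, instances):
        return np.full(len(instances), self.constant)


class OracleClassifier:
    """Scores by peeking at the label (upper-bound sanity check)."""

    def fit(self, instances):
        pass

    def score(self, instances):
        return np.array([
            0.9 if i.label == "synergy" else 0.1 for i in instances
        ])


class TestCrossValidate:
    def test_majority_classifier_bac_half(self):
        originals = make_instances(30, 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = cross_validate(
                lambda seed: ConstantClassifier(), originals, seed=0
            )
        for m in result.fold_metrics:
            assert m.bac == pytest.approx(0.5)

    def test_oracle_classifier_perfect(self):
        originals = make_instances(30, 10)
        result = cross_validate(
            lambda seed: OracleClassifier(), originals, seed=0
        )
        assert result.mean_metrics()["auc"] == 1.0
        assert result.mean_metrics()["delta_bac"] == pytest.approx(0.0)

    def test_report_schema(self):
        originals = make_instances(30, 10)
        result = cross_validate(
            lambda seed: OracleClassifier(), originals, seed=0
        )
        report = result.report_row("GNN", "Original")
        assert list(report.columns) == REPORT_COLUMNS

    def test_group_report(self):
        originals = (
            make_instances(12, 6, cell="c1") +
            make_instances(12, 6, cell="c2", prefix="E")
        )
        result = cross_validate(
            lambda seed: OracleClassifier(), originals, seed=0
        )
        groups = result.group_report(lambda inst: inst.cell_line)
        assert set(groups["Group"]) == {"c1", "c2"}
        assert (groups["AUC"] == 1.0).all()

    def test_mean_recomputable_from_folds(self):
        originals = make_instances(40, 15)
        result = cross_validate(
            lambda seed: OracleClassifier(), originals, seed=1
        )
        m = result.mean_metrics()
        assert m["bac"] == pytest.approx(
            np.mean([fm.bac for fm in result.fold_metrics])
        )


class TestIndependentValidate:
    def test_imbalanced_6_49_shape(self):
        external = make_instances(6, 49)
        clf = OracleClassifier()
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no NaN/degenerate warnings
            m = independent_validate(clf, external)
        assert np.isfinite([m.auc, m.bac, m.ppv, m.fpr, m.mcc]).all()

    def test_evaluating_twice_identical(self):
        external = make_instances(10, 10)
        clf = OracleClassifier()
        assert independent_validate(clf, external) == \
            independent_validate(clf, external)
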