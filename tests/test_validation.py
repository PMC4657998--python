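"""Fold plans, metrics, summaries, chance agreement, ROC, and the CV engines."""

import numpy as np
import pandas as pd
import pytest

from vocclass import (
    CVScheme,
    FeatureTable,
    ModelSpec,
    chance_agreement,
    confusion_metrics,
    make_folds,
    monte_carlo_null,
    pooled_roc,
    repeated_kfold_cv,
    six_number_summary,
)
from vocclass.feature_table import ContractError


class TestMakeFolds:
    def test_partition_102_into_10(self):
        assign = make_folds(102, 10, seed=0)
        sizes = np.bincount(assign, minlength=10)
        assert sorted(sizes) == [10] * 8 + [11, 11]
        assert set(assign) == set(range(10))

    def test_stratified_balance_59_43(self):
        labels = np.array(["cancer"] * 59 + ["control"] * 43)
        assign = make_folds(102, 3, labels=labels, stratified=True, seed=1)
        for j in range(3):
            canc = ((assign == j) & (labels == "cancer")).sum()
            ctrl = ((assign == j) & (labels == "control")).sum()
            assert canc in (19, 20) and ctrl in (14, 15)

    def test_deterministic(self):
        a = make_folds(50, 5, seed=42)
        b = make_folds(50, 5, seed=42)
        assert np.array_equal(a, b)

    def test_partition_invariants_many_seeds(self):
        """Across 100 seeds: disjoint cover with sizes differing by at most 1."""
        labels = np.array([0] * 31 + [1] * 20)
        for seed in range(100):
            assign = make_folds(51, 7, labels=labels, stratified=True, seed=seed)
            sizes = np.bincount(assign, minlength=7)
            assert sizes.sum() == 51
            assert sizes.max() - sizes.min() <= 1
            per_class = np.array([np.bincount(assign[labels == c], minlength=7) for c in (0, 1)])
            assert (per_class.max(axis=1) - per_class.min(axis=1) <= 1).all()

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 6, seed=0)

    def test_tiny_class_degrades_with_warning(self):
        labels = np.array([0] * 18 + [1] * 2)
        with pytest.warns(UserWarning, match="fewer samples than folds"):
            assign = make_folds(20, 5, labels=labels, stratified=True, seed=0)
        assert np.bincount(assign).sum() == 20


class TestConfusionMetrics:
    def test_direct_formula(self):
        y_true = [1, 1, 1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 1, 0, 0]
        rec = confusion_metrics(y_true, y_pred, positive_class=1)
        assert rec.confusion == (3, 2, 2, 1)
        assert rec.accuracy == pytest.approx(0.625)
        assert rec.sensitivity == pytest.approx(0.75)
        assert rec.specificity == pytest.approx(0.5)

    def test_all_correct(self):
        rec = confusion_metrics([1, 0, 1], [1, 0, 1], positive_class=1)
        assert (rec.accuracy, rec.sensitivity, rec.specificity) == (1.0, 1.0, 1.0)

    def test_no_positives_flagged_undefined(self):
        rec = confusion_metrics([0, 0], [0, 1], positive_class=1)
        assert rec.sensitivity is None
        assert rec.specificity == pytest.approx(0.5)

    def test_unknown_label_rejected(self):
        with pytest.raises(ContractError):
            confusion_metrics([0, 1, 2], [0, 1, 1], positive_class=1)


class TestSixNumberSummary:
    def test_hand_interpolated_quartiles(self):
        s = six_number_summary([0.1, 0.2, 0.3, 0.4])
        assert (s.min, s.max) == (0.1, 0.4)
        assert s.q1 == pytest.approx(0.175)
        assert s.median == pytest.approx(0.25)
        assert s.mean == pytest.approx(0.25)
        assert s.q3 == pytest.approx(0.325)

    def test_two_values(self):
        s = six_number_summary([0.0, 1.0])
        assert (s.q1, s.median, s.q3) == (0.25, 0.5, 0.75)

    def test_constant_vector(self):
        s = six_number_summary([0.7] * 5)
        assert s.min == s.q1 == s.median == s.mean == s.q3 == s.max == 0.7

    def test_ordering_invariant(self, rng):
        s = six_number_summary(rng.random(31))
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max
        assert s.min <= s.mean <= s.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            six_number_summary([])


class TestChanceAgreement:
    def test_cohort_marginals(self):
        assert chance_agreement(59, 43) == pytest.approx(0.5123, abs=5e-5)

    def test_balanced(self):
        assert chance_agreement(50, 50) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            chance_agreement(100, 0)


class TestPooledROC:
    def test_perfect_scores(self):
        roc = pooled_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], positive_class=1)
        assert roc.auc == 1.0

    def test_inverted_scores(self):
        roc = pooled_roc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0], positive_class=1)
        assert roc.auc == 0.0

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        while y.sum() in (0, 2000):
            y = rng.integers(0, 2, 2000)
        roc = pooled_roc(rng.random(2000), y, positive_class=1)
        assert abs(roc.auc - 0.5) < 0.05

    def test_constant_scores_diagonal(self):
        roc = pooled_roc([0.5] * 6, [1, 1, 1, 0, 0, 0], positive_class=1)
        assert roc.auc == pytest.approx(0.5)
        assert roc.tpr[-1] == 1.0 and roc.fpr[-1] == 1.0


def _separable_table(n=40):
    idx = [f"s{i}" for i in range(n)]
    half = n // 2
    v = pd.DataFrame({"sep": [1.0] * half + [0.0] * half,
                      "noise": np.tile([0.0, 1.0], half)}, index=idx)
    labels = pd.Series(["cancer"] * half + ["control"] * half, index=idx)
    return FeatureTable(values=v, labels=labels, binary=True)


class TestRepeatedKFold:
    def test_separable_all_folds_perfect(self):
        t = _separable_table()
        scheme = CVScheme.repeated_kfold(repeats=3, k=5, master_seed=0)
        res = repeated_kfold_cv(t, ModelSpec(kind="lda"), ["sep"], scheme)
        assert len(res.records) == 15
        assert (res.accuracies() == 1.0).all()
        s = res.summary()
        assert s.min == s.mean == s.max == 1.0

    def test_fold_accuracy_granularity_102_samples(self, default_cohort):
        """With n=102, k=10 every fold accuracy is a multiple of 1/10 or 1/11."""
        t, truth = default_cohort
        scheme = CVScheme.repeated_kfold(repeats=1, k=10, master_seed=2)
        res = repeated_kfold_cv(t, ModelSpec(kind="lda"), truth.planted_features, scheme)
        for rec in res.records:
            assert rec.n_test in (10, 11)
            assert (rec.accuracy * rec.n_test) == pytest.approx(round(rec.accuracy * rec.n_test))

    def test_null_features_near_chance(self, rng):
        n = 80
        idx = [f"s{i}" for i in range(n)]
        v = pd.DataFrame((rng.random((n, 3)) < 0.5).astype(int), index=idx,
                         columns=["a", "b", "c"])
        labels = pd.Series(np.repeat(["cancer", "control"], n // 2), index=idx)
        t = FeatureTable(values=v, labels=labels, binary=True)
        scheme = CVScheme.repeated_kfold(repeats=5, k=10, master_seed=3)
        res = repeated_kfold_cv(t, ModelSpec(kind="forest", n_trees=25), ["a", "b", "c"], scheme)
        # balanced cohort, uninformative features: chance is 0.5
        assert abs(res.mean_accuracy - 0.5) < 3 * 0.5 / np.sqrt(len(res.records) * 8)

    def test_determinism_bitwise(self, default_cohort):
        t, truth = default_cohort
        scheme = CVScheme.repeated_kfold(repeats=2, k=5, master_seed=9)
        spec = ModelSpec(kind="lda", continuous=("psa",))
        a = repeated_kfold_cv(t, spec, truth.planted_features + ["psa"], scheme)
        b = repeated_kfold_cv(t, spec, truth.planted_features + ["psa"], scheme)
        assert [r.__dict__ for r in a.records] == [r.__dict__ for r in b.records]
        assert np.array_equal(a.score_matrix, b.score_matrix, equal_nan=True)


class TestMonteCarloNull:
    def test_permutation_preserves_class_sizes(self):
        y = np.array([1] * 59 + [0] * 43)
        permuted = np.random.default_rng(0).permutation(y)
        assert permuted.sum() == 59 and len(permuted) - permuted.sum() == 43

    def test_null_reproducible(self, default_cohort):
        t, truth = default_cohort
        scheme = CVScheme.repeated_kfold(repeats=2, k=5, master_seed=4)
        a = monte_carlo_null(t, ModelSpec(kind="lda"), truth.planted_features, scheme)
        b = monte_carlo_null(t, ModelSpec(kind="lda"), truth.planted_features, scheme)
        assert a.accuracies().tolist() == b.accuracies().tolist()
        assert a.scheme.permute_labels
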