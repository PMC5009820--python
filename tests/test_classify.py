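"""Information gain, leakage-free cross-validation, permutation null."""

import numpy as np
import pandas as pd
import pytest

from mutclust.classify import (
    LabeledDataset,
    cross_validate,
    default_classifier_factory,
    information_gain,
    permutation_test,
    select_by_information_gain,
)


def planted_dataset(n_per_class=20, n_noise=30, sep=5.0, seed=0):
    """Three classes, one perfectly informative gene per class, plus noise genes."""
    rng = np.random.default_rng(seed)
    n = 3 * n_per_class
    y = pd.Series(np.repeat([1, 2, 3], n_per_class), index=[f"P{i}" for i in range(n)])
    X = pd.DataFrame(
        rng.normal(0, 1, size=(n, n_noise)),
        index=y.index,
        columns=[f"noise{i}" for i in range(n_noise)],
    )
    for cls in (1, 2, 3):
        X[f"marker{cls}"] = np.where(y == cls, sep, 0.0) + rng.normal(0, 0.2, n)
    return LabeledDataset(X=X, y=y)


class TestInformationGain:
    def test_constant_feature_zero_gain(self):
        y = [0] * 10 + [1] * 10
        assert information_gain(np.ones(20), y) == 0.0

    def test_perfect_threshold_separation_one_bit(self):
        y = [0] * 10 + [1] * 10
        x = [1.0] * 10 + [5.0] * 10
        assert information_gain(x, y) == pytest.approx(1.0)

    def test_three_class_perfect_separation(self):
        y = [0] * 8 + [1] * 8 + [2] * 8
        x = [1.0] * 8 + [5.0] * 8 + [9.0] * 8
        assert information_gain(x, y) == pytest.approx(np.log2(3))

    def test_mdl_rule_suppresses_random_features(self, rng):
        labels = rng.integers(0, 3, size=200)
        gains = [information_gain(rng.normal(size=200), labels) for _ in range(100)]
        assert np.mean(np.asarray(gains) == 0.0) >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            information_gain([1.0, 2.0], [0, 0])

    def test_gain_bounded_by_label_entropy(self, rng):
        y = rng.integers(0, 2, size=60)
        while np.unique(y).size < 2:
            y = rng.integers(0, 2, size=60)
        for _ in range(20):
            x = rng.normal(size=60)
            assert 0.0 <= information_gain(x, y) <= 1.0 + 1e-12


class TestFeatureSelection:
    def test_top_k_contains_markers(self):
        ds = planted_dataset()
        genes = select_by_information_gain(ds.X, ds.y, 3)
        assert set(genes) == {"marker1", "marker2", "marker3"}

    def test_k_top_all_returns_every_gene(self):
        ds = planted_dataset()
        assert sorted(select_by_information_gain(ds.X, ds.y, ds.X.shape[1])) == sorted(ds.X.columns)

    def test_selection_depends_only_on_given_rows(self):
        ds = planted_dataset()
        train = ds.X.index[:40]
        a = select_by_information_gain(ds.X.loc[train], ds.y.loc[train], 5)
        # perturbing rows outside the given split must not change the result
        X_mod = ds.X.copy()
        X_mod.loc[ds.X.index[40:], :] = 999.0
        b = select_by_information_gain(X_mod.loc[train], ds.y.loc[train], 5)
        assert a == b

    def test_no_leakage_canary(self):
        # a canary gene that perfectly encodes the label on held-out patients
        # but is pure noise on training patients must never be selected
        ds = planted_dataset()
        report = cross_validate(ds, default_classifier_factory(20), folds=3, k_top=3, seed=4)
        rng = np.random.default_rng(99)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=4)
        for train_idx, test_idx in skf.split(ds.X, ds.y):
            X = ds.X.copy()  # fresh copy per fold: only this fold's test rows leak
            X["canary"] = rng.normal(size=len(ds.y))
            X.iloc[test_idx, X.columns.get_loc("canary")] = ds.y.iloc[test_idx] * 100.0
            genes = select_by_information_gain(X.iloc[train_idx], ds.y.iloc[train_idx], 3)
            assert "canary" not in genes
        assert report.accuracy > 0.9  # sanity: the honest markers suffice


class TestCrossValidate:
    def test_degenerate_classifier_metrics(self):
        ds = planted_dataset(n_per_class=10, n_noise=5)

        class AlwaysOne:
            classes_ = np.array([1])

            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.ones(len(X), dtype=int)

            def predict_proba(self, X):
                return np.ones((len(X), 1))

        report = cross_validate(ds, lambda seed: AlwaysOne(), folds=5, k_top=5, seed=0)
        assert report.accuracy == pytest.approx(1 / 3)
        assert report.per_class.loc[1, "tpr"] == 1.0
        assert report.per_class.loc[2, "tpr"] == 0.0
        assert report.per_class.loc[3, "tpr"] == 0.0

    def test_separable_data_high_accuracy_and_auc(self):
        ds = planted_dataset()
        report = cross_validate(ds, default_classifier_factory(50), folds=5, k_top=5, seed=1)
        assert report.accuracy >= 0.95
        assert (report.per_class["auc"] >= 0.95).all()

    def test_confusion_row_sums_equal_class_counts(self):
        ds = planted_dataset(n_per_class=12, n_noise=10, sep=1.0)
        report = cross_validate(ds, default_classifier_factory(20), folds=4, k_top=5, seed=2)
        counts = ds.y.value_counts()
        for cls in ds.classes:
            assert report.confusion.loc[cls].sum() == counts[cls]
        weighted = np.average(report.fold_accuracies, weights=report.fold_sizes)
        assert report.accuracy == pytest.approx(weighted)

    def test_fold_reduction_warning_for_small_classes(self):
        ds = planted_dataset(n_per_class=4, n_noise=5)
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_validate(ds, default_classifier_factory(10), folds=10, k_top=3, seed=0)

    def test_auc_invariant_under_monotone_score_transform(self):
        ds = planted_dataset(n_per_class=12, n_noise=8, sep=1.5)
        factory = default_classifier_factory(30)

        class Warped:
            def __init__(self, seed):
                self.inner = factory(seed)

            def fit(self, X, y):
                self.inner.fit(X, y)
                self.classes_ = self.inner.classes_
                return self

            def predict(self, X):
                return self.inner.predict(X)

            def predict_proba(self, X):
                return np.exp(5 * self.inner.predict_proba(X))  # strictly monotone warp

        plain = cross_validate(ds, factory, folds=4, k_top=6, seed=3)
        warped = cross_validate(ds, lambda s: Warped(s), folds=4, k_top=6, seed=3)
        np.testing.assert_allclose(
            plain.per_class["auc"], warped.per_class["auc"], atol=1e-12
        )


class TestPermutationTest:
    def test_strong_signal_beats_every_permutation(self):
        ds = planted_dataset(n_per_class=12, n_noise=10)
        result = permutation_test(
            ds, default_classifier_factory(20), n_permutations=20, seed=0, folds=3, k_top=4
        )
        assert result.count_better == 0
        assert result.p_label == "< 0.05"

    def test_p_value_is_fraction_of_better_permutations(self):
        ds = planted_dataset(n_per_class=10, n_noise=10)

        class CoinFlip:
            def __init__(self, seed):
                self.rng = np.random.default_rng(seed)

            def fit(self, X, y):
                self.classes_ = np.unique(y)
                return self

            def predict(self, X):
                return self.rng.choice(self.classes_, size=len(X))

            def predict_proba(self, X):
                p = self.rng.uniform(size=(len(X), len(self.classes_)))
                return p / p.sum(axis=1, keepdims=True)

        result = permutation_test(ds, lambda s: CoinFlip(s), n_permutations=30, seed=1,
                                  folds=3, k_top=4)
        assert result.p_value == result.count_better / 30
        assert 0.0 <= result.p_value <= 1.0

    def test_class_sizes_preserved_under_shuffling(self):
        ds = planted_dataset(n_per_class=8, n_noise=4)
        rng = np.random.default_rng(7)
        shuffled = pd.Series(rng.permutation(ds.y.to_numpy()), index=ds.y.index)
        assert shuffled.value_counts().sort_index().equals(ds.y.value_counts().sort_index())
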