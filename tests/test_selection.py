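"""Correlation reduction, Fisher LDA, LOOCV, exhaustive search, ROC."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mpmtex import (SubsetSearchConfig, best_subset_search, correlation_filter,
                    fit_fisher_lda, loocv_accuracy, mean_abs_correlation,
                    repeated_selection, roc_auc)

from conftest import make_feature_table
from oracles import brute_auc, brute_mean_abs_corr


class TestMeanAbsCorrelation:
    def test_duplicated_feature_scores_one(self, rng):
        x = rng.normal(size=20)
        table = make_feature_table(np.column_stack([x, x]), ["tumor"] * 10 + ["normal"] * 10)
        scores = mean_abs_correlation(table)
        np.testing.assert_allclose(scores.values, [1.0, 1.0])

    def test_exactly_uncorrelated_features_score_zero(self):
        # Orthogonal, zero-mean columns are exactly uncorrelated.
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        table = make_feature_table(X, ["tumor", "tumor", "normal", "normal"])
        np.testing.assert_allclose(mean_abs_correlation(table).values, [0.0, 0.0],
                                   atol=1e-12)

    def test_matches_pairwise_bruteforce(self, rng):
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        X = np.column_stack([x, x, z])
        table = make_feature_table(X, ["tumor"] * 15 + ["normal"] * 15)
        scores = mean_abs_correlation(table)
        expected = brute_mean_abs_corr(X)
        np.testing.assert_allclose(scores.values, expected, atol=1e-12)
        r13 = abs(sps.pearsonr(x, z).statistic)
        assert scores.iloc[0] == pytest.approx((1 + r13) / 2)

    def test_too_few_features_rejected(self, rng):
        table = make_feature_table(rng.normal(size=(10, 1)), ["tumor"] * 5 + ["normal"] * 5)
        with pytest.raises(ValueError):
            mean_abs_correlation(table)


class TestCorrelationFilter:
    def test_independent_features_all_retained(self, rng):
        X = rng.normal(size=(200, 6))
        table = make_feature_table(X, ["tumor"] * 100 + ["normal"] * 100)
        reduced = correlation_filter(table, threshold=0.45)
        assert reduced.feature_names == table.feature_names

    def test_near_duplicates_removed_independents_survive(self, rng):
        """A block of mutually near-duplicate features is eliminated while
        independent features pass the mean-|r| threshold."""
        n = 120
        base = rng.normal(size=n)
        dups = np.column_stack([base + rng.normal(0, 0.05, n) for _ in range(10)])
        indep = rng.normal(size=(n, 4))
        X = np.column_stack([dups, indep])
        table = make_feature_table(X, ["tumor"] * 60 + ["normal"] * 60)
        reduced = correlation_filter(table, threshold=0.45)
        assert reduced.feature_names == table.feature_names[10:]

    def test_max_features_caps_at_lowest_scores(self, rng):
        X = rng.normal(size=(60, 8))
        table = make_feature_table(X, ["tumor"] * 30 + ["normal"] * 30)
        reduced = correlation_filter(table, threshold=0.45, max_features=3)
        assert reduced.width == 3
        scores = mean_abs_correlation(table)
        kept = set(reduced.feature_names)
        assert kept == set(scores.nsmallest(3).index)

    def test_threshold_zero_removes_everything(self, rng):
        X = rng.normal(size=(20, 4))
        table = make_feature_table(X, ["tumor"] * 10 + ["normal"] * 10)
        with pytest.raises(ValueError, match="removed every"):
            correlation_filter(table, threshold=0.0)


class TestFisherLDA:
    def test_axis_separable_projects_onto_first_axis(self):
        X = np.array([[0, 0], [0, 1], [3, 0], [3, 1]], dtype=float)
        y = ["a", "a", "b", "b"]
        model = fit_fisher_lda(X, y)
        assert abs(model.w[0]) > 1e3 * abs(model.w[1] if model.w[1] else 1e-30) \
            or model.w[1] == pytest.approx(0.0, abs=1e-9)
        assert list(model.predict(X)) == y

    def test_predictions_invariant_to_feature_rescaling(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array(["a"] * 15 + ["b"] * 15)
        X[y == "b"] += [1.0, -0.5, 0.2]
        base = fit_fisher_lda(X, y).predict(X)
        Xs = X.copy()
        Xs[:, 0] *= 10.0
        scaled = fit_fisher_lda(Xs, y).predict(Xs)
        np.testing.assert_array_equal(base, scaled)

    def test_well_separated_gaussians_near_bayes_accuracy(self, rng):
        # 1-D classes 4 sigma apart: Bayes error ~2.3%.
        X = np.concatenate([rng.normal(0, 1, 200), rng.normal(4, 1, 200)])[:, None]
        y = np.array(["a"] * 200 + ["b"] * 200)
        model = fit_fisher_lda(X, y)
        acc = (model.predict(X) == y).mean()
        assert acc >= 0.97

    def test_agrees_with_sklearn_lda_direction(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(40, 3))
        y = np.array(["a"] * 20 + ["b"] * 20)
        X[y == "b"] += [1.0, 0.3, -0.6]
        ours = fit_fisher_lda(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        np.testing.assert_array_equal(ours.predict(X), ref.predict(X))

    def test_degenerate_classes_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError):
            fit_fisher_lda(X, ["a"] * 6)
        with pytest.raises(ValueError):
            fit_fisher_lda(X, ["a"] * 5 + ["b"])


class TestLOOCV:
    def test_perfectly_separated_feature_scores_one(self):
        X = np.column_stack([np.r_[np.zeros(5), np.ones(5) * 10],
                             np.arange(10) % 3]).astype(float)
        table = make_feature_table(X, ["normal"] * 5 + ["tumor"] * 5)
        acc, scores = loocv_accuracy(table, ["F 01"])
        assert acc == 1.0
        assert len(scores) == 10

    def test_permuted_labels_center_on_chance(self):
        accs = []
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            X = rng.normal(size=(20, 2))
            labels = np.array(["tumor"] * 10 + ["normal"] * 10)
            rng.shuffle(labels)
            table = make_feature_table(X, labels)
            acc, _ = loocv_accuracy(table, ["F 01", "F 02"])
            accs.append(acc)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_returns_exactly_n_scores(self, rng):
        X = rng.normal(size=(14, 3))
        table = make_feature_table(X, ["tumor"] * 7 + ["normal"] * 7)
        _, scores = loocv_accuracy(table, ["F 02", "F 03"])
        assert scores.shape == (14,)

    def test_empty_subset_rejected(self, rng):
        table = make_feature_table(rng.normal(size=(10, 2)),
                                   ["tumor"] * 5 + ["normal"] * 5)
        with pytest.raises(ValueError):
            loocv_accuracy(table, [])


class TestBestSubsetSearch:
    def _table_with_one_informative(self, rng, F=10, n=20):
        X = rng.normal(size=(n, F))
        y = np.array(["normal"] * (n // 2) + ["tumor"] * (n // 2))
        X[y == "tumor", 0] += 10.0
        return make_feature_table(X, y)

    def test_finds_the_informative_feature(self, rng):
        table = self._table_with_one_informative(rng)
        subset, acc = best_subset_search(table, n=1, seed=0)
        assert subset == ("F 01",)
        assert acc == 1.0

    def test_full_subset_is_the_only_candidate(self, rng):
        table = self._table_with_one_informative(rng, F=4)
        subset, _ = best_subset_search(table, n=4, seed=0)
        assert subset == tuple(table.feature_names)

    def test_oversized_subset_rejected(self, rng):
        table = self._table_with_one_informative(rng, F=3)
        with pytest.raises(ValueError):
            best_subset_search(table, n=4)

    def test_exhaustive_search_equals_independent_enumeration(self, rng):
        X = rng.normal(size=(16, 6))
        y = np.array(["normal"] * 8 + ["tumor"] * 8)
        X[y == "tumor"] += 0.8
        table = make_feature_table(X, y)
        for n in (1, 2, 3):
            _, best_acc = best_subset_search(table, n=n, seed=1)
            enumerated = max(
                loocv_accuracy(table, list(sub))[0]
                for sub in itertools.combinations(table.feature_names, n))
            assert best_acc == pytest.approx(enumerated)

    def test_tie_break_uniform_over_duplicated_features(self, rng):
        x = np.r_[np.zeros(8), np.ones(8) * 5]
        X = np.column_stack([x, x.copy()])
        table = make_feature_table(X, ["normal"] * 8 + ["tumor"] * 8)
        picks = [best_subset_search(table, n=1, seed=s)[0][0]
                 for s in range(200)]
        frac = np.mean([p == "F 01" for p in picks])
        assert 0.4 <= frac <= 0.6


class TestRepeatedSelection:
    def _table(self, rng, F=5, n=20, shift=3.0):
        X = rng.normal(size=(n, F))
        y = np.array(["normal"] * (n // 2) + ["tumor"] * (n // 2))
        X[y == "tumor", 0] += shift
        return make_feature_table(X, y)

    def test_selection_counts_sum_to_n_times_runs(self, rng):
        table = self._table(rng)
        summary = repeated_selection(table, SubsetSearchConfig(n_max=3, runs=10, seed=4))
        for n, res in summary.by_n.items():
            assert sum(res.selection_counts.values()) == n * 10
            assert all(v <= 10 for v in res.misclassification.values())

    def test_theoretical_selection_maxima(self):
        assert SubsetSearchConfig(n_max=5, runs=100).theoretical_max_selections == 500
        assert SubsetSearchConfig(n_max=6, runs=100).theoretical_max_selections == 600

    def test_unique_best_subset_gives_zero_sd(self, rng):
        # One overwhelming feature: the best subset at n=1 is unique.
        table = self._table(rng, shift=12.0)
        summary = repeated_selection(table, SubsetSearchConfig(n_max=1, runs=25, seed=0))
        res = summary.by_n[1]
        assert len(set(res.best_subsets)) == 1
        assert res.accuracy_sd == 0.0

    def test_bit_identical_under_same_seed(self, rng):
        table = self._table(rng, shift=0.5)
        cfg = SubsetSearchConfig(n_max=2, runs=8, seed=13)
        a = repeated_selection(table, cfg)
        b = repeated_selection(table, cfg)
        for n in a.by_n:
            assert a.by_n[n].best_subsets == b.by_n[n].best_subsets
            np.testing.assert_array_equal(a.by_n[n].accuracies, b.by_n[n].accuracies)
            np.testing.assert_array_equal(a.by_n[n].pooled_scores,
                                          b.by_n[n].pooled_scores)
            assert a.by_n[n].auc == b.by_n[n].auc


class TestROC:
    def test_perfect_separation_auc_one(self):
        (fpr, tpr), auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_null_scores_center_on_half(self):
        aucs = []
        for rep in range(1000):
            rng = np.random.default_rng(rep)
            scores = rng.normal(size=40)
            labels = np.array([0] * 20 + [1] * 20)
            aucs.append(roc_auc(scores, labels)[1])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) > 0.5).astype(int)
        labels[:2] = [0, 1]  # both classes present
        base = roc_auc(scores, labels)[1]
        assert roc_auc(np.exp(scores), labels)[1] == pytest.approx(base)
        assert roc_auc(3 * scores + 7, labels)[1] == pytest.approx(base)

    def test_equals_mann_whitney_normalization(self, rng):
        scores = rng.integers(0, 5, 30).astype(float)  # force ties
        labels = np.array([0] * 15 + [1] * 15)
        auc = roc_auc(scores, labels)[1]
        assert auc == pytest.approx(brute_auc(scores, labels), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
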