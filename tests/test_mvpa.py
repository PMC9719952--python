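import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from switchconn import mvpa
from switchconn.mvpa import (
    SubjectPrediction,
    classification_metrics,
    f_score,
    feature_count_grid,
    loocv_classify,
    permutation_test,
    roc_curve_auc,
    sweep_feature_counts,
)


def _labels(n_pos, n_neg):
    return np.array(["patient"] * n_pos + ["control"] * n_neg)


class TestFScore:
    def test_hand_computed_toy(self):
        X = np.array([[2.0], [4.0], [0.0], [2.0]])
        table = f_score(X, _labels(2, 2))
        assert table.scores[0] == pytest.approx(0.5)

    def test_equal_class_means_score_zero(self):
        X = np.array([[1.0], [3.0], [0.0], [4.0]])  # both class means = grand mean 2
        table = f_score(X, _labels(2, 2))
        assert table.scores[0] == pytest.approx(0.0)

    def test_separated_constant_classes_rank_first(self):
        """Zero variance with separated means is maximally discriminative."""
        X = np.column_stack([
            [1.0, 1.0, 0.0, 0.0],          # constant per class, separated -> inf
            [0.5, 0.5, 0.5, 0.5],          # constant everywhere -> 0
            [2.0, 4.0, 0.0, 2.0],          # finite score 0.5
        ])
        table = f_score(X, _labels(2, 2))
        assert np.isinf(table.scores[0])
        assert table.scores[1] == 0.0
        assert list(table.ranking) == [0, 2, 1]

    def test_tie_break_by_ascending_index(self):
        X = np.column_stack([[2.0, 4.0, 0.0, 2.0]] * 3)
        table = f_score(X, _labels(2, 2))
        assert list(table.ranking) == [0, 1, 2]

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            f_score(np.zeros((3, 2)), np.array(["patient", "control", "control"]))

    def test_duplicating_cohort_preserves_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 6))
        y = _labels(5, 5)
        base = f_score(X, y)
        doubled = f_score(np.vstack([X, X]), np.concatenate([y, y]))
        # class means unchanged; variances shrink uniformly, ranking preserved
        assert np.array_equal(base.ranking, doubled.ranking)


class TestLOOCV:
    def test_perfectly_separating_feature_gives_full_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 20))
        X[:, 7] = np.concatenate([np.ones(8), -np.ones(8)]) + rng.normal(0, 0.01, 16)
        records = loocv_classify(X, _labels(8, 8), k=1)
        accuracy, _, _ = classification_metrics(records)
        assert accuracy == 100.0

    def test_feature_ranking_uses_training_fold_only(self):
        """A deliberately leaky ranking inflates accuracy on pure noise."""
        y = _labels(10, 10)
        clean_acc, leaky_acc = [], []
        for seed in range(5):
            X = np.random.default_rng(100 + seed).normal(size=(20, 300))
            records = loocv_classify(X, y, k=5)
            clean_acc.append(classification_metrics(records)[0])
            # leaky variant: rank once using ALL subjects including the test one
            keep = f_score(X, y).top(5)
            leaky = []
            for i in range(20):
                mask = np.ones(20, bool)
                mask[i] = False
                train_X, test_X = mvpa._standardize(X[np.ix_(mask, keep)], X[i, keep][None, :])
                pred, score = mvpa._fit_predict(train_X, y[mask], test_X, C=1.0)
                leaky.append(SubjectPrediction(i, str(y[i]), pred, score))
            leaky_acc.append(classification_metrics(leaky)[0])
        assert np.mean(leaky_acc) > np.mean(clean_acc) + 10.0

    def test_invalid_feature_count_rejected(self):
        with pytest.raises(ValueError, match="k must lie"):
            loocv_classify(np.zeros((8, 4)), _labels(4, 4), k=5)


class TestSweep:
    def test_grid_arithmetic_matches_dimension(self):
        grid = feature_count_grid(24531, 20, 20)
        assert grid[0] == 20
        assert grid[-1] == 24520
        assert grid[206] == 4140  # step 207 of the sweep

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            feature_count_grid(10, 20, 20)

    def test_smallest_k_at_tied_maximum(self):
        """When all grid values tie, the smallest feature count is selected."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 6))
        X[:, 0] = np.concatenate([np.ones(6), -np.ones(6)])
        result = sweep_feature_counts(X, _labels(6, 6), grid_start=1, grid_step=1)
        assert np.all(result.accuracy_by_feature_count == 100.0)
        assert result.selected_feature_count == 1

    def test_summary_recomputable_from_records(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 8))
        result = sweep_feature_counts(X, _labels(5, 5), grid_start=2, grid_step=3)
        acc, sens, spec = classification_metrics(result.records)
        assert result.accuracy == acc
        assert result.sensitivity == sens
        assert result.specificity == spec


class TestMetrics:
    def test_all_correct(self):
        records = [SubjectPrediction(i, lab, lab, s)
                   for i, (lab, s) in enumerate([("patient", 1.0), ("patient", 2.0),
                                                 ("control", -1.0), ("control", -2.0)])]
        assert classification_metrics(records) == (100.0, 100.0, 100.0)

    def test_hand_computed_confusion(self):
        """TP=3, TN=2, FP=1, FN=2 -> 62.5% / 60.0% / 66.7%."""
        records = (
            [SubjectPrediction(i, "patient", "patient", 1.0) for i in range(3)]
            + [SubjectPrediction(3 + i, "patient", "control", -1.0) for i in range(2)]
            + [SubjectPrediction(5 + i, "control", "control", -1.0) for i in range(2)]
            + [SubjectPrediction(7, "control", "patient", 1.0)]
        )
        accuracy, sensitivity, specificity = classification_metrics(records)
        assert accuracy == pytest.approx(62.5)
        assert sensitivity == pytest.approx(60.0)
        assert specificity == pytest.approx(200 / 3)

    def test_everything_predicted_patient(self):
        records = [SubjectPrediction(0, "patient", "patient", 1.0),
                   SubjectPrediction(1, "patient", "patient", 1.0),
                   SubjectPrediction(2, "control", "patient", 1.0)]
        accuracy, sensitivity, specificity = classification_metrics(records)
        assert sensitivity == 100.0
        assert specificity == 0.0

    def test_missing_class_rejected(self):
        records = [SubjectPrediction(0, "patient", "patient", 1.0),
                   SubjectPrediction(1, "patient", "control", -1.0)]
        with pytest.raises(ValueError, match="specificity"):
            classification_metrics(records)


class TestROC:
    def _records(self, pos_scores, neg_scores):
        recs = [SubjectPrediction(i, "patient", "patient", s)
                for i, s in enumerate(pos_scores)]
        recs += [SubjectPrediction(len(recs) + i, "control", "control", s)
                 for i, s in enumerate(neg_scores)]
        return recs

    def test_perfect_separation(self):
        _, auc = roc_curve_auc(self._records([2.0, 3.0], [-1.0, 0.0]))
        assert auc == 1.0

    def test_hand_computed_pairwise(self):
        """Patients (2, 3) vs controls (1, 2.5): 3 wins of 4 pairs -> 0.75."""
        _, auc = roc_curve_auc(self._records([2.0, 3.0], [1.0, 2.5]))
        assert auc == pytest.approx(0.75)

    def test_matches_independent_auc_with_ties(self):
        rng = np.random.default_rng(4)
        scores = np.round(rng.normal(size=30), 1)  # rounding forces ties
        y = rng.integers(0, 2, size=30)
        y[:2], y[-2:] = 1, 0  # ensure both classes
        labels = np.where(y == 1, "patient", "control")
        records = [SubjectPrediction(i, labels[i], labels[i], scores[i])
                   for i in range(30)]
        _, auc = roc_curve_auc(records)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_curve_spans_unit_square(self):
        points, _ = roc_curve_auc(self._records([1.0, 0.2], [0.5, -1.0]))
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    def test_constant_scores_chance_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            _, auc = roc_curve_auc(self._records([1.0, 1.0], [1.0, 1.0]))
        assert auc == 0.5


class TestPermutation:
    def test_strict_count_boundaries(self):
        """p uses a strict > count: 0 when never exceeded, 1 when always."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 10))
        y = _labels(6, 6)
        below = permutation_test(X, y, k_selected=3, n_permutations=19, seed=0,
                                 observed_accuracy=-1.0)
        assert below.p_value == 1.0
        above = permutation_test(X, y, k_selected=3, n_permutations=19, seed=0,
                                 observed_accuracy=101.0)
        assert above.p_value == 0.0
        assert np.array_equal(below.null_accuracies, above.null_accuracies)

    def test_separable_groups_significant(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 40))
        X[:10, :5] += 2.5
        y = _labels(10, 10)
        records = loocv_classify(X, y, k=5)
        acc, _, _ = classification_metrics(records)
        result = permutation_test(X, y, k_selected=5, n_permutations=99, seed=7,
                                  observed_accuracy=acc)
        assert result.p_value < 0.05
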