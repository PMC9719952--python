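"""Connectome-based group classification.

Discriminates patients from controls using whole-brain FC feature
vectors: features are ranked by F-score *within each training fold*, the
top k are fed to a linear support-vector machine (C = 1), and
performance is assessed by leave-one-out cross-validation.  The feature
count k is chosen by sweeping a grid (default 20 to one step below the
feature dimension, step 20) and taking the smallest k that attains the
maximum LOOCV accuracy.  Significance of the observed accuracy comes
from a label-permutation null: p is the fraction of permutations whose
accuracy strictly exceeds the observed one.

The per-feature F-score is

    F(i) = [(m_i+ - m_i)^2 + (m_i- - m_i)^2] / (s2_i+ + s2_i-)

where m_i is the grand mean of feature i, m_i+/- the class means, and
s2_i+/- the class sample variances (n-1 denominators).  Higher F means
more discriminative; ranking is by descending F with index order
breaking ties.  Patients are the positive class throughout, so
sensitivity is the fraction of patients correctly identified and
specificity the fraction of controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

POSITIVE = "patient"
NEGATIVE = "control"


@dataclass
class FScoreTable:
    """Per-feature discriminability scores and the induced ranking."""

    scores: np.ndarray
    ranking: np.ndarray

    def top(self, k: int) -> np.ndarray:
        """Indices of the k highest-scoring features."""
        if not 1 <= k <= self.ranking.size:
            raise ValueError(f"k must lie in [1, {self.ranking.size}]")
        return self.ranking[:k]


@dataclass
class SubjectPrediction:
    subject: int
    true_label: str
    predicted_label: str
    decision_score: float


@dataclass
class ClassificationResult:
    """LOOCV outcome at the selected feature count plus the sweep curve."""

    records: list[SubjectPrediction]
    selected_feature_count: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    feature_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    accuracy_by_feature_count: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None


def _as_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = set(np.unique(labels).tolist())
    if classes != {POSITIVE, NEGATIVE}:
        raise ValueError(
            f"labels must contain exactly the classes {POSITIVE!r} and "
            f"{NEGATIVE!r}; got {sorted(map(str, classes))}"
        )
    return labels


def f_score(features: np.ndarray, labels) -> FScoreTable:
    """Rank features by between-group separation over within-group variance.

    Requires at least 2 subjects per class.  Degenerate denominators:
    zero within-class variance with a nonzero numerator scores +inf
    (maximally discriminative, ranked first); zero numerator and
    denominator scores 0.
    """
    X = np.asarray(features, dtype=float)
    y = _as_labels(labels)
    pos, neg = y == POSITIVE, y == NEGATIVE
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("each class needs at least 2 subjects for the F-score")
    grand = X.mean(axis=0)
    mean_pos = X[pos].mean(axis=0)
    mean_neg = X[neg].mean(axis=0)
    num = (mean_pos - grand) ** 2 + (mean_neg - grand) ** 2
    denom = X[pos].var(axis=0, ddof=1) + X[neg].var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / denom
    scores[(denom == 0) & (num > 0)] = np.inf
    scores[(denom == 0) & (num == 0)] = 0.0
    ranking = np.lexsort((np.arange(scores.size), -scores))
    return FScoreTable(scores=scores, ranking=ranking)


class _FoldScorer:
    """Training-fold F-score rankings via leave-one-out sum updates.

    Maintains per-class feature sums and sums of squares over all
    subjects; each fold subtracts the held-out subject from its class,
    so the scores use exclusively training-fold statistics while
    costing O(n_features) per fold.  Rankings agree with
    :func:`f_score` on the training fold (up to floating-point
    reordering of exact ties in the two variance formulas).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.pos = y == POSITIVE
        self.X2 = X * X
        self.sums = {c: X[self.pos == c].sum(axis=0) for c in (True, False)}
        self.sq = {c: self.X2[self.pos == c].sum(axis=0) for c in (True, False)}
        self.counts = {c: int((self.pos == c).sum()) for c in (True, False)}

    def ranking(self, held_out: int) -> np.ndarray:
        cls = bool(self.pos[held_out])
        sums = dict(self.sums)
        sq = dict(self.sq)
        counts = dict(self.counts)
        sums[cls] = sums[cls] - self.X[held_out]
        sq[cls] = sq[cls] - self.X2[held_out]
        counts[cls] -= 1
        if counts[True] < 2 or counts[False] < 2:
            raise ValueError("each training fold needs at least 2 subjects per class")
        mean_pos = sums[True] / counts[True]
        mean_neg = sums[False] / counts[False]
        grand = (sums[True] + sums[False]) / (counts[True] + counts[False])
        var_pos = np.maximum(sq[True] - sums[True] ** 2 / counts[True], 0.0) / (counts[True] - 1)
        var_neg = np.maximum(sq[False] - sums[False] ** 2 / counts[False], 0.0) / (counts[False] - 1)
        num = (mean_pos - grand) ** 2 + (mean_neg - grand) ** 2
        denom = var_pos + var_neg
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = num / denom
        scores[(denom == 0) & (num > 0)] = np.inf
        scores[(denom == 0) & (num == 0)] = 0.0
        return np.lexsort((np.arange(scores.size), -scores))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _fit_predict(
    train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray, C: float
) -> tuple[str, float]:
    clf = SVC(kernel="linear", C=C)
    clf.fit(train_X, (train_y == POSITIVE).astype(int))
    score = float(clf.decision_function(test_X)[0])
    pred = POSITIVE if clf.predict(test_X)[0] == 1 else NEGATIVE
    return pred, score


def loocv_classify(
    features: np.ndarray,
    labels,
    k: int,
    C: float = 1.0,
    standardize: bool = True,
) -> list[SubjectPrediction]:
    """Leave-one-out classification at a fixed feature count.

    For each held-out subject, features are ranked by F-score on the
    training fold only, the top ``k`` kept, optionally standardized to
    the training fold's mean/SD, and a linear SVM (hinge loss, given
    ``C``) is trained and applied to the held-out subject.
    """
    X = np.asarray(features, dtype=float)
    y = _as_labels(labels)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must lie in [1, {X.shape[1]}]")
    scorer = _FoldScorer(X, y)
    records = []
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        keep = scorer.ranking(i)[:k]
        train_X, test_X = X[np.ix_(mask, keep)], X[i, keep][None, :]
        if standardize:
            train_X, test_X = _standardize(train_X, test_X)
        pred, score = _fit_predict(train_X, y[mask], test_X, C)
        records.append(SubjectPrediction(i, str(y[i]), pred, score))
    return records


def feature_count_grid(n_features: int, grid_start: int = 20, grid_step: int = 20) -> np.ndarray:
    """Feature-count sweep grid: grid_start, +grid_step, ... < n_features."""
    if grid_start < 1 or grid_step < 1:
        raise ValueError("grid_start and grid_step must be positive")
    grid = np.arange(grid_start, n_features, grid_step)
    if grid.size == 0:
        raise ValueError(
            f"empty sweep grid: start {grid_start}, step {grid_step}, "
            f"{n_features} features"
        )
    return grid


def sweep_feature_counts(
    features: np.ndarray,
    labels,
    grid_start: int = 20,
    grid_step: int = 20,
    C: float = 1.0,
    standardize: bool = True,
) -> ClassificationResult:
    """LOOCV accuracy over the feature-count grid; keep the best k.

    Per fold the F-score ranking is computed once and reused across the
    grid.  The selected k is the smallest grid value attaining the
    maximum accuracy; the returned records, metrics, and ROC/AUC are
    those of the selected k.
    """
    X = np.asarray(features, dtype=float)
    y = _as_labels(labels)
    grid = feature_count_grid(X.shape[1], grid_start, grid_step)
    n = X.shape[0]
    scorer = _FoldScorer(X, y)
    preds = np.empty((grid.size, n), dtype=object)
    scores = np.empty((grid.size, n))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ranking = scorer.ranking(i)
        for g, k in enumerate(grid):
            keep = ranking[:k]
            train_X, test_X = X[np.ix_(mask, keep)], X[i, keep][None, :]
            if standardize:
                train_X, test_X = _standardize(train_X, test_X)
            preds[g, i], scores[g, i] = _fit_predict(train_X, y[mask], test_X, C)
    accuracies = np.array([
        100.0 * np.mean([preds[g, i] == y[i] for i in range(n)])
        for g in range(grid.size)
    ])
    best = int(np.argmax(accuracies))  # argmax returns the first (smallest k) maximum
    records = [
        SubjectPrediction(i, str(y[i]), preds[best, i], float(scores[best, i]))
        for i in range(n)
    ]
    accuracy, sensitivity, specificity = classification_metrics(records)
    _, auc = roc_curve_auc(records)
    return ClassificationResult(
        records=records,
        selected_feature_count=int(grid[best]),
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        feature_counts=grid,
        accuracy_by_feature_count=accuracies,
    )


def classification_metrics(records: list[SubjectPrediction]) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity (percent); patients positive.

    Accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN) over
    patients; specificity = TN/(TN+FP) over controls.
    """
    if not records:
        raise ValueError("no prediction records")
    tp = sum(r.true_label == POSITIVE and r.predicted_label == POSITIVE for r in records)
    fn = sum(r.true_label == POSITIVE and r.predicted_label == NEGATIVE for r in records)
    tn = sum(r.true_label == NEGATIVE and r.predicted_label == NEGATIVE for r in records)
    fp = sum(r.true_label == NEGATIVE and r.predicted_label == POSITIVE for r in records)
    if tp + fn == 0:
        raise ValueError("no patients present; sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no controls present; specificity undefined")
    accuracy = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    return accuracy, sensitivity, specificity


def roc_curve_auc(records: list[SubjectPrediction]) -> tuple[np.ndarray, float]:
    """ROC from decision scores used as thresholds, and its AUC.

    The curve sweeps every observed score as a threshold (score >=
    threshold predicts patient); the AUC equals the Mann-Whitney
    probability that a random patient's score exceeds a random
    control's, counting ties as one half.
    """
    y = np.array([r.true_label for r in records])
    s = np.array([r.decision_score for r in records], dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("decision scores must be finite")
    pos, neg = s[y == POSITIVE], s[y == NEGATIVE]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required for a ROC curve")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    points = np.array([
        [np.mean(neg >= th), np.mean(pos >= th)] for th in thresholds
    ])
    if np.unique(s).size == 1:
        warnings.warn("constant decision scores; AUC is chance level", stacklevel=2)
        return points, 0.5
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (wins + 0.5 * ties) / (pos.size * neg.size)
    return points, float(auc)


def permutation_test(
    features: np.ndarray,
    labels,
    k_selected: int,
    n_permutations: int = 1000,
    seed: int | None = None,
    C: float = 1.0,
    standardize: bool = True,
    observed_accuracy: float | None = None,
) -> PermutationResult:
    """Label-permutation null for the LOOCV accuracy.

    Each permutation shuffles the group labels and reruns the full
    LOOCV procedure (fold-wise F-score ranking and SVM) at the fixed
    selected feature count.  The p-value is the fraction of
    permutations whose accuracy is strictly greater than the observed
    one — no +1 correction, so a never-exceeded observation gives p = 0
    and an always-exceeded one p = 1.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = _as_labels(labels)
    if observed_accuracy is None:
        records = loocv_classify(features, y, k_selected, C=C, standardize=standardize)
        observed_accuracy, _, _ = classification_metrics(records)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(y)
        rec = loocv_classify(features, perm, k_selected, C=C, standardize=standardize)
        null[p], _, _ = classification_metrics(rec)
    p_value = float(np.sum(null > observed_accuracy) / n_permutations)
    return PermutationResult(
        observed_accuracy=float(observed_accuracy),
        null_accuracies=null,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed if isinstance(seed, int) else None,
    )
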