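"""Correlation-based feature reduction and exhaustive subset-wise Fisher LDA
with leave-one-out cross-validation over repeated seeded runs.

The classifier is Fisher's linear discriminant: w = (S + eps*I)^-1 (mu1 - mu0)
with the pooled within-class covariance S and a projected-midpoint decision
threshold (equal class priors; the cohorts are near-balanced). A ridge eps
is added only when S is singular to working precision. For each subset size
n, every C(F, n) feature subset is scored by LOOCV; the per-run randomness
is exactly the uniform tie-break among subsets attaining the maximal
(integer) count of correct left-out classifications — the fit itself is
deterministic. Repeated runs therefore share one deterministic evaluation
of all subsets and differ only in the seeded tie-break.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

__all__ = [
    "LDAModel",
    "SubsetSearchConfig",
    "SubsetSizeResult",
    "SelectionSummary",
    "mean_abs_correlation",
    "correlation_filter",
    "fit_fisher_lda",
    "loocv_accuracy",
    "best_subset_search",
    "repeated_selection",
    "roc_auc",
]


# ---------------------------------------------------------------------------
# Correlation-based reduction
# ---------------------------------------------------------------------------

def mean_abs_correlation(table) -> pd.Series:
    """Mean |Pearson r| of each feature against every other feature.

    Constant features cannot be correlated; they are assigned score 1.0
    (so any threshold < 1 removes them). Pairs involving a constant feature
    contribute 0 to the other feature's mean.
    """
    X = table.features.to_numpy(dtype=float)
    n, f = X.shape
    if f < 2:
        raise ValueError("need at least 2 features")
    if n < 3:
        raise ValueError("need at least 3 samples")
    constant = np.ptp(X, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.abs(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 0.0)
    scores = corr.sum(axis=1) / (f - 1)
    scores[constant] = 1.0
    return pd.Series(scores, index=table.feature_names, name="mean_abs_correlation")


def correlation_filter(table, threshold: float = 0.45,
                       max_features: int | None = None):
    """Keep exactly the features whose mean |r| score is below ``threshold``.

    Scores are computed once on the full table (single pass); column order
    is preserved. ``max_features`` optionally caps the survivors at the
    lowest-scoring ones (order still preserved), for scaled-down runs.
    """
    scores = mean_abs_correlation(table)
    keep = [name for name in table.feature_names if scores[name] < threshold]
    if not keep:
        raise ValueError(f"correlation filter at {threshold} removed every feature")
    if max_features is not None and len(keep) > max_features:
        best = set(scores[keep].nsmallest(max_features).index)
        keep = [name for name in keep if name in best]
    return table.subset(keep)


# ---------------------------------------------------------------------------
# Fisher LDA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDAModel:
    """Fitted Fisher discriminant; positive scores predict ``classes[1]``."""

    classes: tuple[str, str]
    mu0: np.ndarray
    mu1: np.ndarray
    sigma: np.ndarray
    ridge: float
    w: np.ndarray
    threshold: float

    def decision(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w - self.threshold

    def predict(self, X) -> np.ndarray:
        idx = (self.decision(X) > 0).astype(int)
        return np.asarray(self.classes)[idx]


def _pooled_fit(X0: np.ndarray, X1: np.ndarray) -> tuple[np.ndarray, float, float, np.ndarray, np.ndarray]:
    """Core Fisher fit from the two class sample matrices."""
    n0, n1 = len(X0), len(X1)
    d = X0.shape[1]
    mu0 = X0.mean(axis=0)
    mu1 = X1.mean(axis=0)
    W = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    dof = max(n0 + n1 - 2, 1)
    sigma = W / dof
    ridge = 0.0
    try:
        w = np.linalg.solve(sigma, mu1 - mu0)
        # Reject numerically meaningless solves on singular matrices.
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
        cond = np.linalg.cond(sigma)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        ridge = 1e-6 * float(np.trace(sigma)) / d
        if ridge == 0.0:
            ridge = 1e-12
        w = np.linalg.solve(sigma + ridge * np.eye(d), mu1 - mu0)
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return w, threshold, ridge, mu0, mu1


def fit_fisher_lda(X, y) -> LDAModel:
    """Fit Fisher's LDA on a two-class sample.

    ``y`` may hold any two label values; classes are ordered by sorted label
    (so with {"normal", "tumor"}, positive scores mean tumor). Predictions
    are invariant under per-feature affine rescaling of the inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    m0 = y == classes[0]
    if m0.sum() < 2 or (~m0).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    w, thr, ridge, mu0, mu1 = _pooled_fit(X[m0], X[~m0])
    sigma = ((X[m0] - mu0).T @ (X[m0] - mu0) +
             (X[~m0] - mu1).T @ (X[~m0] - mu1)) / max(len(y) - 2, 1)
    return LDAModel(classes=(str(classes[0]), str(classes[1])),
                    mu0=mu0, mu1=mu1, sigma=sigma, ridge=ridge, w=w,
                    threshold=thr)


def _loocv_scores(X: np.ndarray, y1: np.ndarray) -> np.ndarray:
    """Signed left-out discriminant scores for all N leave-one-out folds.

    ``y1`` is boolean (True = positive class). Positive score predicts the
    positive class. Uses sufficient-statistic downdating per fold.
    """
    N, d = X.shape
    n1 = int(y1.sum())
    n0 = N - n1
    if n0 < 2 or n1 < 2 or N < 4:
        raise ValueError("LOOCV needs N >= 4 with at least 2 samples per class")
    X0, X1 = X[~y1], X[y1]
    s0, s1 = X0.sum(axis=0), X1.sum(axis=0)
    S0, S1 = X0.T @ X0, X1.T @ X1
    scores = np.empty(N)
    eye = np.eye(d)
    for k in range(N):
        x = X[k]
        if y1[k]:
            m1, sum1, Sq1 = n1 - 1, s1 - x, S1 - np.outer(x, x)
            m0, sum0, Sq0 = n0, s0, S0
        else:
            m0, sum0, Sq0 = n0 - 1, s0 - x, S0 - np.outer(x, x)
            m1, sum1, Sq1 = n1, s1, S1
        mu0 = sum0 / m0
        mu1 = sum1 / m1
        W = (Sq0 - m0 * np.outer(mu0, mu0)) + (Sq1 - m1 * np.outer(mu1, mu1))
        sigma = W / max(m0 + m1 - 2, 1)
        try:
            w = np.linalg.solve(sigma, mu1 - mu0)
            if not np.all(np.isfinite(w)) or np.linalg.cond(sigma) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            ridge = 1e-6 * float(np.trace(sigma)) / d
            if ridge == 0.0:
                ridge = 1e-12
            w = np.linalg.solve(sigma + ridge * eye, mu1 - mu0)
        scores[k] = x @ w - w @ (mu0 + mu1) / 2.0
    return scores


def _as_matrix(table) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    X = table.features.to_numpy(dtype=float)
    labels = np.asarray(table.labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y1 = labels == classes[1]
    return X, y1, list(table.feature_names), list(table.sample_ids)


def loocv_accuracy(table, subset: list[str] | tuple[str, ...]) -> tuple[float, np.ndarray]:
    """LOOCV fraction-correct for one feature subset, plus left-out scores.

    Returns exactly N signed scores (one per sample, in table order);
    accuracy is the fraction of left-out samples whose score sign matches
    their class.
    """
    if not subset:
        raise ValueError("empty feature subset")
    X, y1, names, _ = _as_matrix(table)
    cols = [names.index(f) for f in subset]
    scores = _loocv_scores(X[:, cols], y1)
    correct = int(((scores > 0) == y1).sum())
    return correct / len(y1), scores


def best_subset_search(table, n: int, seed: int = 0) -> tuple[tuple[str, ...], float]:
    """Exhaustive LOOCV search over all C(F, n) subsets.

    Ties on the (integer) number of correct classifications are broken
    uniformly at random with the seed; otherwise the search is
    deterministic.
    """
    X, y1, names, _ = _as_matrix(table)
    F = len(names)
    if n > F:
        raise ValueError(f"subset size {n} exceeds {F} features")
    ncorrect, _ = _evaluate_all_subsets(X, y1, F, n)
    best = max(ncorrect.values())
    tied = [s for s, v in ncorrect.items() if v == best]
    rng = np.random.default_rng(seed)
    choice = tied[int(rng.integers(len(tied)))]
    return tuple(names[j] for j in choice), best / len(y1)


def _evaluate_all_subsets(X: np.ndarray, y1: np.ndarray, F: int, n: int):
    """Deterministic LOOCV evaluation of every subset of size n.

    Returns ({subset_index_tuple: n_correct}, {subset_index_tuple: scores}).
    """
    ncorrect: dict[tuple[int, ...], int] = {}
    scores_of: dict[tuple[int, ...], np.ndarray] = {}
    for cols in itertools.combinations(range(F), n):
        scores = _loocv_scores(X[:, cols], y1)
        ncorrect[cols] = int(((scores > 0) == y1).sum())
        scores_of[cols] = scores
    return ncorrect, scores_of


# ---------------------------------------------------------------------------
# Repeated runs and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetSearchConfig:
    """Configuration of the repeated exhaustive search."""

    n_max: int = 5
    runs: int = 100
    corr_threshold: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")

    @property
    def theoretical_max_selections(self) -> int:
        """Largest possible selection count of a single feature over all
        subset sizes and runs (n_max * runs)."""
        return self.n_max * self.runs


@dataclass
class SubsetSizeResult:
    """Results of all runs at one subset size n."""

    n: int
    best_subsets: list[tuple[str, ...]]
    selection_counts: dict[str, int]
    accuracies: np.ndarray
    accuracy_mean: float
    accuracy_sd: float
    misclassification: dict[str, int]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class SelectionSummary:
    """Per-subset-size selection frequencies, accuracies and ROC data."""

    by_n: dict[int, SubsetSizeResult]
    n_samples: int
    sample_ids: list[str]
    feature_names: list[str]
    config: SubsetSearchConfig

    @property
    def theoretical_max_selections(self) -> int:
        return self.config.theoretical_max_selections

    def to_csvs(self, out_dir: str) -> list[str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = []

        def _write(name: str, frame: pd.DataFrame) -> None:
            path = os.path.join(out_dir, name)
            frame.to_csv(path, index=False)
            paths.append(path)

        _write("selection_counts.csv", pd.DataFrame([
            {"feature": f, "n": n, "count": r.selection_counts.get(f, 0)}
            for n, r in sorted(self.by_n.items()) for f in self.feature_names
        ]))
        _write("accuracy.csv", pd.DataFrame([
            {"n": n, "mean": r.accuracy_mean, "sd": r.accuracy_sd}
            for n, r in sorted(self.by_n.items())
        ]))
        _write("misclassification.csv", pd.DataFrame([
            {"sample_id": s, "n": n, "count": r.misclassification.get(s, 0)}
            for n, r in sorted(self.by_n.items()) for s in self.sample_ids
        ]))
        _write("auc.csv", pd.DataFrame([
            {"n": n, "auc": r.auc} for n, r in sorted(self.by_n.items())
        ]))
        for n, r in sorted(self.by_n.items()):
            _write(f"roc_{n}.csv", pd.DataFrame({"fpr": r.fpr, "tpr": r.tpr}))
        return paths


def _run_seed(master: int, n: int, run: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), int(n), int(run)]))


def repeated_selection(table, config: SubsetSearchConfig) -> SelectionSummary:
    """Exhaustive search at each n = 1..n_max, repeated ``runs`` times.

    Subset LOOCV scores are deterministic, so all subsets are evaluated once
    per n and the repeated runs differ only in the seeded uniform tie-break
    among maximal subsets. Per run the chosen subset contributes its
    selection counts, its LOOCV accuracy, one misclassification count for
    every wrongly classified left-out sample, and its pooled left-out
    scores for the ROC curve.
    """
    X, y1, names, ids = _as_matrix(table)
    F = len(names)
    if config.n_max > F:
        raise ValueError(f"n_max={config.n_max} exceeds {F} retained features")

    by_n: dict[int, SubsetSizeResult] = {}
    for n in range(1, config.n_max + 1):
        ncorrect, scores_of = _evaluate_all_subsets(X, y1, F, n)
        best = max(ncorrect.values())
        tied = [s for s, v in ncorrect.items() if v == best]

        best_subsets: list[tuple[str, ...]] = []
        counts: dict[str, int] = {}
        accuracies = np.empty(config.runs)
        miscls: dict[str, int] = {}
        pooled_scores, pooled_labels = [], []
        for run in range(config.runs):
            rng = _run_seed(config.seed, n, run)
            cols = tied[int(rng.integers(len(tied)))]
            subset = tuple(names[j] for j in cols)
            best_subsets.append(subset)
            for f in subset:
                counts[f] = counts.get(f, 0) + 1
            scores = scores_of[cols]
            accuracies[run] = ncorrect[cols] / len(y1)
            wrong = (scores > 0) != y1
            for sid in np.asarray(ids)[wrong]:
                miscls[sid] = miscls.get(sid, 0) + 1
            pooled_scores.append(scores)
            pooled_labels.append(y1.astype(int))
        pooled_scores = np.concatenate(pooled_scores)
        pooled_labels = np.concatenate(pooled_labels)
        (fpr, tpr), auc_value = roc_auc(pooled_scores, pooled_labels)
        by_n[n] = SubsetSizeResult(
            n=n,
            best_subsets=best_subsets,
            selection_counts=counts,
            accuracies=accuracies,
            accuracy_mean=float(accuracies.mean()),
            accuracy_sd=float(accuracies.std()),
            misclassification=miscls,
            pooled_scores=pooled_scores,
            pooled_labels=pooled_labels,
            fpr=fpr,
            tpr=tpr,
            auc=auc_value,
        )
    return SelectionSummary(by_n=by_n, n_samples=len(y1), sample_ids=ids,
                            feature_names=names, config=config)


def roc_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC points by threshold sweep and trapezoidal AUC.

    The AUC equals the Mann-Whitney U normalization (probability that a
    positive outscores a negative, ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("need both class labels")
    y = (labels == uniq[1]).astype(int)
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    return (fpr, tpr), float(_sk_auc(fpr, tpr))
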