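"""Nested cross-validation, incremental feature addition, and evaluation.

The harness mirrors the two-level design used throughout this analysis
family: the outer loop is leave-one-out over subjects (generalization
estimate), the inner loop is stratified 5-fold grid search over SVM
hyperparameters (model selection), so the held-out subject never touches
standardization, feature ranking, or hyperparameter choice.

Within each outer training set, the chosen selector produces a feature
ranking; the SVM then adds features one at a time in ranking order, and the
out-of-fold predictions pooled at each feature count k give an
accuracy/sensitivity/specificity curve over k.  The reported optimal k is
the pooled-curve argmax (smallest k on ties).  Decision values at the
optimal k feed the ROC curve, whose trapezoidal area equals the normalized
Mann-Whitney U statistic.

Confusion-matrix metrics, with the patient group as the positive class:

    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Leakage policy: by default the ranking is recomputed inside every outer
training fold (``leak_free``).  An optional ``paper_compat`` mode ranks
once on the full dataset before the outer loop — the optimistic variant
many published pipelines describe ambiguously — and is clearly flagged in
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_model import CorticalFeatureTable, FeatureLabel, GroupComparison, subset
from .selection import (
    FeatureRanking,
    scdrm_fit,
    scdrm_rank,
    standardize_apply,
    standardize_fit,
    svm_rfe,
    ttest_rank,
)

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "CVConfig",
    "CVEvaluation",
    "compute_metrics",
    "compute_roc",
    "nested_cv_evaluate",
    "rank_features_matrix",
    "reduced_cv_config",
]

METHODS = ("ttest", "scdrm", "svmrfe")


class StratificationError(ValueError):
    """An inner fold cannot be formed with both classes present."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled confusion-matrix counts; patients are the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class Metrics:
    """Accuracy/sensitivity/specificity as proportions; None when the
    corresponding denominator is zero (undefined, not NaN)."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in (
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
            )
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Exact confusion-matrix ratios; undefined ratios become None."""
    if counts.total == 0:
        raise ValueError("no evaluated subjects")
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    return Metrics(
        accuracy=(counts.TP + counts.TN) / counts.total,
        sensitivity=counts.TP / pos if pos > 0 else None,
        specificity=counts.TN / neg if neg > 0 else None,
    )


def compute_roc(scores: np.ndarray, labels: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points by threshold sweep and trapezoidal AUC.

    ``labels`` are binary with 1 = positive; higher scores mean more
    positive.  The returned AUC equals the Mann-Whitney U statistic
    normalized by (number of positives x number of negatives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite decision scores")
    if len(np.unique(labels)) != 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Settings for the nested CV harness.

    The SVM grid defaults to the canonical LIBSVM ranges (linear and RBF
    kernels, C = 2^-5..2^15, gamma = 2^-15..2^3, log2-spaced).  ``max_k``
    caps the incremental curve length; ``None`` evaluates every prefix.
    """

    kernels: tuple[str, ...] = ("linear", "rbf")
    C_grid: tuple[float, ...] = tuple(float(2.0**k) for k in range(-5, 16, 2))
    gamma_grid: tuple[float, ...] = tuple(float(2.0**k) for k in range(-15, 4, 2))
    inner_folds: int = 5
    max_k: int | None = None
    alpha: float = 0.05
    lambda_grid: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1, 0.5, 1.0)
    scdrm_tol: float = 1e-6
    scdrm_max_iter: int = 200
    rfe_step: int = 1
    rfe_C: float = 1.0
    leakage_mode: str = "leak_free"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leakage_mode not in ("leak_free", "paper_compat"):
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")

    def candidates(self) -> list[dict]:
        out = []
        for kernel in self.kernels:
            for C in self.C_grid:
                if kernel == "linear":
                    out.append({"kernel": "linear", "C": C})
                else:
                    out.extend(
                        {"kernel": kernel, "C": C, "gamma": g} for g in self.gamma_grid
                    )
        return out


def reduced_cv_config(**overrides) -> CVConfig:
    """A deliberately small harness configuration for simulation studies:
    linear kernel, coarse C grid, short incremental curve, two-point
    lambda grid.  Keeps leave-one-out tractable at cohort scale."""
    base = dict(
        kernels=("linear",),
        C_grid=(1.0,),
        gamma_grid=(),
        max_k=30,
        lambda_grid=(0.01, 0.1),
        scdrm_max_iter=50,
    )
    base.update(overrides)
    return CVConfig(**base)


def _fold_seed(seed: int, fold: int, k: int = 0) -> int:
    return (seed * 1_000_003 + fold * 1_009 + k * 7) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Feature ranking on fold matrices
# ---------------------------------------------------------------------------

def _one_hot(y: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def _inner_cv_accuracy(
    X: np.ndarray, y: np.ndarray, params: dict, inner_folds: int, seed: int
) -> float:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise StratificationError("inner CV needs >= 2 subjects of each class")
    n_splits = min(inner_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    for tr, va in skf.split(X, y):
        clf = SVC(**params)
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[va]) == y[va]).sum())
    return correct / len(y)


def _grid_search(
    X: np.ndarray, y: np.ndarray, candidates: list[dict], inner_folds: int, seed: int
) -> dict:
    """Pick SVM hyperparameters by inner stratified CV accuracy; ties go to
    the earlier candidate (linear before RBF, smaller C/gamma first)."""
    if len(candidates) == 1:
        return candidates[0]
    best, best_acc = candidates[0], -1.0
    for params in candidates:
        acc = _inner_cv_accuracy(X, y, params, inner_folds, seed)
        if acc > best_acc:
            best, best_acc = params, acc
    return best


def rank_features_matrix(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    config: CVConfig,
    labels: Sequence[FeatureLabel] | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Run one selector on an (already standardized) training matrix.

    ``y`` is binary with 1 = positive class.  For SCDRM, lambda is chosen
    from ``config.lambda_grid`` by inner-CV accuracy of a linear SVM on the
    top-ranked features (ties to the smaller lambda).
    """
    if method == "ttest":
        return ttest_rank(X[y == 1], X[y == 0], alpha=config.alpha, labels=labels)
    if method == "svmrfe":
        return svm_rfe(X, y, C=config.rfe_C, step=config.rfe_step, labels=labels)
    if method == "scdrm":
        Y = _one_hot(y)
        grid = config.lambda_grid
        if len(grid) == 1:
            model = scdrm_fit(X, Y, grid[0], tol=config.scdrm_tol, max_iter=config.scdrm_max_iter)
            return scdrm_rank(model, labels=labels)
        best_rank, best_acc, best_lam = None, -1.0, None
        m = min(20, X.shape[1])
        for lam in grid:
            model = scdrm_fit(X, Y, lam, tol=config.scdrm_tol, max_iter=config.scdrm_max_iter)
            ranking = scdrm_rank(model, labels=labels)
            feats = ranking.order[:m]
            acc = _inner_cv_accuracy(
                X[:, feats], y, {"kernel": "linear", "C": 1.0}, config.inner_folds, seed
            )
            if acc > best_acc:
                best_rank, best_acc, best_lam = ranking, acc, lam
        return best_rank
    raise ValueError(f"unknown selection method {method!r} (expected one of {METHODS})")


# ---------------------------------------------------------------------------
# Outer fold evaluation
# ---------------------------------------------------------------------------

def evaluate_outer_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    method: str,
    config: CVConfig,
    k_values: Sequence[int],
    labels: Sequence[FeatureLabel] | None = None,
    fold_index: int = 0,
    ranking: FeatureRanking | None = None,
) -> tuple[np.ndarray, np.ndarray, FeatureRanking]:
    """Fit one outer fold and predict held-out rows at each feature count.

    Everything fitted here (standardization, ranking, hyperparameters, SVM)
    uses ``X_train``/``y_train`` only; ``X_test`` rows are transformed and
    scored but never touch fitting.  Returns (predictions, decision scores)
    of shape (n_test, len(k_values)) plus the ranking used.
    """
    mean, sd = standardize_fit(X_train)
    Xtr = standardize_apply(X_train, mean, sd)
    Xte = standardize_apply(np.atleast_2d(X_test), mean, sd)
    if ranking is None:
        ranking = rank_features_matrix(
            Xtr, y_train, method, config, labels=labels, seed=_fold_seed(config.seed, fold_index)
        )
    # Fall back to the full ranking order when the selector retains nothing.
    available = ranking.retained if len(ranking.retained) else ranking.order
    candidates = config.candidates()
    preds = np.empty((Xte.shape[0], len(k_values)), dtype=int)
    scores = np.empty((Xte.shape[0], len(k_values)))
    for kk, k in enumerate(k_values):
        feats = available[: min(k, len(available))]
        params = _grid_search(
            Xtr[:, feats], y_train, candidates, config.inner_folds,
            _fold_seed(config.seed, fold_index, k),
        )
        clf = SVC(**params)
        clf.fit(Xtr[:, feats], y_train)
        preds[:, kk] = clf.predict(Xte[:, feats])
        scores[:, kk] = clf.decision_function(Xte[:, feats])
    return preds, scores, ranking


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------

@dataclass
class CVEvaluation:
    """Pooled leave-one-out results for one (comparison, method) cell."""

    comparison: GroupComparison
    method: str
    k_values: list[int]
    curve: list[Metrics]
    counts: list[ConfusionCounts]
    optimal_k: int
    optimal_metrics: Metrics
    decision_scores: np.ndarray = field(repr=False)
    y_true: np.ndarray = field(repr=False)
    roc: list[tuple[float, float]] = field(repr=False)
    auc: float = 0.0
    leakage_mode: str = "leak_free"

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison.name,
            "method": self.method,
            "leakage_mode": self.leakage_mode,
            "k_values": list(self.k_values),
            "curve": [m.as_percent() for m in self.curve],
            "counts": [
                {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN} for c in self.counts
            ],
            "optimal_k": self.optimal_k,
            "optimal_metrics": self.optimal_metrics.as_percent(),
            "decision_scores": self.decision_scores.tolist(),
            "y_true": self.y_true.tolist(),
            "roc": [[float(a), float(b)] for a, b in self.roc],
            "auc": self.auc,
        }


def pooled_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(((y_pred == 1) & (y_true == 1)).sum()),
        TN=int(((y_pred == 0) & (y_true == 0)).sum()),
        FP=int(((y_pred == 1) & (y_true == 0)).sum()),
        FN=int(((y_pred == 0) & (y_true == 1)).sum()),
    )


def nested_cv_evaluate(
    table: CorticalFeatureTable,
    comparison: GroupComparison,
    method: str,
    config: CVConfig | None = None,
) -> CVEvaluation:
    """Leave-one-out nested CV with incremental feature addition.

    The table is first restricted to the comparison's two groups (features
    are used as given; subset measures beforehand if needed).  Returns the
    pooled metrics curve over feature counts, the optimal count, and the
    ROC/AUC of the pooled out-of-fold decision values at that count.
    """
    if config is None:
        config = CVConfig()
    if method not in METHODS:
        raise ValueError(f"unknown selection method {method!r} (expected one of {METHODS})")
    sub = subset(table, comparison)
    y = (sub.groups == comparison.positive_group).astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("each group needs at least 2 subjects for LOOCV")
    if config.leakage_mode == "paper_compat":
        warnings.warn(
            "paper_compat mode ranks features on the full dataset before the "
            "outer loop; reported accuracies are optimistically biased",
            UserWarning,
            stacklevel=2,
        )
    n, d = sub.values.shape
    K = min(config.max_k, d) if config.max_k else d
    k_values = list(range(1, K + 1))

    full_ranking = None
    if config.leakage_mode == "paper_compat":
        mean, sd = standardize_fit(sub.values)
        full_ranking = rank_features_matrix(
            standardize_apply(sub.values, mean, sd), y, method, config,
            labels=sub.labels, seed=_fold_seed(config.seed, 0),
        )

    preds = np.empty((n, K), dtype=int)
    scores = np.empty((n, K))
    for i in range(n):
        tr = np.arange(n) != i
        p, s, _ = evaluate_outer_fold(
            sub.values[tr], y[tr], sub.values[i], method, config, k_values,
            labels=sub.labels, fold_index=i, ranking=full_ranking,
        )
        preds[i] = p[0]
        scores[i] = s[0]

    counts = [pooled_counts(y, preds[:, kk]) for kk in range(K)]
    curve = [compute_metrics(c) for c in counts]
    accs = np.asarray([m.accuracy for m in curve])
    optimal_idx = int(np.argmax(accs))  # argmax returns the first (smallest k) tie
    optimal_k = k_values[optimal_idx]
    decision = scores[:, optimal_idx]
    roc, auc = compute_roc(decision, y)
    return CVEvaluation(
        comparison=comparison,
        method=method,
        k_values=k_values,
        curve=curve,
        counts=counts,
        optimal_k=optimal_k,
        optimal_metrics=curve[optimal_idx],
        decision_scores=decision,
        y_true=y,
        roc=roc,
        auc=auc,
        leakage_mode=config.leakage_mode,
    )
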