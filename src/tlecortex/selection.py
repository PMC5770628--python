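"""The three feature-ranking engines.

* ``ttest_filter`` — univariate filter: per-feature pooled-variance
  two-sample t statistic

      T = (mean1 - mean2) / sqrt( ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2)
                                  * (1/n1 + 1/n2) ),

  two-sided p at n1+n2-2 degrees of freedom; features with p below the
  significance level are retained and ranked by ascending p.

* ``scdrm_fit`` / ``scdrm_rank`` — the sparse-constrained dimensionality
  reduction model: minimize over the d x c weight matrix W

      J(W) = ||X W - Y||_{2,1} + lambda * ||W||_{2,1},

  where the l2,1 norm sums Euclidean norms of matrix rows and Y is the
  one-hot class-label matrix.  The row-structured penalty zeroes whole
  feature rows of W, so the row norm ||w_i||_2 scores feature i.  The
  problem is convex but nonsmooth; it is solved by iteratively reweighted
  least squares (IRLS): each iteration forms diagonal reweighting matrices
  with entries 1/(2 max(||row||_2, eps)) for the residual and weight rows
  and solves the resulting regularized least-squares system, which
  monotonically decreases the eps-smoothed objective.

* ``svm_rfe`` — recursive feature elimination with a linear soft-margin
  SVM: repeatedly train on the surviving features, score each by the
  squared primal weight w_j^2, drop the lowest-scoring features, and rank
  features by reverse elimination order.

All engines assume features have been standardized (z-scored with training
statistics); the cross-validation harness does this per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .data_model import CorticalFeatureTable, FeatureLabel, GroupComparison

__all__ = [
    "TTestResult",
    "SCDRMModel",
    "FeatureRanking",
    "standardize_fit",
    "standardize_apply",
    "ttest_statistics",
    "ttest_rank",
    "ttest_filter",
    "scdrm_fit",
    "scdrm_objective",
    "scdrm_rank",
    "svm_rfe",
]


@dataclass
class TTestResult:
    """Per-feature two-sample t statistics (arrays over features)."""

    t: np.ndarray
    p: np.ndarray
    mean1: np.ndarray
    mean2: np.ndarray
    sd1: np.ndarray
    sd2: np.ndarray
    n1: int
    n2: int

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


@dataclass
class SCDRMModel:
    """Fitted sparse-regression weight matrix with its solver trace."""

    W: np.ndarray
    lam: float
    objective_trace: np.ndarray
    converged: bool
    iterations: int

    @property
    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.W, axis=1)


@dataclass
class FeatureRanking:
    """An ordered permutation of feature indices, most important first.

    ``scores`` are on the method's native scale, aligned with ``order``
    (p-value ascending for the t filter, row norm descending for SCDRM,
    elimination rank descending for RFE).  ``retained`` is the subset of
    feature indices surviving the method's own filter criterion.
    """

    method: str
    order: np.ndarray
    scores: np.ndarray
    retained: np.ndarray
    labels: list[FeatureLabel] | None = None
    stats: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        self.retained = np.asarray(self.retained, dtype=int)
        d = len(self.order)
        if sorted(self.order.tolist()) != list(range(d)):
            raise ValueError("order must be a permutation of feature indices")
        if len(self.scores) != d:
            raise ValueError("scores must align with order")
        if not set(self.retained.tolist()) <= set(range(d)):
            raise ValueError("retained must be a subset of feature indices")

    @property
    def n_features(self) -> int:
        return len(self.order)

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "order": self.order.tolist(),
            "scores": self.scores.tolist(),
            "retained": self.retained.tolist(),
        }
        if self.labels is not None:
            d["labels"] = [str(self.labels[i]) for i in self.order]
        return d


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean/SD for z-scoring; zero-variance features get SD 1."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def standardize_apply(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd


# ---------------------------------------------------------------------------
# t-test filter
# ---------------------------------------------------------------------------

def ttest_statistics(X1: np.ndarray, X2: np.ndarray) -> TTestResult:
    """Pooled-variance two-sample t per column of two group matrices.

    Features with zero pooled variance get p := 1 (T is 0 when the means
    also coincide, +-inf otherwise).
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        raise ValueError("t statistic needs at least one subject per group and df >= 1")
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    # a single-subject group contributes zero to the pooled variance (n-1 = 0)
    s1 = X1.std(axis=0, ddof=1) if n1 > 1 else np.zeros(X1.shape[1])
    s2 = X2.std(axis=0, ddof=1) if n2 > 1 else np.zeros(X2.shape[1])
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, np.where(m1 == m2, 0.0, np.inf * np.sign(m1 - m2)))
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(np.where(se > 0, t, 0.0)), df), 1.0)
    return TTestResult(t=t, p=p, mean1=m1, mean2=m2, sd1=s1, sd2=s2, n1=n1, n2=n2)


def _canonical_key(labels: Sequence[FeatureLabel] | None, d: int) -> np.ndarray:
    if labels is None:
        return np.arange(d)
    return np.asarray([l.canonical_index for l in labels])


def ttest_rank(
    X1: np.ndarray,
    X2: np.ndarray,
    alpha: float = 0.05,
    labels: Sequence[FeatureLabel] | None = None,
) -> FeatureRanking:
    """Rank columns by two-sample t-test p-value between two group matrices.

    Retains features with p < ``alpha``; orders by ascending p, ties broken
    by descending |T| then canonical label order.
    """
    res = ttest_statistics(X1, X2)
    d = len(res.p)
    key = _canonical_key(labels, d)
    abs_t = np.abs(np.nan_to_num(res.t, posinf=np.inf, neginf=-np.inf))
    # np.lexsort: last key is primary.
    order = np.lexsort((key, -abs_t, res.p))
    retained = order[res.p[order] < alpha]
    return FeatureRanking(
        method="ttest",
        order=order,
        scores=res.p[order],
        retained=retained,
        labels=list(labels) if labels is not None else None,
        stats=res,
    )


def ttest_filter(
    table: CorticalFeatureTable,
    comparison: GroupComparison,
    alpha: float = 0.05,
) -> FeatureRanking:
    """:func:`ttest_rank` applied to the two groups of a feature table."""
    mask1 = table.group_mask(comparison.positive_group)
    mask2 = table.group_mask(comparison.negative_group)
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError(f"comparison {comparison.name} needs >= 2 subjects per group")
    return ttest_rank(table.values[mask1], table.values[mask2], alpha=alpha, labels=table.labels)


# ---------------------------------------------------------------------------
# SCDRM (l2,1-loss + l2,1-penalty sparse regression)
# ---------------------------------------------------------------------------

def scdrm_objective(X: np.ndarray, Y: np.ndarray, W: np.ndarray, lam: float, eps: float = 0.0) -> float:
    """J(W) = ||XW - Y||_{2,1} + lam ||W||_{2,1}, optionally eps-smoothed."""
    R = X @ W - Y
    loss = np.sum(np.sqrt(np.sum(R**2, axis=1) + eps**2))
    pen = np.sum(np.sqrt(np.sum(W**2, axis=1) + eps**2))
    return float(loss + lam * pen)


def scdrm_fit(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 200,
    eps: float = 1e-8,
) -> SCDRMModel:
    """Fit the l2,1-loss / l2,1-penalty model by IRLS.

    Each iteration solves the reweighted ridge system

        (X^T D_a X + lam * D_b) W = X^T D_a Y,

    with D_a = diag(1/max(||r_i||, eps)) over residual rows and
    D_b = diag(1/max(||w_j||, eps)) over weight rows; when d > n the system
    is solved in the n-dimensional dual via the push-through identity.
    Iteration stops when the relative change of the eps-smoothed objective
    drops below ``tol``.  W is initialized by ridge regression.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(Y).all():
        raise ValueError("non-finite input to scdrm_fit")
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    n, d = X.shape
    c = Y.shape[1]
    ridge = max(lam, 1e-8)
    W = np.linalg.solve(X.T @ X + ridge * np.eye(d), X.T @ Y)

    trace = [scdrm_objective(X, Y, W, lam, eps=eps)]
    converged = False
    it = 0
    lam_eff = max(lam, 1e-12)  # keeps the reweighted system nonsingular at lam=0
    for it in range(1, max_iter + 1):
        R = X @ W - Y
        a = np.sqrt(np.sum(R**2, axis=1) + eps**2)  # residual row norms, floored
        b = np.sqrt(np.sum(W**2, axis=1) + eps**2)  # weight row norms, floored
        inv_a = 1.0 / a
        inv_b = 1.0 / b
        if d <= n:
            A = (X.T * inv_a) @ X + lam_eff * np.diag(inv_b)
            W = np.linalg.solve(A, (X.T * inv_a) @ Y)
        else:
            # push-through identity: W = diag(b) X^T (X diag(b) X^T + lam diag(a))^{-1} Y
            Xb = X * b  # X @ diag(b)
            K = Xb @ X.T + lam_eff * np.diag(a)
            W = Xb.T @ np.linalg.solve(K, Y)
        trace.append(scdrm_objective(X, Y, W, lam, eps=eps))
        if abs(trace[-2] - trace[-1]) <= tol * max(abs(trace[-2]), 1e-12):
            converged = True
            break
    return SCDRMModel(
        W=W,
        lam=lam,
        objective_trace=np.asarray(trace),
        converged=converged,
        iterations=it,
    )


def scdrm_rank(
    model: SCDRMModel,
    labels: Sequence[FeatureLabel] | None = None,
    retain_eps: float = 1e-6,
) -> FeatureRanking:
    """Rank features by the row norms of W, descending.

    Retains features whose score exceeds ``retain_eps`` times the maximum
    score; an all-zero W retains nothing and orders by canonical label.
    """
    norms = model.row_norms
    d = len(norms)
    key = _canonical_key(labels, d)
    order = np.lexsort((key, -norms))
    max_norm = norms.max() if d else 0.0
    # a W at the solver's eps floor (1e-8) is numerically all-zero
    if max_norm > 1e-8:
        retained = order[norms[order] > retain_eps * max_norm]
    else:
        retained = np.empty(0, dtype=int)
    return FeatureRanking(
        method="scdrm",
        order=order,
        scores=norms[order],
        retained=retained,
        labels=list(labels) if labels is not None else None,
    )


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    step: int = 1,
    labels: Sequence[FeatureLabel] | None = None,
) -> FeatureRanking:
    """Recursive feature elimination with a linear soft-margin SVM.

    Trains on the surviving features, scores each by its squared primal
    weight, removes the ``step`` lowest-scoring features, and repeats.  The
    final order is reverse elimination order (last survivor first); score of
    a feature is its elimination rank (d for the last survivor down to 1).
    Ties in w^2 are broken by canonical label order: the later-canonical
    feature is eliminated first.  All features are retained — downstream
    incremental evaluation decides how many to use.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("svm_rfe requires exactly two classes")
    if step < 1:
        raise ValueError("step must be >= 1")
    n, d = X.shape
    key = _canonical_key(labels, d)
    surviving = list(range(d))
    eliminated: list[int] = []
    while surviving:
        if len(surviving) == 1:
            eliminated.append(surviving.pop())
            break
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, surviving], y)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        # Eliminate lowest w^2 first; among ties the later-canonical feature
        # goes first so earlier-canonical features end up ranked higher.
        sub_order = sorted(
            range(len(surviving)),
            key=lambda j: (w2[j], -key[surviving[j]]),
        )
        n_drop = min(step, len(surviving) - 1)
        # Within one batch, lowest-w^2 features are recorded as eliminated
        # first, keeping the ranking deterministic for step > 1.
        for f in [surviving[j] for j in sub_order[:n_drop]]:
            surviving.remove(f)
            eliminated.append(f)
    order = np.asarray(eliminated[::-1], dtype=int)
    ranks = np.arange(d, 0, -1, dtype=float)  # aligned with order
    return FeatureRanking(
        method="svmrfe",
        order=order,
        scores=ranks,
        retained=order.copy(),
        labels=list(labels) if labels is not None else None,
    )
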