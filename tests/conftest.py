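"""Shared fixtures and the independent SCDRM oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

import tlecortex as tc


def scdrm_oracle_objective(X: np.ndarray, Y: np.ndarray, lam: float, eps: float = 1e-10) -> float:
    """Minimum of the l2,1 + l2,1 objective by a generic smooth convex solver.

    Independent of the package's IRLS path: minimizes the eps-smoothed
    objective sum_i sqrt(||r_i||^2 + eps) + lam * sum_j sqrt(||w_j||^2 + eps)
    with analytic gradients via L-BFGS-B from two starts.
    """
    n, d = X.shape
    c = Y.shape[1]

    def f(w):
        W = w.reshape(d, c)
        R = X @ W - Y
        return float(
            np.sum(np.sqrt(np.sum(R**2, axis=1) + eps))
            + lam * np.sum(np.sqrt(np.sum(W**2, axis=1) + eps))
        )

    def g(w):
        W = w.reshape(d, c)
        R = X @ W - Y
        a = np.sqrt(np.sum(R**2, axis=1) + eps)
        b = np.sqrt(np.sum(W**2, axis=1) + eps)
        return (X.T @ (R / a[:, None]) + lam * W / b[:, None]).ravel()

    starts = [np.zeros(d * c), np.linalg.lstsq(X, Y, rcond=None)[0].ravel()]
    best = np.inf
    for w0 in starts:
        res = minimize(
            f, w0, jac=g, method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
        )
        best = min(best, float(res.fun))
    return best


def random_scdrm_instance(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    n = int(rng.integers(4, 13))
    d = int(rng.integers(2, 13))
    X = rng.normal(size=(n, d))
    y = rng.integers(0, 2, n)
    Y = np.eye(2)[y]
    lam = float(rng.uniform(0.01, 1.0))
    return X, Y, lam


@pytest.fixture(scope="session")
def default_cohort() -> tc.CorticalFeatureTable:
    """One study-condition cohort (133 x 272, 15 planted effects/comparison)."""
    return tc.generate_cohort(tc.default_cohort_spec(seed=7))


@pytest.fixture(scope="session")
def null_cohort() -> tc.CorticalFeatureTable:
    """A cohort with no planted effects (nuisance structure still present)."""
    return tc.generate_cohort(tc.SyntheticCohortSpec(effects=[], seed=11))


@pytest.fixture()
def tiny_table() -> tc.CorticalFeatureTable:
    """3 subjects x 4 features, hand-set values."""
    labels = [
        tc.parse_label("lh_entorhinal_CSA"),
        tc.parse_label("rh_entorhinal_CSA"),
        tc.parse_label("lh_insula_CTh"),
        tc.parse_label("rh_cuneus_GMV"),
    ]
    subjects = [
        tc.SubjectRecord("s1", "LTLE", 25.0, "M", "1.5T"),
        tc.SubjectRecord("s2", "NC", 30.5, "F", "3.0T"),
        tc.SubjectRecord("s3", "NC", 22.25, "M", "1.5T"),
    ]
    values = np.array(
        [[1.5, 2.25, 0.125, 3.0], [2.0, 2.5, 0.25, 4.0], [1.75, 2.125, 0.5, 3.5]]
    )
    return tc.CorticalFeatureTable(subjects=subjects, labels=labels, values=values)
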