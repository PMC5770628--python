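"""Region-level group-difference statistics.

Two-sample t-tests per feature (e.g. the 40 subcortical segmentation
volumes), and a covariate-adjusted variant fitting, per feature, the linear
model ``value ~ group + age + sex`` by least squares and reporting the
group coefficient's t statistic — the region-level analogue of a vertexwise
GLM with age and sex as nuisance factors.

Both accept either a :class:`~tlecortex.data_model.CorticalFeatureTable` or
a plain DataFrame whose first columns are the standard metadata
(``subject_id, group, age, sex, scanner``) followed by feature columns, so
the same functions serve cortical and subcortical tables.

No multiple-comparison correction is applied by default (raw thresholds);
Benjamini-Hochberg is available as a switch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import CorticalFeatureTable, GroupComparison
from .selection import ttest_statistics

__all__ = ["groupwise_ttests", "adjusted_group_test"]

_META = ["subject_id", "group", "age", "sex", "scanner"]


def _extract(table) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    if isinstance(table, CorticalFeatureTable):
        names = [str(l) for l in table.labels]
        meta = table.to_dataframe()[_META]
        return names, table.values, meta
    df = pd.DataFrame(table)
    missing = [c for c in _META if c not in df.columns]
    if missing:
        raise ValueError(f"metadata column(s) {missing} missing from table")
    names = [c for c in df.columns if c not in _META]
    return names, df[names].to_numpy(dtype=float), df[_META]


def groupwise_ttests(
    table,
    comparison: GroupComparison,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-feature two-sample t-tests for one group contrast.

    Returns the features with p <= ``alpha`` (after optional
    Benjamini-Hochberg correction when ``correction="bh"``), sorted by
    ascending p, with columns comparison/feature/t/p/direction, where
    direction is the sign of the patient-minus-control mean difference.
    """
    names, values, meta = _extract(table)
    groups = meta["group"].to_numpy()
    m1 = groups == comparison.positive_group
    m2 = groups == comparison.negative_group
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError(f"comparison {comparison.name} has an empty group in this table")
    res = ttest_statistics(values[m1], values[m2])
    p = res.p
    if correction == "bh":
        p = multipletests(p, method="fdr_bh")[1]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    out = pd.DataFrame(
        {
            "comparison": comparison.name,
            "feature": names,
            "t": res.t,
            "p": p,
            "direction": np.sign(res.mean1 - res.mean2).astype(int),
        }
    )
    out = out[out["p"] <= alpha].sort_values("p", kind="stable").reset_index(drop=True)
    return out


def adjusted_group_test(
    table,
    comparison: GroupComparison,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Covariate-adjusted group comparison per feature.

    Fits ``value ~ intercept + group + covariates`` by ordinary least
    squares for every feature simultaneously and reports the group
    coefficient's t statistic and two-sided p.  Raises on constant or
    collinear design columns, naming the offender.
    """
    names, values, meta = _extract(table)
    groups = meta["group"].to_numpy()
    m1 = groups == comparison.positive_group
    m2 = groups == comparison.negative_group
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError(f"comparison {comparison.name} has an empty group in this table")
    rows = m1 | m2
    sub_meta = meta[rows]
    Yf = values[rows]
    g = (groups[rows] == comparison.positive_group).astype(float)

    cols: list[np.ndarray] = [np.ones(rows.sum()), g]
    col_names = ["intercept", "group"]
    for cov in covariates:
        if cov == "sex":
            x = (sub_meta["sex"].to_numpy() == "M").astype(float)
        elif cov in sub_meta.columns:
            x = sub_meta[cov].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        if np.ptp(x) == 0:
            raise ValueError(f"covariate column {cov!r} is constant")
        cols.append(x)
        col_names.append(cov)
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        # identify the first column that adds no rank
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, : j + 1]) <= np.linalg.matrix_rank(D[:, :j]):
                raise ValueError(f"design column {col_names[j]!r} is collinear")
        raise ValueError("rank-deficient design")

    n, p_dim = D.shape
    beta, _, _, _ = np.linalg.lstsq(D, Yf, rcond=None)
    resid = Yf - D @ beta
    dof = n - p_dim
    sigma2 = (resid**2).sum(axis=0) / dof
    cov_unscaled = np.linalg.inv(D.T @ D)
    se = np.sqrt(cov_unscaled[1, 1] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta[1] / se, 0.0)
    pvals = np.where(se > 0, 2.0 * stats.t.sf(np.abs(tvals), dof), 1.0)
    out = pd.DataFrame(
        {
            "comparison": comparison.name,
            "feature": names,
            "t": tvals,
            "p": pvals,
            "direction": np.sign(beta[1]).astype(int),
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)
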