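"""Weighted sample profile, prevalence tables and association screens.

Covers the descriptive layer of the analysis: weighted percentage
distribution of the sample, weighted outcome prevalence by covariate level,
a Pearson chi-square independence test, the Cochran-Armitage trend test for
ordered covariates, and variance inflation factors for the multicollinearity
screen (VIF > 10 flagged).

Chi-square on weighted data uses weighted counts rescaled to the unweighted
total by default; p-values are approximate under clustering, and an
unweighted variant is available.  The trend test uses unweighted counts by
default, matching the standard Cochran-Armitage construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "prevalence_by",
    "sample_profile",
    "chi_square_independence",
    "cochran_armitage_trend",
    "variance_inflation_factors",
]

VIF_CUTOFF = 10.0


def prevalence_by(
    records: pd.DataFrame,
    covariate: str,
    outcome: str = "anaemic",
    weight: str = "weight",
    level_order: list[str] | None = None,
) -> pd.DataFrame:
    """Weighted outcome prevalence (%) by covariate level, with an overall row.

    Returns columns ``level``, ``weighted_pct`` (share of the weighted
    sample), ``n`` (unweighted), ``prevalence_pct`` (weighted prevalence of
    the outcome, in percent).
    """
    if covariate not in records.columns:
        raise KeyError(
            f"unknown covariate {covariate!r}; available: "
            f"{sorted(records.columns)}"
        )
    w = records[weight].to_numpy(dtype=float)
    y = records[outcome].to_numpy(dtype=float)
    total_w = w.sum()
    rows = []
    levels = (
        level_order
        if level_order is not None
        else sorted(records[covariate].unique())
    )
    for level in levels:
        m = (records[covariate] == level).to_numpy()
        wl = w[m]
        rows.append(
            {
                "level": level,
                "weighted_pct": 100.0 * wl.sum() / total_w,
                "n": int(m.sum()),
                "prevalence_pct": 100.0 * (wl @ y[m]) / wl.sum() if wl.size else np.nan,
            }
        )
    rows.append(
        {
            "level": "Overall",
            "weighted_pct": 100.0,
            "n": len(records),
            "prevalence_pct": 100.0 * (w @ y) / total_w,
        }
    )
    return pd.DataFrame(rows)


def sample_profile(
    records: pd.DataFrame,
    covariates: list[str],
    weight: str = "weight",
) -> pd.DataFrame:
    """Weighted percentage and unweighted count per level of each covariate."""
    w = records[weight].to_numpy(dtype=float)
    total_w = w.sum()
    rows = []
    for cov in covariates:
        if cov not in records.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        for level in sorted(records[cov].unique()):
            m = (records[cov] == level).to_numpy()
            rows.append(
                {
                    "variable": cov,
                    "level": level,
                    "weighted_pct": 100.0 * w[m].sum() / total_w,
                    "n": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a levels x outcome table.

    Returns (statistic, degrees of freedom, p-value).  Raises on a zero row
    or column margin, where expected counts are undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a 2-d contingency table with >= 2 rows and columns")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("zero row/column margin: expected counts undefined")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def weighted_outcome_table(
    records: pd.DataFrame,
    covariate: str,
    outcome: str = "anaemic",
    weight: str | None = "weight",
) -> pd.DataFrame:
    """Levels x {non-case, case} count table; weighted counts are rescaled to
    the unweighted total so the chi-square statistic keeps its nominal scale."""
    y = records[outcome].astype(int)
    if weight is None:
        tab = pd.crosstab(records[covariate], y).astype(float)
    else:
        w = records[weight].astype(float)
        tab = pd.crosstab(records[covariate], y, values=w, aggfunc="sum").fillna(0.0)
        tab *= len(records) / w.sum()
    return tab


def cochran_armitage_trend(counts, scores=None) -> tuple[float, float]:
    """Cochran-Armitage test for trend in proportions across ordered levels.

    ``counts`` is a (k, 2) array of [cases, non-cases] per ordered level;
    ``scores`` default to 1..k.  The statistic is

        T = sum_i s_i (n1_i - n_i * pbar),
        Var(T) = pbar (1 - pbar) [sum_i n_i s_i^2 - (sum_i n_i s_i)^2 / N],

    with Z = T / sqrt(Var(T)) referred to the standard normal (two-sided p).
    Z is invariant to affine rescaling of the scores and flips sign when the
    level order is reversed.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
        raise ValueError("need a (k >= 3, 2) array of [cases, non-cases]")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    s = (
        np.arange(1, c.shape[0] + 1, dtype=float)
        if scores is None
        else np.asarray(scores, dtype=float)
    )
    n1 = c[:, 0]
    ni = c.sum(axis=1)
    N = ni.sum()
    pbar = n1.sum() / N
    if pbar in (0.0, 1.0):
        raise ValueError("no variation in the outcome; trend test undefined")
    T = s @ (n1 - ni * pbar)
    var = pbar * (1 - pbar) * (s**2 @ ni - (s @ ni) ** 2 / N)
    z = T / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def variance_inflation_factors(X, names: list[str] | None = None) -> pd.DataFrame:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others.

    Perfectly collinear columns report ``inf``.  Columns with VIF above 10
    are flagged as multicollinear.
    """
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    if np.any(A.std(axis=0) == 0):
        raise ValueError("constant column: VIF undefined")
    n, k = A.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    out = []
    for j in range(k):
        yj = A[:, j]
        Z = np.column_stack([np.ones(n), np.delete(A, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        ss_res = resid @ resid
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"variable": names[j], "vif": vif, "flagged": vif > VIF_CUTOFF})
    return pd.DataFrame(out)
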