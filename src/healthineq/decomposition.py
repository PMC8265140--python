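"""Wagstaff decomposition of the concentration index.

For a linear (probability) model y_i = alpha + sum_k beta_k x_ki + eps_i,
the concentration index of y decomposes additively:

    C = sum_k (beta_k * xbar_k / mu) * C_k + GC_eps / mu

where eta_k = beta_k xbar_k / mu is the elasticity of the outcome with
respect to regressor k, C_k is the concentration index of x_k against the
same wealth ranks, and GC_eps / mu = (2 / mu) cov_w(eps, R) is the residual
(unexplained) component.  The identity is exact when the same weights and
the same fractional ranks are used for the OLS fit, for C, and for every
C_k — which is what this module does.  Using OLS (a linear probability
model) rather than a nonlinear fit is what makes the identity close
exactly.

Percentage contributions divide each absolute contribution eta_k * C_k by
the explained (calculated) index by default; dividing by the actual index
is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .inequality import ConcentrationIndex
from .wealth import _check_weights, fractional_rank

__all__ = [
    "WagstaffDecomposition",
    "DecompositionResult",
    "wagstaff_decompose",
    "percentage_contributions",
    "group_contributions",
]


@dataclass
class DecompositionResult:
    """Per-regressor decomposition table plus the identity terms.

    ``table`` has one row per dummy regressor with columns ``coefficient``,
    ``mean``, ``elasticity``, ``ci`` (the regressor's concentration index),
    ``absolute_contribution`` and ``percentage_contribution``.
    """

    table: pd.DataFrame
    explained_ci: float  # "Calculated CI"
    actual_ci: float  # "Actual CI"
    residual: float  # GC_eps / mu
    mu: float
    intercept: float
    residual_check: float = field(repr=False, default=np.nan)
    percentage_denominator: str = "explained"

    def group_totals(self, grouping: dict[str, list[str]]) -> pd.DataFrame:
        return group_contributions(self, grouping)


class WagstaffDecomposition(BaseEstimator):
    """Decompose the concentration index into per-regressor contributions.

    Fit signature: ``fit(X, y, scores=..., sample_weight=...)`` where ``X``
    is the dummy design (references already dropped), ``scores`` the wealth
    scores defining the ranking, ``y`` the (binary) outcome.

    Attributes (after fit)
    ----------------------
    result_ : DecompositionResult
    betas_, elasticities_, regressor_ci_, contributions_ : pd.Series
    explained_ci_, actual_ci_, residual_ : float
    """

    def __init__(self, percentage_denominator: str = "explained"):
        self.percentage_denominator = percentage_denominator

    def fit(self, X, y, scores=None, sample_weight=None):
        if scores is None:
            raise ValueError("wealth scores are required to rank individuals")
        Xd = pd.DataFrame(X).astype(float)
        y = np.asarray(y, dtype=float)
        n = y.shape[0]
        s = np.asarray(scores, dtype=float).reshape(n)
        w = np.ones(n) if sample_weight is None else _check_weights(sample_weight, n)
        wn = w / w.sum()

        mu = float(wn @ y)
        if mu == 0:
            raise ValueError("outcome has zero mean; decomposition undefined")

        design = sm.add_constant(Xd, has_constant="add")
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            # name the columns involved in the deficiency via pivoted QR
            from scipy.linalg import qr

            _, _, piv = qr(design.to_numpy() * np.sqrt(wn)[:, None], pivoting=True)
            dropped = [design.columns[j] for j in piv[rank:]]
            raise ValueError(f"design is rank deficient; collinear columns: {dropped}")

        ols = sm.WLS(y, design, weights=w).fit()
        betas = ols.params.drop("const")
        alpha = float(ols.params["const"])

        ranks = fractional_rank(s, w)
        rbar = float(wn @ ranks)
        y_ci = ConcentrationIndex(use_ranks=True).fit(ranks, y, sample_weight=w)
        actual = y_ci.C_

        means = pd.Series({k: float(wn @ Xd[k].to_numpy()) for k in Xd.columns})
        eta = betas * means / mu
        # C_k via the covariance form; for a zero-mean regressor the index is
        # undefined but the contribution eta_k * C_k = 2 beta_k cov(x_k, R)/mu
        # stays well-defined, so contributions are computed from covariances.
        cov_xr = pd.Series(
            {k: float((wn * (Xd[k].to_numpy() - means[k])) @ (ranks - rbar))
             for k in Xd.columns}
        )
        ck = pd.Series(
            {k: 2.0 * cov_xr[k] / means[k] if means[k] != 0 else np.nan
             for k in Xd.columns}
        )
        contrib = 2.0 * betas * cov_xr / mu
        explained = float(contrib.sum())
        residual = actual - explained

        eps = y - np.asarray(ols.fittedvalues)
        residual_check = float(2.0 * (wn * eps) @ (ranks - rbar) / mu)

        denom = {"explained": explained, "actual": actual}[self.percentage_denominator]
        if denom == 0:
            raise ValueError("zero percentage denominator")
        table = pd.DataFrame(
            {
                "coefficient": betas,
                "mean": means,
                "elasticity": eta,
                "ci": ck,
                "absolute_contribution": contrib,
                "percentage_contribution": 100.0 * contrib / denom,
            }
        )
        self.betas_ = betas
        self.elasticities_ = eta
        self.regressor_ci_ = ck
        self.contributions_ = contrib
        self.explained_ci_ = explained
        self.actual_ci_ = actual
        self.residual_ = residual
        self.mu_ = mu
        self.result_ = DecompositionResult(
            table=table,
            explained_ci=explained,
            actual_ci=actual,
            residual=residual,
            mu=mu,
            intercept=alpha,
            residual_check=residual_check,
            percentage_denominator=self.percentage_denominator,
        )
        return self


def wagstaff_decompose(
    y, X, scores, weights=None, percentage_denominator: str = "explained"
) -> DecompositionResult:
    """Functional wrapper around :class:`WagstaffDecomposition`."""
    est = WagstaffDecomposition(percentage_denominator=percentage_denominator)
    est.fit(X, y, scores=scores, sample_weight=weights)
    return est.result_


def percentage_contributions(
    result: DecompositionResult, denominator: str = "explained"
) -> pd.Series:
    """Per-regressor percentage contributions under the chosen denominator."""
    denom = {"explained": result.explained_ci, "actual": result.actual_ci}[denominator]
    if denom == 0:
        raise ValueError("zero percentage denominator")
    return 100.0 * result.table["absolute_contribution"] / denom


def group_contributions(
    result: DecompositionResult, grouping: dict[str, list[str]]
) -> pd.DataFrame:
    """Aggregate absolute and percentage contributions over covariate groups.

    ``grouping`` maps a group label to its dummy-column names and must
    partition the assigned columns (no column in two groups).
    """
    seen: dict[str, str] = {}
    for g, cols in grouping.items():
        for c in cols:
            if c in seen:
                raise ValueError(f"column {c!r} assigned to both {seen[c]!r} and {g!r}")
            seen[c] = g
    rows = []
    for g, cols in grouping.items():
        missing = [c for c in cols if c not in result.table.index]
        if missing:
            raise KeyError(f"unknown regressor(s) in group {g!r}: {missing}")
        sub = result.table.loc[cols]
        rows.append(
            {
                "group": g,
                "absolute_contribution": float(sub["absolute_contribution"].sum()),
                "percentage_contribution": float(
                    sub["percentage_contribution"].sum()
                ),
            }
        )
    return pd.DataFrame(rows)
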