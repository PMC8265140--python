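"""Concentration index and concentration curve.

The concentration index C summarises socio-economic inequality in a health
variable y as twice the weighted covariance between y and the fractional
wealth rank R, divided by the mean of y:

    C = (2 / mu) * sum_i w_i (y_i - mu)(R_i - Rbar)

with normalized weights w_i and Rbar the weighted mean rank (1/2 by
construction).  C lies in [-1, 1]; for a binary outcome it further lies in
[mu - 1, 1 - mu].  Negative C means the outcome is concentrated among the
poor, and the concentration curve then lies above the line of equality.

The weighted covariance uses the population (normalized-weight) form with
no finite-sample correction, matching the defining formula.  An optional
Wagstaff normalization C / (1 - mu) for binary outcomes is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .wealth import _check_weights, fractional_rank

__all__ = [
    "ConcentrationIndex",
    "InequalityResult",
    "concentration_index",
    "concentration_curve",
    "stratified_ci",
]


@dataclass
class InequalityResult:
    """Concentration index with its ingredients and curve coordinates."""

    C: float
    mu: float
    n: int
    curve: np.ndarray  # (k, 2): cumulative population share, cumulative outcome share
    stratum: str | None = None
    wagstaff_normalized_C: float | None = field(default=None, repr=False)


class ConcentrationIndex(BaseEstimator):
    """Estimator computing the weighted concentration index of y on X.

    Parameters
    ----------
    use_ranks : bool
        If True (default False), ``X`` passed to :meth:`fit` already holds
        fractional ranks; otherwise it holds wealth scores and ranks are
        computed internally.
    wagstaff_normalize : bool
        Also report C / (1 - mu), the binary-outcome normalization.  The
        plain index remains the primary result.

    Attributes
    ----------
    C_ : float              concentration index
    mu_ : float             weighted outcome mean
    ranks_ : ndarray        fractional ranks used
    curve_ : ndarray        concentration-curve coordinates, (0,0) .. (1,1)
    """

    def __init__(self, use_ranks: bool = False, wagstaff_normalize: bool = False):
        self.use_ranks = use_ranks
        self.wagstaff_normalize = wagstaff_normalize

    def fit(self, X, y, sample_weight=None):
        y = np.asarray(y, dtype=float)
        n = y.shape[0]
        x = np.asarray(X, dtype=float).reshape(n)
        w = (
            np.ones(n)
            if sample_weight is None
            else _check_weights(sample_weight, n)
        )
        wn = w / w.sum()
        mu = float(wn @ y)
        if mu == 0:
            raise ValueError("outcome has zero mean; index undefined")
        if self.use_ranks:
            r = x
        else:
            r = fractional_rank(x, w)
        rbar = float(wn @ r)
        self.ranks_ = r
        self.mu_ = mu
        self.C_ = float(2.0 * (wn * (y - mu)) @ (r - rbar) / mu)
        self.curve_ = _curve_coords(y, r, wn, mu)
        self.n_ = n
        if self.wagstaff_normalize:
            self.wagstaff_C_ = self.C_ / (1.0 - mu) if mu < 1 else np.nan
        return self

    def result_(self, stratum: str | None = None) -> InequalityResult:
        return InequalityResult(
            C=self.C_,
            mu=self.mu_,
            n=self.n_,
            curve=self.curve_,
            stratum=stratum,
            wagstaff_normalized_C=getattr(self, "wagstaff_C_", None),
        )


def _curve_coords(y, r, wn, mu) -> np.ndarray:
    order = np.argsort(r, kind="stable")
    pop = np.cumsum(wn[order])
    out = np.cumsum(wn[order] * y[order]) / mu
    return np.column_stack([np.r_[0.0, pop], np.r_[0.0, out]])


def concentration_index(y, ranks, weights=None) -> InequalityResult:
    """Concentration index from precomputed fractional ranks.

    ``ranks`` must come from :func:`healthineq.wealth.fractional_rank` on the
    same individuals and weights.
    """
    est = ConcentrationIndex(use_ranks=True).fit(ranks, y, sample_weight=weights)
    return est.result_()


def concentration_curve(y, scores, weights=None) -> np.ndarray:
    """Concentration-curve coordinates ranking individuals poorest to richest.

    Returns an array of (cumulative population share, cumulative outcome
    share) pairs starting at (0, 0) and ending at (1, 1).  The curve lies
    above the diagonal exactly when the concentration index is negative.
    """
    est = ConcentrationIndex(use_ranks=False).fit(scores, y, sample_weight=weights)
    return est.curve_


def stratified_ci(
    records: pd.DataFrame,
    stratum: str,
    outcome: str = "anaemic",
    score: str = "wealth_score",
    weight: str = "weight",
) -> tuple[dict[str, InequalityResult], dict[str, str]]:
    """Concentration index per stratum, with ranks recomputed within stratum.

    Returns ``(results, skipped)`` where ``skipped`` maps a stratum label to
    the reason it could not be computed (constant wealth score, zero-variance
    or zero-mean outcome).
    """
    if stratum not in records.columns:
        raise KeyError(f"stratum column {stratum!r} not in records")
    results: dict[str, InequalityResult] = {}
    skipped: dict[str, str] = {}
    for label, grp in records.groupby(stratum, observed=True, sort=True):
        label = str(label)
        y = grp[outcome].to_numpy(dtype=float)
        s = grp[score].to_numpy(dtype=float)
        w = grp[weight].to_numpy(dtype=float)
        if np.unique(s).size < 2:
            skipped[label] = "fewer than 2 distinct wealth scores"
            continue
        if np.all(y == y[0]):
            skipped[label] = "zero-variance outcome"
            continue
        if (w / w.sum()) @ y == 0:
            skipped[label] = "zero-mean outcome"
            continue
        est = ConcentrationIndex().fit(s, y, sample_weight=w)
        results[label] = est.result_(stratum=label)
    return results, skipped
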