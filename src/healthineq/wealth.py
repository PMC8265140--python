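"""Household wealth scoring and economic ranking.

The socio-economic ranking variable of the concentration index is built in
three steps: a household asset score (first principal component of the
standardized asset indicators), population-weighted quintiles of that score
at the individual level, and the weighted fractional rank R_i in (0, 1).
Household scores are replicated to every de jure household member before
ranking, so all ranking is at the individual level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WealthIndex",
    "compute_asset_scores",
    "assign_quintiles",
    "fractional_rank",
]


def _check_weights(weights, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have length {n}, got shape {w.shape}")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and strictly positive")
    return w


class WealthIndex(BaseEstimator, TransformerMixin):
    """First-principal-component asset score for household wealth.

    Each asset indicator column is standardized to mean 0 / variance 1
    (zero-variance columns are dropped with a warning), and the household
    score is the projection of the standardized indicators onto the leading
    eigenvector of their correlation matrix.  The sign of the component is
    fixed so that the score correlates positively with the plain asset sum:
    households owning more assets score higher.

    Attributes
    ----------
    loadings_ : ndarray of shape (n_kept_assets,)
        First principal component in the standardized asset space.
    mean_, scale_ : ndarray
        Per-column standardization constants of the kept columns.
    kept_columns_ : ndarray of int
        Indices of the asset columns with nonzero variance.
    explained_variance_ratio_ : float
        Share of total standardized variance carried by the first component.
    """

    def __init__(self, min_households: int = 3, min_assets: int = 2):
        self.min_households = min_households
        self.min_assets = min_assets

    def _validate(self, X) -> np.ndarray:
        A = np.asarray(X, dtype=float)
        if A.ndim != 2:
            raise ValueError("asset matrix must be 2-dimensional")
        if not np.all(np.isfinite(A)):
            raise ValueError("asset matrix contains missing or non-finite entries")
        if A.shape[0] < self.min_households or A.shape[1] < self.min_assets:
            raise ValueError(
                f"need at least {self.min_households} households and "
                f"{self.min_assets} assets, got {A.shape}"
            )
        return A

    def fit(self, X, y=None):
        A = self._validate(X)
        sd = A.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("no variation in assets")
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance asset column(s)",
                UserWarning,
                stacklevel=2,
            )
        self.kept_columns_ = np.flatnonzero(keep)
        Ak = A[:, keep]
        self.mean_ = Ak.mean(axis=0)
        self.scale_ = Ak.std(axis=0)
        Z = (Ak - self.mean_) / self.scale_
        corr = Z.T @ Z / Z.shape[0]
        evals, evecs = np.linalg.eigh(corr)
        v = evecs[:, -1]
        # orient: richer households (larger asset sum) get higher scores
        scores = Z @ v
        if np.cov(scores, A[:, keep].sum(axis=1))[0, 1] < 0:
            v = -v
        self.loadings_ = v
        self.explained_variance_ratio_ = float(evals[-1] / evals.sum())
        return self

    def transform(self, X) -> np.ndarray:
        A = self._validate(X)
        Z = (A[:, self.kept_columns_] - self.mean_) / self.scale_
        return Z @ self.loadings_


def compute_asset_scores(assets) -> np.ndarray:
    """Household wealth scores from an asset indicator matrix (fit+transform)."""
    if isinstance(assets, pd.DataFrame):
        assets = assets.to_numpy(dtype=float)
    return WealthIndex().fit_transform(assets)


def fractional_rank(scores, weights) -> np.ndarray:
    """Weighted fractional rank R_i of each individual in the wealth distribution.

    With weights normalized to sum 1 and individuals sorted ascending by
    score, R_i = sum_{j<i} w_j + w_i / 2.  Tied scores receive the shared
    midpoint rank of their tie group (Lerman-Yitzhaki convention), which
    makes the rank — and hence the concentration index — invariant to the
    ordering within ties.  The weighted mean of R is exactly 1/2.
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        bad = np.flatnonzero(~np.isfinite(s))
        raise ValueError(f"non-finite wealth scores at rows {bad.tolist()[:10]}")
    w = _check_weights(weights, s.shape[0])
    wn = w / w.sum()
    order = np.argsort(s, kind="stable")
    ss, ws = s[order], wn[order]
    cum = np.cumsum(ws)
    # midpoint rank of each tie group: weight before group + group weight / 2
    grp_start = np.flatnonzero(np.r_[True, np.diff(ss) != 0])
    grp_id = np.cumsum(np.r_[True, np.diff(ss) != 0]) - 1
    grp_end_cum = np.r_[cum[grp_start[1:] - 1], cum[-1]]
    grp_before = np.r_[0.0, grp_end_cum[:-1]]
    r_sorted = (grp_before + grp_end_cum)[grp_id] / 2.0
    r = np.empty_like(r_sorted)
    r[order] = r_sorted
    return r


def assign_quintiles(scores, weights) -> np.ndarray:
    """Population-weighted wealth quintiles, poorest = 1 ... richest = 5.

    Cut points sit at cumulative weight shares 0.2/0.4/0.6/0.8 of the
    individual-level score distribution.  Every individual is labelled by
    the quintile containing the midpoint of its cumulative-weight interval,
    so tied scores always share a label; an individual whose own weight
    straddles a cut point takes the quintile of its midpoint (the 20% weight
    share per quintile can then only break at that tie).
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty input")
    r = fractional_rank(s, weights)
    return np.searchsorted([0.2, 0.4, 0.6, 0.8], r, side="right").astype(int) + 1
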