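"""Anaemia classification and survey-weighted logistic regression.

WHO-style grading of men's haemoglobin: any anaemia below 13.0 g/dL, mild
12.0-12.9, moderate 9.0-11.9, severe below 9.0.  A reading of exactly
13.0 g/dL is classified non-anaemic, and the severe/moderate boundary is
closed at 9.0 (severe iff hb < 9.0).

The regression maximises the weighted Bernoulli log-likelihood
sum_i w_i [y_i log p_i + (1 - y_i) log(1 - p_i)] by iteratively reweighted
least squares, with sampling weights treated as analytic weights normalized
to mean 1 (so the reported standard errors reflect the actual sample size,
and rescaling all weights by a constant changes nothing).  Odds ratios with
Wald 95% intervals are reported per dummy regressor against the declared
reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "AnaemiaCall",
    "classify_anaemia",
    "WeightedLogisticRegression",
    "fit_weighted_logistic",
    "build_dummies",
]

SEVERITY_ORDER = ("none", "mild", "moderate", "severe")


@dataclass
class AnaemiaCall:
    haemoglobin: float
    severity: str
    anaemic: int


def classify_anaemia(hb) -> "AnaemiaCall | list[AnaemiaCall]":
    """Grade haemoglobin (g/dL): none >= 13.0, mild [12, 13), moderate [9, 12),
    severe < 9.0; binary anaemic = 1 iff hb < 13.0.

    Accepts a scalar or a sequence; readings outside the plausible 2-25 g/dL
    band trigger a warning, non-finite values an error.
    """
    arr = np.atleast_1d(np.asarray(hb, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite haemoglobin value(s)")
    if np.any((arr < 2.0) | (arr > 25.0)):
        warnings.warn(
            "haemoglobin outside the plausible 2-25 g/dL range",
            UserWarning,
            stacklevel=2,
        )
    sev = np.select(
        [arr >= 13.0, arr >= 12.0, arr >= 9.0],
        ["none", "mild", "moderate"],
        default="severe",
    )
    calls = [
        AnaemiaCall(haemoglobin=float(h), severity=str(s), anaemic=int(h < 13.0))
        for h, s in zip(arr, sev)
    ]
    return calls[0] if np.isscalar(hb) or np.ndim(hb) == 0 else calls


def build_dummies(
    records: pd.DataFrame, covariates: dict[str, str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot design minus reference levels.

    ``covariates`` maps covariate name -> reference level.  Returns the dummy
    DataFrame (columns ``var[level]``) and a map covariate -> its dummy
    column names, preserving the observed level order with the reference
    dropped.
    """
    cols = {}
    groups: dict[str, list[str]] = {}
    for var, ref in covariates.items():
        if var not in records.columns:
            raise KeyError(f"unknown covariate {var!r}")
        levels = list(pd.unique(records[var]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from {var!r}")
        groups[var] = []
        for level in sorted(str(l) for l in levels):
            if level == str(ref):
                continue
            name = f"{var}[{level}]"
            cols[name] = (records[var].astype(str) == level).astype(float)
            groups[var].append(name)
    return pd.DataFrame(cols, index=records.index), groups


class WeightedLogisticRegression(BaseEstimator):
    """Survey-weighted logistic regression with odds-ratio reporting.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the coefficient update (max abs change).
    max_iter : int
        IRLS iteration cap; non-convergence is flagged, not raised.
    separation_threshold : float
        Absolute coefficient size beyond which complete separation is
        declared and an error raised naming the regressor.

    Attributes
    ----------
    params_ : pd.Series          coefficients (including ``const``)
    summary_ : pd.DataFrame      coef, se, OR, CI bounds, p per regressor
    converged_ : bool
    n_used_ : int
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 100,
        separation_threshold: float = 15.0,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.separation_threshold = separation_threshold

    def fit(self, X, y, sample_weight=None):
        Xd = pd.DataFrame(X).astype(float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome has a single class; model undefined")
        w = (
            np.ones(len(y))
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.mean()  # analytic-weight normalization

        design = sm.add_constant(Xd, has_constant="add")
        model = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=self.max_iter, tol=self.tol)

        big = res.params.abs() > self.separation_threshold
        if big.any():
            raise ValueError(
                "separation detected (diverging coefficient) for: "
                + ", ".join(res.params.index[big])
            )
        self.converged_ = bool(res.converged)
        if not self.converged_:
            warnings.warn("IRLS did not converge; results flagged", UserWarning,
                          stacklevel=2)
        self.params_ = res.params
        self.result_ = res
        self.n_used_ = len(y)
        ci = res.conf_int()
        self.summary_ = pd.DataFrame(
            {
                "coef": res.params,
                "se": res.bse,
                "odds_ratio": np.exp(res.params),
                "or_ci_low": np.exp(ci[0]),
                "or_ci_high": np.exp(ci[1]),
                "p_value": res.pvalues,
            }
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        design = sm.add_constant(pd.DataFrame(X).astype(float), has_constant="add")
        p = np.asarray(self.result_.predict(design))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def fit_weighted_logistic(
    records: pd.DataFrame,
    covariates: dict[str, str],
    outcome: str = "anaemic",
    weight: str | None = "weight",
) -> pd.DataFrame:
    """Fit the weighted logistic model over categorical covariates.

    ``covariates`` maps covariate -> reference level.  Returns a tidy table
    with one row per non-reference dummy: coefficient, SE, odds ratio, Wald
    95% CI, p-value and significance stars (*** p<0.001, ** p<0.05, * p<0.10).
    """
    X, groups = build_dummies(records, covariates)
    w = None if weight is None else records[weight].to_numpy(dtype=float)
    est = WeightedLogisticRegression().fit(
        X, records[outcome].to_numpy(dtype=float), sample_weight=w
    )
    tab = est.summary_.drop(index="const").reset_index(names="regressor")
    tab["covariate"] = [r.split("[")[0] for r in tab["regressor"]]
    tab["stars"] = [_stars(p) for p in tab["p_value"]]
    tab.attrs["converged"] = est.converged_
    tab.attrs["n_used"] = est.n_used_
    tab.attrs["groups"] = groups
    return tab
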