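"""Synthetic two-stage survey microdata with planted wealth-related inequality.

Emulates a national household-survey design: clusters (PSUs) are drawn,
households within clusters, and adult male individuals within households.
Each household carries a latent affluence variable (with a cluster-level
component), a set of binary asset indicators whose ownership probability
rises with affluence, and a wealth score computed as the first principal
component of those assets.  A binary anaemia outcome is drawn per
individual from a logistic model over the categorical covariates plus a
``wealth_effect`` term on the standardized wealth score; haemoglobin is
then drawn from a truncated normal on the matching side of the 13.0 g/dL
threshold, so the continuous and binary outcomes agree exactly.

Default covariate marginals and logistic coefficients emulate a national
men's health survey profile (prevalence near 23%, pro-poor concentration
of anaemia with a population-scale concentration index near -0.12).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .inequality import ConcentrationIndex
from .wealth import WealthIndex, assign_quintiles

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "generate_dataset",
    "planted_truth",
    "write_dataset",
]

# covariate level marginals emulating a national adult-male profile
_DEFAULT_CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "age_group": {
        "15-19": 0.167, "20-29": 0.291, "30-39": 0.254,
        "40-49": 0.210, "50-54": 0.078,
    },
    "marital_status": {"never_married": 0.360, "currently_married": 0.640},
    "education": {
        "no_education": 0.131, "primary": 0.127,
        "secondary": 0.572, "higher": 0.171,
    },
    "mass_media": {"no_exposure": 0.080, "exposure": 0.920},
    "bmi_class": {"underweight": 0.197, "normal": 0.607, "overweight": 0.195},
    "tobacco": {"no": 0.542, "yes": 0.458},
    "caste": {
        "scheduled_caste": 0.199, "scheduled_tribe": 0.089,
        "other_backward_class": 0.438, "others": 0.274,
    },
    "religion": {"hindu": 0.819, "muslim": 0.128, "others": 0.053},
    "residence": {"urban": 0.373, "rural": 0.627},
    "region": {
        "north": 0.141, "central": 0.220, "east": 0.189,
        "northeast": 0.033, "west": 0.181, "south": 0.237,
    },
}

# log odds-ratios vs the reference level (first level of each covariate above)
_DEFAULT_LOGIT_COEFS: dict[str, dict[str, float]] = {
    "age_group": {"20-29": -0.357, "30-39": -0.261, "40-49": -0.041, "50-54": 0.182},
    "marital_status": {"currently_married": -0.010},
    "education": {"primary": -0.105, "secondary": -0.186, "higher": -0.342},
    "mass_media": {"exposure": -0.073},
    "bmi_class": {"underweight": 0.412, "overweight": -0.223},
    "tobacco": {"yes": -0.083},
    "caste": {
        "scheduled_caste": -0.030, "scheduled_tribe": 0.285,
        "other_backward_class": -0.030,
    },
    "religion": {"muslim": -0.128, "others": -0.030},
    "residence": {"rural": 0.113},
    "region": {
        "central": 0.010, "east": 0.336, "northeast": -0.288,
        "west": -0.139, "south": -0.073,
    },
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey generator.

    ``wealth_effect`` is the log-odds slope of anaemia on the standardized
    wealth score and controls the planted gradient (negative values plant
    pro-poor concentration, the realistic direction; positive values invert
    it, which is useful for symmetry checks);
    ``logit_intercept`` sets the baseline prevalence.  The defaults are
    calibrated so a large draw shows ~23% prevalence and a concentration
    index near -0.12.
    """

    n_clusters: int = 100
    households_per_cluster: int = 25
    mean_members_per_household: float = 1.4
    category_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: normalized_category_probs(_DEFAULT_CATEGORY_PROBS)
    )
    logit_intercept: float = -0.90
    logit_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in _DEFAULT_LOGIT_COEFS.items()
        }
    )
    asset_loadings: tuple[float, ...] = (
        1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2,
    )
    wealth_effect: float = -0.285
    cluster_affluence_sd: float = 0.3
    weight_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("invalid config field n_clusters: must be >= 1")
        if self.households_per_cluster < 1:
            raise ValueError("invalid config field households_per_cluster: must be >= 1")
        if self.mean_members_per_household < 1:
            raise ValueError(
                "invalid config field mean_members_per_household: must be >= 1"
            )
        if self.weight_dispersion < 0:
            raise ValueError("invalid config field weight_dispersion: must be >= 0")
        for var, probs in self.category_probs.items():
            p = np.array(list(probs.values()), dtype=float)
            if np.any(p < 0):
                raise ValueError(f"invalid config field category_probs[{var!r}]: "
                                 "negative probability")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"invalid config field category_probs[{var!r}]: "
                    f"probabilities sum to {p.sum():.15f}, not 1"
                )
        for var, coefs in self.logit_coefs.items():
            if var not in self.category_probs:
                raise ValueError(
                    f"invalid config field logit_coefs: unknown covariate {var!r}"
                )
            levels = set(self.category_probs[var])
            unknown = set(coefs) - levels
            if unknown:
                raise ValueError(
                    f"invalid config field logit_coefs[{var!r}]: "
                    f"unknown levels {sorted(unknown)}"
                )

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """Config with no planted structure: all coefficients and effects 0."""
        defaults = dict(
            logit_intercept=0.0,
            logit_coefs={k: {lv: 0.0 for lv in v} for k, v in
                         _DEFAULT_LOGIT_COEFS.items()},
            wealth_effect=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["asset_loadings"] = list(d["asset_loadings"])
        return d


@dataclass
class TrueParameters:
    """Ground truth planted by the generator, for recovery tests."""

    prevalence: float
    planted_logit_coefs: dict[str, dict[str, float]]
    planted_intercept: float
    planted_wealth_effect: float
    large_sample_ci: float
    n_reference: int

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not -1.0 <= self.large_sample_ci <= 1.0:
            raise ValueError("large_sample_ci must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _renormalized(probs: dict[str, float]) -> np.ndarray:
    p = np.array(list(probs.values()), dtype=float)
    return p / p.sum()


def normalized_category_probs(
    probs: dict[str, dict[str, float]],
) -> dict[str, dict[str, float]]:
    """Renormalise near-1 probability vectors (e.g. printed percentages) exactly."""
    return {
        var: dict(zip(levels.keys(), _renormalized(levels)))
        for var, levels in probs.items()
    }


def _truncnorm_rvs(lo, hi, mean, sd, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Generate one synthetic survey, one row per individual.

    Deterministic given ``config.seed``.  Columns: person, cluster and
    household IDs; sampling ``weight`` (log-normal, mean 1); the categorical
    covariates; household ``wealth_score`` (asset PCA, shared within
    household), ``latent_affluence``, ``wealth_quintile``; ``anaemic`` and a
    consistent ``haemoglobin`` (anaemic == 1 exactly when hb < 13.0 g/dL).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_hh = config.n_clusters * config.households_per_cluster
    cluster_of_hh = np.repeat(np.arange(config.n_clusters),
                              config.households_per_cluster)

    # latent household affluence with a cluster-level component (two-stage design)
    icc_sd = config.cluster_affluence_sd
    u_cluster = rng.normal(0.0, icc_sd, size=config.n_clusters)
    affluence = u_cluster[cluster_of_hh] + rng.normal(
        0.0, math.sqrt(max(1.0 - icc_sd**2, 1e-12)), size=n_hh
    )

    # binary assets: ownership probability rises with affluence, staggered
    # baselines so the indicators span common to rare goods
    loadings = np.asarray(config.asset_loadings, dtype=float)
    offsets = np.linspace(-1.5, 1.5, loadings.size)
    p_assets = 1.0 / (1.0 + np.exp(-(affluence[:, None] * loadings + offsets)))
    assets = (rng.random((n_hh, loadings.size)) < p_assets).astype(float)

    wealth_score = WealthIndex().fit_transform(assets)

    # household sizes: 1 + Poisson(mean - 1) eligible members
    sizes = 1 + rng.poisson(config.mean_members_per_household - 1.0, size=n_hh)
    hh_idx = np.repeat(np.arange(n_hh), sizes)
    n = hh_idx.size

    df = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "cluster_id": cluster_of_hh[hh_idx],
            "household_id": hh_idx,
            "latent_affluence": affluence[hh_idx],
            "wealth_score": wealth_score[hh_idx],
        }
    )

    # sampling weights: positive, right-skewed, normalized to mean 1
    if config.weight_dispersion > 0:
        w = rng.lognormal(0.0, config.weight_dispersion, size=n)
        df["weight"] = w / w.mean()
    else:
        df["weight"] = 1.0

    # categorical covariates (independent draws from the configured marginals)
    for var, probs in config.category_probs.items():
        levels = list(probs.keys())
        p = _renormalized(probs)
        df[var] = rng.choice(levels, size=n, p=p)

    # linear predictor of the anaemia logit
    eta = np.full(n, config.logit_intercept)
    for var, coefs in config.logit_coefs.items():
        col = df[var].to_numpy()
        for level, beta in coefs.items():
            if beta != 0.0:
                eta += beta * (col == level)
    z = df["wealth_score"].to_numpy()
    z_sd = z.std()
    z_std = (z - z.mean()) / z_sd if z_sd > 0 else np.zeros(n)
    eta += config.wealth_effect * z_std

    anaemic = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    df["anaemic"] = anaemic

    # haemoglobin consistent with the 13.0 g/dL threshold by construction
    hb = np.empty(n)
    n1 = int(anaemic.sum())
    if n1:
        hb[anaemic == 1] = _truncnorm_rvs(2.0, 13.0, 11.5, 1.5, n1, rng)
    if n - n1:
        hb[anaemic == 0] = _truncnorm_rvs(13.0, 25.0, 14.8, 1.3, n - n1, rng)
    df["haemoglobin"] = hb

    df["wealth_quintile"] = assign_quintiles(
        df["wealth_score"].to_numpy(), df["weight"].to_numpy()
    )
    return df


def planted_truth(config: SimulationConfig, n_reference: int = 200_000) -> TrueParameters:
    """Ground truth from one large reference draw of ``n_reference`` individuals.

    Generates a super-population sample with the same per-household settings
    (scaling the number of clusters), then measures the weighted prevalence
    and the concentration index of the outcome against the wealth score.
    """
    if n_reference < 1000:
        raise ValueError("n_reference < 1000 gives an unstable truth; refused")
    per_cluster = config.households_per_cluster * config.mean_members_per_household
    n_clusters = max(1, math.ceil(n_reference / per_cluster))
    ref_cfg = SimulationConfig(
        **{**config.to_dict(), "n_clusters": n_clusters,
           "asset_loadings": tuple(config.asset_loadings)}
    )
    df = generate_dataset(ref_cfg)
    w = df["weight"].to_numpy()
    prev = float((w / w.sum()) @ df["anaemic"].to_numpy())
    est = ConcentrationIndex().fit(
        df["wealth_score"].to_numpy(),
        df["anaemic"].to_numpy(dtype=float),
        sample_weight=w,
    )
    return TrueParameters(
        prevalence=prev,
        planted_logit_coefs={k: dict(v) for k, v in config.logit_coefs.items()},
        planted_intercept=config.logit_intercept,
        planted_wealth_effect=config.wealth_effect,
        large_sample_ci=est.C_,
        n_reference=len(df),
    )


def write_dataset(df: pd.DataFrame, path, truth: TrueParameters | None = None,
                  config: SimulationConfig | None = None, truth_path=None) -> None:
    """Write the survey as CSV plus an optional JSON sidecar with the truth."""
    df.to_csv(path, index=False)
    if truth_path is not None:
        sidecar = {}
        if truth is not None:
            sidecar["truth"] = truth.to_dict()
        if config is not None:
            sidecar["config"] = config.to_dict()
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)
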