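"""Configuration-driven end-to-end pipeline.

Ties the stages together: load or simulate the survey, construct the wealth
ranking, produce the descriptive and regression tables, the concentration
index and curve (overall and by stratum), and the decomposition table.
Outputs are plain CSV files plus a JSON run log with seed, row accounting
(input rows = analyzed + dropped) and package versions.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decomposition import wagstaff_decompose
from .descriptive import (
    chi_square_independence,
    cochran_armitage_trend,
    prevalence_by,
    sample_profile,
    weighted_outcome_table,
)
from .inequality import ConcentrationIndex, stratified_ci
from .models import build_dummies, fit_weighted_logistic
from .simulate import SimulationConfig, generate_dataset, planted_truth, write_dataset
from .wealth import assign_quintiles, compute_asset_scores, fractional_rank

logger = logging.getLogger("healthineq")

__all__ = ["PipelineConfig", "run_pipeline", "default_covariate_spec"]

# covariate -> reference level, in reporting order
_DEFAULT_COVARIATES: dict[str, str] = {
    "age_group": "15-19",
    "marital_status": "never_married",
    "education": "no_education",
    "mass_media": "no_exposure",
    "bmi_class": "normal",
    "tobacco": "no",
    "caste": "others",
    "religion": "hindu",
    "wealth_quintile_cat": "Q1",
    "residence": "urban",
    "region": "north",
}

_ORDERED_COVARIATES = ("education", "wealth_quintile_cat")


def default_covariate_spec() -> dict[str, str]:
    return dict(_DEFAULT_COVARIATES)


@dataclass
class PipelineConfig:
    """Run settings: exactly one of ``input_path`` or ``simulation``."""

    output_dir: str
    input_path: str | None = None
    simulation: SimulationConfig | None = None
    outcome: str = "anaemic"
    haemoglobin: str | None = "haemoglobin"
    weight: str = "weight"
    wealth_score: str | None = "wealth_score"
    asset_columns: list[str] | None = None
    covariates: dict[str, str] = field(default_factory=default_covariate_spec)
    stratum: str | None = "region"
    percentage_denominator: str = "explained"
    weighted_chi_square: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_path / simulation must be provided"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "asset_loadings" in sim:
                sim["asset_loadings"] = tuple(sim["asset_loadings"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


def _analysis_columns(cfg: PipelineConfig, df: pd.DataFrame) -> list[str]:
    cols = [cfg.outcome, cfg.weight]
    if cfg.wealth_score and cfg.wealth_score in df.columns:
        cols.append(cfg.wealth_score)
    cols += [c for c in cfg.covariates if c in df.columns]
    return cols


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``output_dir``.

    Emits table1.csv (sample profile), table2.csv (prevalence + tests),
    table3.csv (logistic odds ratios), table4.csv (decomposition),
    curves/<stratum>.csv and curves/overall.csv, state_ci.csv (per-stratum
    index), dataset.csv + truth.json in simulation mode, and run_log.json.
    On any stage failure the partial bundle is removed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    log: dict = {"seed": config.seed, "version": __version__,
                 "numpy": np.__version__, "pandas": pd.__version__}

    def _write(df: pd.DataFrame, name: str) -> None:
        p = out / name
        p.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, index=False)
        created.append(p)

    try:
        stage = "load"
        if config.simulation is not None:
            sim_cfg = config.simulation
            df = generate_dataset(sim_cfg)
            truth = planted_truth(sim_cfg, n_reference=max(100_000, len(df)))
            write_dataset(df, out / "dataset.csv", truth=truth, config=sim_cfg,
                          truth_path=out / "truth.json")
            created += [out / "dataset.csv", out / "truth.json"]
        else:
            df = pd.read_csv(config.input_path)

        stage = "validate"
        needed = [config.outcome, config.weight] + [
            c for c in config.covariates if c != "wealth_quintile_cat"
        ]
        missing_cols = [c for c in needed if c not in df.columns]
        if missing_cols:
            raise KeyError(f"declared columns missing from input: {missing_cols}")

        stage = "missing-data"
        n_input = len(df)
        analysis_cols = _analysis_columns(config, df)
        keep = df[analysis_cols].notna().all(axis=1)
        dropped_by_col = {
            c: int(df[c].isna().sum()) for c in analysis_cols if df[c].isna().any()
        }
        df = df.loc[keep].reset_index(drop=True)
        log["rows"] = {
            "input": n_input,
            "analyzed": int(keep.sum()),
            "dropped": int(n_input - keep.sum()),
            "dropped_by_variable": dropped_by_col,
        }
        logger.info("rows: %s", log["rows"])

        stage = "wealth"
        w = df[config.weight].to_numpy(dtype=float)
        if config.wealth_score and config.wealth_score in df.columns:
            scores = df[config.wealth_score].to_numpy(dtype=float)
        elif config.asset_columns:
            hh_scores = compute_asset_scores(df[config.asset_columns])
            scores = hh_scores
        else:
            raise KeyError("neither a wealth score column nor asset columns found")
        df["_score"] = scores
        df["_rank"] = fractional_rank(scores, w)
        df["wealth_quintile_cat"] = pd.Categorical(
            [f"Q{q}" for q in assign_quintiles(scores, w)],
            categories=[f"Q{q}" for q in range(1, 6)],
        )

        covs = {k: v for k, v in config.covariates.items() if k in df.columns}

        stage = "descriptives"
        _write(sample_profile(df, list(covs), weight=config.weight), "table1.csv")
        t2 = []
        for cov in covs:
            tab = prevalence_by(df, cov, outcome=config.outcome, weight=config.weight)
            tab.insert(0, "variable", cov)
            counts = weighted_outcome_table(
                df, cov, outcome=config.outcome,
                weight=config.weight if config.weighted_chi_square else None,
            )
            try:
                stat, dof, p = chi_square_independence(counts.to_numpy())
                tab["chi2_p"] = [p] * len(tab)
            except ValueError:
                tab["chi2_p"] = np.nan
            if cov in _ORDERED_COVARIATES and counts.shape[0] >= 3:
                ordered = counts[[1, 0]].to_numpy()
                z, p_trend = cochran_armitage_trend(ordered)
                tab["trend_p"] = [p_trend] * len(tab)
            t2.append(tab)
        _write(pd.concat(t2, ignore_index=True), "table2.csv")

        stage = "logistic"
        t3 = fit_weighted_logistic(
            df, covs, outcome=config.outcome, weight=config.weight
        )
        _write(t3, "table3.csv")

        stage = "inequality"
        ci_est = ConcentrationIndex(use_ranks=True).fit(
            df["_rank"].to_numpy(), df[config.outcome].to_numpy(dtype=float),
            sample_weight=w,
        )
        log["concentration_index"] = ci_est.C_
        log["prevalence_pct"] = 100.0 * ci_est.mu_
        _write(
            pd.DataFrame(ci_est.curve_, columns=["cum_population", "cum_outcome"]),
            "curves/overall.csv",
        )
        if config.stratum and config.stratum in df.columns:
            results, skipped = stratified_ci(
                df, config.stratum, outcome=config.outcome,
                score="_score", weight=config.weight,
            )
            rows = [
                {"stratum": k, "C": r.C, "mu": r.mu, "n": r.n}
                for k, r in results.items()
            ]
            rows += [
                {"stratum": k, "C": np.nan, "mu": np.nan, "n": 0, "skipped": why}
                for k, why in skipped.items()
            ]
            _write(pd.DataFrame(rows), "state_ci.csv")
            for k, r in results.items():
                _write(
                    pd.DataFrame(r.curve, columns=["cum_population", "cum_outcome"]),
                    f"curves/{k}.csv",
                )

        stage = "decomposition"
        X, groups = build_dummies(df, covs)
        dec = wagstaff_decompose(
            df[config.outcome].to_numpy(dtype=float), X, df["_score"].to_numpy(),
            weights=w, percentage_denominator=config.percentage_denominator,
        )
        t4 = dec.table.reset_index(names="regressor")
        t4["covariate"] = [r.split("[")[0] for r in t4["regressor"]]
        gt = dec.group_totals(groups).rename(columns={"group": "covariate"})
        footer = pd.DataFrame(
            {
                "regressor": ["Calculated CI", "Actual CI", "Residual"],
                "absolute_contribution": [dec.explained_ci, dec.actual_ci,
                                          dec.residual],
            }
        )
        _write(pd.concat([t4, footer], ignore_index=True), "table4.csv")
        _write(gt, "table4_groups.csv")
        log["decomposition"] = {
            "explained_ci": dec.explained_ci,
            "actual_ci": dec.actual_ci,
            "residual": dec.residual,
        }

        with open(out / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2)
        created.append(out / "run_log.json")
        return log
    except Exception:
        logger.exception("pipeline failed at stage %r; removing partial outputs",
                         stage)
        for p in created:
            p.unlink(missing_ok=True)
        if (out / "curves").exists():
            shutil.rmtree(out / "curves", ignore_errors=True)
        raise
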