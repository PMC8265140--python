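# healthineq

Socio-economic inequality analysis of binary health outcomes in complex
survey microdata.

Public-health surveys show that conditions like anaemia fall hardest on
the poor, but a prevalence table does not say *how much* of the burden is
concentrated at the bottom of the wealth distribution or which covariates
carry that concentration.  `healthineq` implements the standard
health-equity measurement chain for epidemiologists and health economists
working with DHS-style household survey data:

- **Wealth index** — household asset score from the first principal
  component of standardized asset indicators, population-weighted
  quintiles, and the weighted fractional rank *R* ∈ (0, 1);
- **Concentration index and curve** — C = (2/μ) cov_w(y, R), overall and
  by stratum, with the curve above the diagonal exactly when C < 0
  (outcome concentrated among the poor);
- **Association screens** — weighted prevalence tables, chi-square,
  Cochran–Armitage trend test, VIF multicollinearity check, and
  survey-weighted logistic regression with odds ratios and Wald 95% CIs;
- **Wagstaff decomposition** — from a weighted linear probability model
  y = α + Σ β_k x_k + ε, the index decomposes exactly as
  C = Σ_k (β_k x̄_k / μ) C_k + (2/μ) cov_w(ε, R), splitting inequality
  into per-covariate contributions (elasticity × regressor index) plus an
  unexplained residual;
- **Synthetic survey generator** — a two-stage cluster sample with latent
  household affluence, binary assets, eleven categorical covariates, a
  planted logistic outcome model and exact haemoglobin/threshold
  consistency, with a sidecar ground-truth file so every stage is testable
  without restricted microdata.

The estimators follow scikit-learn conventions (`fit`, fitted attributes
with trailing underscores, `get_params`/`set_params`) and are wrapped by
plain functions; everything composes with pandas DataFrames.

## Worked example

```python
import pandas as pd
from healthineq import (SimulationConfig, generate_dataset, fractional_rank,
                        concentration_index, wagstaff_decompose)
from healthineq.models import build_dummies
from healthineq.decomposition import group_contributions

cfg = SimulationConfig(seed=7, n_clusters=400)   # ~14,000 men
df = generate_dataset(cfg)
w, y, s = df["weight"].to_numpy(), df["anaemic"].to_numpy(float), df["wealth_score"].to_numpy()

res = concentration_index(y, fractional_rank(s, w), w)
print(f"weighted prevalence = {100*res.mu:.1f}%")
print(f"concentration index C = {res.C:.4f}")

df["wq"] = pd.Categorical([f"Q{q}" for q in df.wealth_quintile])
covs = {"education": "no_education", "bmi_class": "normal",
        "residence": "urban", "region": "north", "wq": "Q1"}
X, groups = build_dummies(df, covs)
dec = wagstaff_decompose(y, X, s, weights=w)
print(f"explained (calculated) CI = {dec.explained_ci:.4f}")
print(f"residual = {dec.residual:.4f}")
print(group_contributions(dec, groups).round(3).to_string(index=False))
```

prints

```
weighted prevalence = 23.8%
concentration index C = -0.1083
explained (calculated) CI = -0.1045
residual = -0.0039
    group  absolute_contribution  percentage_contribution
education                 -0.001                    0.523
bmi_class                  0.001                   -0.917
residence                  0.000                   -0.024
   region                 -0.000                    0.359
       wq                 -0.105                  100.060
```

Reading this: anaemia affects 23.8% of the simulated men and C = −0.11
means it is concentrated among the poor (the concentration curve lies
above the line of equality).  The decomposition splits C into a part
explained by the regressors (−0.1045) and a residual (−0.0039), which sum
to C exactly.  Because this synthetic population plants inequality purely
through wealth, the wealth-quintile group accounts for essentially all of
the explained index (≈100%), while covariates drawn independently of
wealth contribute ≈0 — exactly the pattern the generator is designed to
make verifiable.

## Command line

```sh
healthineq simulate --seed 1 --n-clusters 400 --out survey.csv --truth-out truth.json
healthineq inequality survey.csv --out curve.csv
healthineq decompose survey.csv --out table4.csv
healthineq all --config pipeline.yaml        # full report bundle
```

`healthineq all` writes table1–table4 CSVs (sample profile, prevalence
with tests, odds ratios, decomposition), concentration-curve coordinates
per stratum, a per-stratum index table and a JSON run log with seed and
row accounting (input = analyzed + dropped under complete-case deletion).

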