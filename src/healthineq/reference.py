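"""Published reference values for the Indian men's anaemia inequality study.

Decomposition table of the national NFHS-4 (2015-16) analysis of anaemia
among men aged 15-54, as printed: per-dummy coefficient (linear probability
model), elasticity, regressor concentration index, absolute contribution to
the outcome concentration index, and percentage contribution (explained-CI
denominator), plus group percentage totals and the index footer.  The
printed cells are mutually redundant (contribution = elasticity x CI, group
totals = member sums, residual = actual - calculated), which makes the
table a self-contained arithmetic fixture for the decomposition code path.

Values are rounded as printed (3 decimals for coefficients through
contributions, 1 decimal for percentages), so re-derived quantities carry
the propagated rounding error of their inputs.
"""

from __future__ import annotations

# regressor -> (coefficient, elasticity, ci, absolute_contribution, pct_contribution)
DECOMPOSITION_ROWS: dict[str, tuple[float, float, float, float, float]] = {
    "age[20-29]": (-0.360, -0.020, 0.010, 0.000, 0.7),
    "age[30-39]": (-0.240, -0.012, -0.002, 0.000, -0.1),
    "age[40-49]": (-0.042, -0.003, 0.016, 0.000, 0.2),
    "age[50-54]": (0.179, 0.003, 0.043, 0.000, -0.4),
    "marital[currently_married]": (-0.013, 0.001, -0.013, 0.000, 0.0),
    "education[primary]": (-0.102, -0.003, -0.278, 0.001, -3.3),
    "education[secondary]": (-0.184, -0.019, 0.030, -0.001, 2.0),
    "education[higher]": (-0.349, -0.010, 0.440, -0.005, 15.8),
    "media[exposure]": (-0.068, -0.014, 0.054, -0.001, 2.7),
    "bmi[underweight]": (0.411, 0.016, -0.219, -0.003, 11.9),
    "bmi[overweight]": (-0.222, -0.006, 0.309, -0.002, 5.9),
    "tobacco[yes]": (-0.079, -0.004, -0.149, 0.001, -2.2),
    "caste[scheduled_caste]": (-0.036, 0.001, -0.157, 0.000, 0.3),
    "caste[scheduled_tribe]": (0.283, 0.006, -0.420, -0.002, 8.4),
    "caste[other_backward_class]": (-0.036, 0.001, 0.014, 0.000, -0.1),
    "religion[muslim]": (-0.130, -0.003, 0.038, 0.000, 0.3),
    "religion[others]": (-0.033, 0.001, 0.229, 0.000, -0.7),
    "wealth[poorer]": (-0.107, -0.003, -0.512, 0.002, -5.9),
    "wealth[middle]": (-0.187, -0.006, -0.110, 0.001, -2.4),
    "wealth[richer]": (-0.253, -0.008, 0.323, -0.003, 8.8),
    "wealth[richest]": (-0.287, -0.009, 0.772, -0.007, 24.6),
    "residence[rural]": (0.115, 0.016, -0.230, -0.004, 12.6),
    "region[central]": (0.012, 0.003, -0.161, -0.001, 1.9),
    "region[east]": (0.334, 0.015, -0.339, -0.005, 17.9),
    "region[northeast]": (-0.294, 0.000, -0.253, 0.000, 0.4),
    "region[west]": (-0.134, -0.002, 0.156, 0.000, 1.1),
    "region[south]": (-0.070, 0.001, 0.186, 0.000, -0.3),
}

GROUP_PCT_TOTALS: dict[str, float] = {
    "age": 0.4,
    "marital": 0.0,
    "education": 14.6,
    "media": 2.7,
    "bmi": 17.8,
    "tobacco": -2.2,
    "caste": 8.6,
    "religion": -0.4,
    "wealth": 25.1,
    "residence": 12.6,
    "region": 20.9,
}

CALCULATED_CI = -0.029  # explained component
ACTUAL_CI = -0.121
RESIDUAL_CI = -0.092
NATIONAL_CI = -0.12  # headline national index as reported
NATIONAL_PREVALENCE_PCT = 23.3


def group_members(group: str) -> list[str]:
    return [k for k in DECOMPOSITION_ROWS if k.startswith(group + "[")]
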