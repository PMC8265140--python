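# Methods

## The measurement problem

Health surveys routinely show that a condition such as anaemia is more
common among the poor, but a prevalence table by wealth quintile does not
quantify *how much* of the burden is concentrated at the bottom of the
wealth distribution, nor which covariates carry that concentration.
`healthineq` implements the standard health-economics answer for complex
survey microdata: rank individuals by a household wealth score, summarise
inequality with the concentration index, and decompose the index into
covariate contributions through a linear model.

## Wealth index and fractional ranks

Household socio-economic position is scored as the first principal
component of the standardized household asset indicators (binary ownership
variables).  Zero-variance indicators are dropped with a warning; the
component sign is fixed so that owning more assets raises the score.  The
household score is replicated to every de jure member, and all ranking is
done at the individual level with sampling weights.

The weighted fractional rank of individual *i* with normalized weights
*ŵ* is

    R_i = Σ_{j<i} ŵ_j + ŵ_i / 2        (individuals sorted by score)

Tied scores receive the shared midpoint rank of their tie group
(Lerman–Yitzhaki convention).  This makes the rank — and everything built
on it — invariant to the ordering within ties, and keeps the weighted mean
of *R* exactly 1/2 for any weights.  Wealth quintiles label each
individual by the quintile containing the midpoint of its cumulative
weight interval, so quintile cuts are population-weighted (each holds a
20% weight share up to tie granularity) and tied scores always share a
label.  An individual whose own weight straddles a cut keeps the quintile
of its midpoint; the 20% share can break only at such a tie.

## Concentration index and curve

For outcome *y* with weighted mean μ > 0,

    C = (2 / μ) Σ_i ŵ_i (y_i − μ)(R_i − R̄)

the population (normalized-weight) covariance form with no n/(n−1)
correction — the defining formula carries none.  C ∈ [−1, 1]; for a binary
outcome |C| ≤ 1 − μ (μ ≤ 1/2).  Negative C means the outcome concentrates
among the poor, in which case the concentration curve — cumulative outcome
share against cumulative population share, poorest first — lies above the
diagonal.  A Wagstaff normalization C/(1 − μ) for binary outcomes is
available (`wagstaff_normalize=True`) but off by default, since the plain
index is the primary quantity reported here.  Stratified indices recompute
fractional ranks within each stratum; strata with a constant wealth score
or a constant/zero-mean outcome are skipped with an explicit reason rather
than erroring the whole run.  The pooled index is not the mean of stratum
indices (the pooled ranking mixes strata); the test suite demonstrates
this on a constructed two-stratum example.

The curve ranks by the continuous wealth score, not by quintile: the score
is the finer ranking variable and the one used for the decomposition.

## Weighted logistic regression

Covariate associations are estimated by logistic regression maximising the
weighted log-likelihood Σ ŵ_i [y_i log p_i + (1−y_i) log(1−p_i)] via
iteratively reweighted least squares (statsmodels GLM with frequency
weights).  Sampling weights are treated as analytic weights normalized to
mean 1, so standard errors reflect the actual sample size and rescaling
all weights changes nothing.  Wald 95% intervals on the odds-ratio scale
are reported per dummy against a declared reference level.  Cluster-robust
standard errors are deliberately not applied by default — the reported
intervals are model-based — and a coefficient exceeding 15 in absolute
value is treated as complete separation and raised as an error naming the
regressor.  The intercept of the null model equals the logit of the
weighted prevalence (a closed-form identity used as a test).

Anaemia grading for men follows the WHO haemoglobin cut-offs: any anaemia
below 13.0 g/dL, mild 12.0–12.9, moderate 9.0–11.9, severe below 9.0.
Two boundary choices are fixed and documented here: a reading of exactly
13.0 g/dL is non-anaemic, and the severe/moderate boundary is closed at
9.0 (severe iff hb < 9.0).  Readings outside 2–25 g/dL warn; non-finite
readings raise.

## Wagstaff decomposition

With a weighted OLS (linear probability) fit y_i = α + Σ_k β_k x_ki + ε_i,

    C = Σ_k (β_k x̄_k / μ) C_k + (2/μ) cov_ŵ(ε, R)

where η_k = β_k x̄_k/μ is the elasticity and C_k the concentration index
of regressor k against the *same* ranks and weights.  OLS rather than a
nonlinear marginal-effects variant is essential: the additive identity
then closes exactly (to float precision), which the suite asserts at
1e−10 on random instances.  Contributions are computed from the covariance
form 2 β_k cov_ŵ(x_k, R)/μ, which equals η_k C_k whenever x̄_k ≠ 0 and
remains defined for a zero-mean regressor (where C_k itself is not).  The
residual is also recomputed independently from the OLS error term and
stored as a consistency check (`residual_check`, agreeing to 1e−8).

Percentage contributions divide by the explained ("calculated") index by
default; the actual index is available as an alternative denominator.
Group totals sum member contributions and require the grouping to
partition the columns.

## Synthetic survey generator

Real national survey microdata of this kind is restricted, so validation
rests on a generator that emulates the relevant design features with known
ground truth:

- **Two-stage sampling**: `n_clusters` PSUs × `households_per_cluster`
  households; household size is 1 + Poisson(mean − 1) eligible men
  (default mean 1.4, so the default 100 × 25 design yields ≈ 3,500
  individuals).
- **Latent affluence** per household: standard normal with a cluster-level
  component (SD 0.3) inducing intra-cluster wealth correlation.
- **Assets**: ten binary indicators with ownership probability
  logistic(loading × affluence + offset), offsets spread over ±1.5 so the
  goods range from common to rare.  The wealth score is the package's own
  PCA score of these assets — the generator exercises the same scoring
  path as real data; the latent affluence is emitted alongside so tests
  can verify the score recovers it (correlation > 0.8).
- **Covariates**: eleven categorical variables (age group, marital status,
  education, mass-media exposure, BMI class, tobacco use, caste, religion,
  residence, region) drawn independently from marginals matching a
  national men's survey profile.
- **Outcome**: anaemic ~ Bernoulli(logistic(intercept + Σ level
  coefficients + wealth_effect × standardized wealth score)).  Default
  coefficients carry the directions and magnitudes typical of national
  estimates (higher risk for underweight, rural, eastern-region, older and
  scheduled-tribe men; lower with education and wealth).
- **Haemoglobin**: drawn *conditionally on* the simulated binary outcome
  from truncated normals below/above 13.0 g/dL (anaemic: N(11.5, 1.5²) on
  (2, 13); non-anaemic: N(14.8, 1.3²) on [13, 25)).  This guarantees exact
  threshold consistency — the fraction below 13.0 equals the anaemia rate
  by construction — which is the property the classifier tests need.
- **Weights**: log-normal with configurable dispersion (default σ = 0.3),
  normalized to mean 1; dispersion 0 gives a self-weighting sample.
- **Determinism**: a single seeded NumPy generator threads through every
  draw; identical config + seed gives byte-identical output.

The defaults were calibrated once so a large reference draw shows weighted
prevalence ≈ 23.3% and concentration index ≈ −0.12 — the national scale
the package is meant to exercise — by setting intercept −0.90 and
wealth_effect −0.285; they are fixed constants, not tuned per run.
`planted_truth` records the ground truth (prevalence, planted
coefficients, large-sample index from a ≥10⁵ reference draw) to a sidecar
file for recovery tests; it refuses reference sizes below 1,000 as
unstable.

What the generator does **not** emulate: non-response and its interaction
with weights, DHS recode file formats, within-household covariate
correlation, spatial structure beyond the categorical region label, and
covariate–wealth dependence (covariates are drawn independently of the
wealth score, so in synthetic data the planted inequality flows almost
entirely through the wealth variable itself — which is why recovery tests
expect the wealth group to dominate the decomposition, and why passing
them shows the arithmetic is right, not that real-world covariates would
decompose the same way).

## Descriptive screens

Prevalence tables are weighted means by covariate level, in percent.  The
chi-square test runs on weighted counts rescaled to the unweighted total
(p-values are approximate under clustering; an unweighted variant is
available).  The Cochran–Armitage trend test uses unweighted counts and
integer scores 1..k by default; its Z is invariant to affine score changes
and antisymmetric under level reversal.  VIF_j = 1/(1 − R²_j) from
least-squares regression of each column on the others; perfect
collinearity reports ∞ rather than crashing, and VIF > 10 is flagged.

## Numerical choices and problem sizes

- Rank/index arithmetic is plain float64; identities are asserted at
  1e−10, consistency checks at 1e−8.
- The PCA eigensolver is `numpy.linalg.eigh` on the correlation matrix of
  standardized indicators (deterministic; sign fixed by the asset-sum
  correlation).
- IRLS converges at a 1e−8 tolerance within 100 iterations;
  non-convergence flags the result instead of raising.
- Rank deficiency in the decomposition design is detected by matrix rank
  and reported with the collinear columns found by pivoted QR.
- Recovery checks use twenty ~50,000-person draws for the concentration
  index and five of those draws for logistic coefficient recovery;
  null-calibration uses one ~100,000-person draw and 1,000 small-sample
  trend-test replicates.  These sizes give Monte-Carlo error comfortably
  inside the asserted tolerances while keeping the default suite fast.

## Known limitations

- No standard errors or dominance tests for the concentration index.
- No design-corrected (Rao–Scott) chi-square and no cluster-robust
  regression intervals by default.
- The decomposition offers no Oaxaca-style between-group variant.
- Quintile weight shares are exact only up to tie granularity.
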