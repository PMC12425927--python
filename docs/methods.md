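# Methods

`soymeta` implements a quantitative synthesis of paired
monoculture-versus-intercropping observations of soil microbial community
traits (Shannon, Chao1, richness, β-diversity, community structure) and
soybean yield. This note documents the statistical model, the conventions
chosen where the methodology is genuinely open, the synthetic-data
generator that stands in for a literature corpus, and the numerical
choices that matter for reproducing results.

## Effect sizes

Every mean-valued trait enters the synthesis as a natural-log response
ratio,

    lnRR = ln(x_t / x_c),

with `x_t` the intercropping (treatment) mean and `x_c` the monoculture
(control) mean, and sampling variance

    v = s_t² / (n_t x_t²) + s_c² / (n_c x_c²),

the sum of each arm's squared coefficient of variation over its replicate
count. Both means must be strictly positive; rows violating this are
rejected at load time with a row-level validation report.

**SD imputation.** Observations reporting a mean without a standard
deviation receive `sd = mean × CV̄`, where `CV̄` is the average
coefficient of variation over rows that do report SDs. The averaging
stratum is trait × arm by default (treatment CVs pooled separately from
control CVs within each trait), which prevents a high-CV trait such as
yield from contaminating the imputed spread of a low-CV diversity index;
a global per-arm pool is available via `pool="global"`. Imputation never
touches a reported SD and is idempotent. A stratum containing no reported
SD at all either raises (default) or leaves the rows missing, in which
case they are dropped from variance-weighted fits with a warning.

**Density screening.** Planting-density comparability is standardized by
the relative density total, `RDT = d1_ic/d1_sc + d2_ic/d2_sc` (1 =
replacement design, >1 = additive design) and, for soybean alone,
`pRDT = d_ic/d_sc`. Observations with a measured RDT below 1 are excluded;
rows with unreported RDT are retained, because the exclusion is by
measured value, not by missingness. Multi-season studies contribute only
their final-year rows (the `is_final_year` flag is this package's
convention for marking them; a study with no flagged row is kept whole
with a warning rather than silently dropped).

## Ordination-derived responses

Published β-diversity and community-structure results usually appear as
2D ordination plots (NMDS, PCA, PCoA, RDA). Given sample coordinates on
the first two axes (no weighting by explained variance), the package
computes mean pairwise Euclidean distances within the control group
(`D_c`), within the treatment group (`D_t`), and across groups (`D_b`),
each unordered pair counted once.

- β-diversity response: `lnRRb = ln(D_t / D_c)` — a dispersion ratio,
  zero when the two groups are equally dispersed.
- Structure response, two conventions:
  - `as_printed`: `ln(D_t / (D_c + D_t))`. This form is algebraically
    bounded above by zero for positive distances.
  - `between_within` (default): `ln(D_b / ((D_c + D_t)/2))` — the
    between-group separation against the mean within-group dispersion.
    This is the only reading consistent with large *positive* structure
    contrasts, which a separation of group centroids produces; it is
    invariant to rigid motions of the coordinates and strictly increasing
    in centroid separation at fixed dispersions.

Because the printed formula and the sign of reported structure effects
cannot both be right, the ordination report stage always emits **both**
conventions side by side rather than silently resolving the ambiguity.
A group whose points coincide yields a zero within-group distance; it is
flagged degenerate and the log ratios are left undefined for that set.

## Pooling model

Observations are nested within articles, so pooling uses a three-layer
random-effects model

    y_ij = μ + b_i + u_ij + e_ij,
    b_i ~ N(0, τ²_study),  u_ij ~ N(0, τ²_obs),  e_ij ~ N(0, v_ij known),

the minimal structure honouring both between-study heterogeneity and
within-study non-independence. Sampling variances are treated as known
(the standard meta-analytic contract). Variance components are estimated
by REML using Fisher scoring with step-halving; non-negativity is
enforced by projection onto the orthant with active-set handling at the
boundary (a component pinned at zero with an outward-pointing score is
frozen; KKT conditions terminate the iteration). Convergence is declared
at a restricted-log-likelihood change below 1e-8, with a 200-iteration
cap; a component below 1e-10 at convergence is reported as exactly 0,
never an epsilon. With one observation per study the study and residual
design matrices coincide and the two components are not separately
identifiable; the study component is then pinned at zero and all excess
heterogeneity loads on τ²_obs.

Inference is Wald (z): 95% CI = μ ± 1.96·se, and an effect is
"significant" exactly when the CI excludes zero. The implementation was
cross-checked against metafor's `rma.mv` (REML, `random = ~1|study/obs`)
on frozen fixtures; agreement is ~1e-6 on μ and ~0.1% on the variance
components.

**Subgroups.** A categorical moderator replaces the intercept with one
dummy per level, sharing the two variance components across levels. The
omnibus Q_M statistic is the Wald chi-square for *equality of level
means* (df = levels − 1), not the test that all level means are zero.
When Q_M is significant at α, all level pairs are compared with
single-step max-|z| adjusted p-values (Tukey-style), approximated by
100 000 seeded Monte-Carlo draws from the joint normal of the contrasts;
with a single contrast the adjusted p equals the unadjusted two-sided p,
and the adjustment is floored at the unadjusted value. A singular
contrast covariance falls back to Bonferroni with a warning.

## Publication bias

Rosenthal's fail-safe number uses one-tailed α = 0.05 (the classical
convention; tailing is taken in the direction of the combined z-sum):
`N_fs = floor((Σ z_i)²/z_α² − k)`, floored at zero, with the robustness
rule `N_fs > 5k + 10`. The Begg-type rank test correlates
variance-standardized deviates from the *fixed-effect* pooled mean
(classical form) with the sampling variances; tau is tie-corrected
(tau-b), and the two-sided p comes from exhaustive permutation
enumeration for k ≤ 8 and a continuity-corrected normal approximation
with tie-corrected variance otherwise. Completely tied inputs carry no
asymmetry signal and report (τ=0, p=1).

## Continuous moderators

Meta-regression is weighted least squares with weights `1/(v_i + τ²)`,
where τ² (study + observation components summed) comes from a single
preliminary intercept-only multilevel fit and is held fixed across
candidate forms — so AIC/BIC comparisons share one weighting and the
nested-R² inequality (quadratic ≥ linear) holds exactly. Coefficient
covariance uses the known-variance convention `(XᵀWX)⁻¹` without
residual rescaling; AIC/BIC come from the Gaussian likelihood with the
same known per-row variances. Candidate forms are linear and quadratic;
selection is lowest AIC, ties broken by lower BIC, then fewer
parameters. (Note a consequence of pure-AIC selection: under a true
linear model the spurious quadratic term is kept whenever its Wald
chi-square gain exceeds 2, so the linear form is retained with
probability ≈ P(χ²₁ < 2) ≈ 0.84, not more.)

A concave quadratic fit is summarized by its turning point
`x* = −b₁/(2b₂)`, its real roots, and the open interval where the fitted
lnRR is positive — e.g. the range of the Shannon response within which
intercropped yield beats monoculture, or the nitrogen rate beyond which
diversity declines. A convex fit with no real roots and positive vertex
is positive everywhere; a convex fit with roots has no single positive
interval and reports none.

Mantel and partial Mantel tests correlate lower-triangle distances with
a one-sided (greater) permutation p. When n! fits within the permutation
budget the null is enumerated exhaustively (exact p); otherwise seeded
random relabelings are drawn and the add-one estimator keeps p strictly
positive. The partial test residualizes both triangles on the
conditioning triangle; a residual that collapses to zero (conditioning
matrix identical to the tested one) defines a partial r of 0.

Moderator importance ranks continuous covariates by permutation
importance from a seeded random-forest regressor: the forest is trained
on 70% of complete rows and importance is the mean increase in held-out
squared error over 10 seeded column permutations — comparable across
predictors of different scales, unlike impurity importance.

## Synthetic-data generator

The generator produces seeded study databases with known truth so every
stage is testable without downloads. Per study `i` a random effect
`b_i ~ N(0, τ²_study)` is drawn; per observation the latent effect is
`θ = μ_true[trait] + moderator shifts + b_i + N(0, σ²_obs)`. The true
control mean is LogNormal(meanlog 1, sdlog 0.3) — positive by
construction — and the true treatment mean `x_c e^θ`. Observed arm means
then carry mean-preserving multiplicative lognormal sampling error of
magnitude `cv_arm/√n_per_arm`: the log-scale Jensen bias is identical in
both arms and cancels in lnRR, while the observed lnRR scatters around θ
with variance close to its nominal sampling variance `v`. This last
ingredient is what makes variance-weighted pooling *calibrated* on
generator output (95% CIs cover at ≈95%); without it the known `v`
would overstate the actual scatter several-fold and every CI would
cover. With `cv_arm = 0` the observed lnRR equals θ exactly (the
noise-free limit used in exactness tests).

Defaults are chosen to emulate a soil-microbial intercropping corpus:
true effects {shannon 0.036, chao1 0.034, richness 0.102, β −0.098,
structure 0.741, yield −0.020}; τ_study = 0.05, σ_obs = 0.03 (small
relative to typical v ≈ 0.02); within-arm CV 0.2 with n = 4 replicates
per arm; 20% of SDs masked missing to exercise imputation; nitrogen rate
uniform on 0–300 kg N ha⁻¹ and the other covariates over standard
agronomic ranges. The quadratic yield link defaults to
`y = −s² + 0.424·s − 0.00633` (turning point 0.212, positive response
roughly over 0.016–0.41 of the Shannon response). Ordination clouds are
two isotropic Gaussians with unit dispersion and centroid separation 3.4
at n = 5 per group, calibrated so the emulated between/within structure
contrast is ≈ 0.74.

Random streams are split hierarchically by (study, observation) index
via `numpy.random.SeedSequence`, so enlarging a database never reshuffles
earlier studies, and a fixed seed yields byte-identical CSV output.

**What the generator does not emulate:** the empirical covariate joint
distribution of a real corpus (covariates are independent uniforms),
selective reporting or true publication bias, non-normal heterogeneity,
correlated effect sizes from shared control arms, or digitization error
in extracted ordination coordinates. Passing recovery and coverage tests
therefore demonstrates internal statistical correctness under the
assumed model, not robustness to those real-data pathologies.

## Problem sizes and numerical conventions

The test suite runs replicate studies at deliberately modest sizes — 200
databases of 30 studies × 3 observations for recovery/coverage, 500 null
replicates of 20 studies × 3 observations for Q_M and k = 20 for the
Kendall type-I checks — sizes at which the whole suite completes in well
under a minute while Monte-Carlo bands (±0.005 on the mean, 90–98%
coverage, 3–8% rejection) remain informative. The acceptance script uses
a corpus-scale database (89 articles × 4 observations) for the pooled
tables and 100 replicate databases for the recovery summary.

Degenerate inputs follow fixed conventions: a single effect size returns
(y, √v) with zero variance components; all-identical subgroup levels give
Q_M ≈ 0; permutation p-values are never exactly zero unless the null is
enumerated exhaustively; tau-squared estimates landing at the boundary
report exactly 0. All randomness — simulation, permutation tests,
post hoc Monte Carlo, forest fitting — flows from explicit integer seeds,
and the full pipeline is a pure function of (input files, config, seed):
reruns are byte-identical, verified file-by-file in the tests.
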