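# Methods

This note documents the statistical model behind `metarr`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not establish.

## Effect sizes and sampling variances

For one effect size comparing group 1 (mean m₁, SD sd₁, n₁ replicates)
with group 2 (m₂, sd₂, n₂), all on a ratio scale (m > 0 required), the
raw log response ratio is lnRR = ln(m₁/m₂).  Because ln(m̄) is a biased
estimator of ln(μ) in small samples, a second-order Taylor correction is
added when CVs (CV = sd/m) are available:

    lnRR₂ = ln(m₁/m₂) + ½ (CV₁²/n₂ − CV₂²/n₁)

and the second-order sampling variance is

    v = CV₁²/n₁ + CV₂²/n₂ + CV₁⁴/(2n₁²) + CV₂⁴/(2n₂²).

**A note on the correction term's indices.**  The point-estimate
correction is implemented with crossed sample-size indices (CV₁² over n₂
and CV₂² over n₁), exactly as printed in the formulation this package
follows; a first-principles delta-method expansion of E[ln m̄] gives the
uncrossed pairing.  The two agree whenever n₁ = n₂, and when group
sample sizes vary symmetrically (as in the simulation harness, where n₁
and n₂ are i.i.d.) the difference is mean-zero.  The variance formulas
are unaffected.  Users who need the uncrossed form can assemble it from
`cv()` and `lnrr_raw()` directly.

### Pooled CVs

When some studies do not report SDs, the unknown CVs are replaced by the
square of a *weighted-average CV* (not an average of CV² — squared CVs
are much more sensitive to outlying CVs from skewed raw data).  The
pooling is nominally two-stage — within each study, CVs are averaged
with group sample sizes as weights; across studies, the study means are
averaged weighted by each study's summed group n — but with these
weights the two stages collapse algebraically to the single
sample-size-weighted mean Σ nᵢCVᵢ / Σ nᵢ over all SD-reporting records.
The code implements that equivalent form.  A record missing only one
group's SD is treated as "SD missing" for strategy dispatch, but its
reported group still contributes to the pool for that group (no
information is discarded).

Pooled CVs are always estimated from the full input dataset's
SD-reporting records, never from a post-filter subset.

### The improved Geary screen

The Taylor corrections assume the group means are approximately normal,
which fails for strongly overdispersed (CV > 1) data at small n.  The
screen (1/CV)·4n^{3/2}/(1+4n) ≥ 3 is applied per group; a record passes
only if both groups pass.  At CV = 5 the smallest passing n is 226
(`geary_min_n(5)`), so overdispersed count-like data essentially never
qualify.  The screen is exposed as a filter utility
(`geary_pass`) and reported by the CLI, but never applied implicitly:
excluding effect sizes is a sensitivity analysis, not a default.  When
many effects fail, `variance_order="first"` switches the pooled
variances to their first-order form (dropping the quartic terms) and the
pooled point correction to the raw log ratio, which do not rely on the
second-order expansion.

## Missing-SD strategies

Writing v for the own-CV second-order variance and ṽ for the pooled-CV
variance with the record's own sample sizes:

| strategy        | SD reported | SD missing | φ-scaled entries |
|-----------------|-------------|------------|------------------|
| reference       | v           | —          | none             |
| complete-case   | v (rest dropped) | dropped | none            |
| missing-cases   | v           | ṽ          | none             |
| all-cases       | ṽ           | ṽ          | none             |
| multiplicative  | ṽ           | ṽ          | all              |
| hybrid          | v           | ṽ          | missing only     |

Point estimates are shared: the corrected lnRR from own CVs where SDs
exist, from pooled CVs where they do not (`point_estimate="pooled"`
switches the complete records to pooled CVs as well; the choice makes
little practical difference).  Complete-case exists purely as the
comparator practice the other strategies are designed to replace.

## The REML model

The multilevel model for effect j in study i is

    y_ij = β₀ + s_i + u_ij + m_ij,
    s_i ~ N(0, σ²ₛ),  u_ij ~ N(0, σ²ᵤ),  m_ij ~ N(0, V_ij),

with V_ij either the known v_ij or φ·ṽ_ij on entries the strategy
flagged as proportional; a single scalar φ is shared by all flagged
entries.  The random-effects variant (`levels="re"`) drops u_ij.
Because studies are independent the marginal covariance is block
diagonal with blocks D + σ²ₛ·11′; the restricted likelihood is evaluated
through the rank-one Woodbury identity and per-study grouped sums, so
one evaluation is O(N) whatever the study sizes.  The REML constant
includes ½log|X′X| (= ½log N for the intercept-only design), so
`loglik_reml` is directly comparable with mainstream meta-analysis
software.

Numerical choices:

- Variance parameters (and φ) are optimised on the log scale, floored at
  1e-10 (φ bounded in [1e-8, 1e8]); the floor is part of the model
  definition, and components that converge to it are reported as exact
  zeros.  Zero-heterogeneity boundaries are common at low τ².
- Three dispersed starts (a moment-based start ±2.5 on the log scale,
  with φ dispersed in the opposite direction to probe variance/φ
  trade-off basins) followed by L-BFGS-B and a derivative-free
  Nelder-Mead polish.  On small datasets the optimum matches a dense
  grid-plus-refinement search to ~1e-6 in log-likelihood.
- β₀ and its SE are the GLS mean and information at the converged
  variance parameters; CIs are Wald z by default.  Wald t (df = k − 1)
  is provided because coverage is sensitive to this choice at small K;
  the default matches standard meta-analytic software.  No
  Knapp–Hartung-type adjustment is implemented.
- I² uses τ²(total)/(τ² + v̄) with the Higgins–Thompson typical sampling
  variance v̄ computed from the model's effective diagonal (φ-scaled
  entries are multiplied by the estimated φ).  The study-level-only
  variant σ²ₛ/(τ² + v̄) is exposed as `i2_study`.  Under a masked φ-mode
  whose mask is all-false, φ drops out of the model; all-true masks are
  fitted as the all-scaled mode.
- A sampling variance of exactly zero (e.g. sd = 0 in both groups)
  raises an error before fitting: a zero diagonal in V is singular.

## Simulation harness

`simulate_dataset` draws K studies; study effects s_i ~ N(0, ICC·τ²) and
effect-level deviations u_ij ~ N(0, (1−ICC)·τ²) place each true effect
at θ + s_i + u_ij with τ = (τ/θ)·θ.  Per effect, group sizes are
3 + Poisson(mean_n − 3); the control mean is fixed at μ₂ = 10 with
μ₁ = μ₂·e^{true lnRR}; study-level true CVs are cv_level·LogNormal(0, σ²)
per group with σ = 0.1 (low) or 0.75 (high) spread.  Observed group
means and SDs come from their exact normal-theory sampling
distributions — m̄ ~ N(μ, σ²/n) and SD² ~ σ²·χ²_{n−1}/(n−1) — which is
distribution-identical to simulating raw response vectors and roughly an
order of magnitude faster.  Observed means that fall nonpositive
(possible in principle, negligible at default CVs) are redrawn, keeping
the data on the ratio scale.  The multi-effect variant draws
1 + Poisson(λ − 1) effects per study (mean exactly λ = 3, at least one),
and is fitted with the multilevel model; the one-effect-per-study
variant uses the random-effects model.

Missingness is imposed at the *study* level, completely at random:
round(p·K) studies lose both groups' SDs in all their effects.  55% is
treated as a soft upper limit (a warning, not an error), reflecting the
range reported in surveys of ecological meta-analyses.

`run_condition` replicates a condition end to end.  Each replicate seeds
its generator from (master seed, replicate index) only, so conditions
sharing a master seed are paired replicate-by-replicate and all methods
within a replicate see identical data — method contrasts are therefore
free of between-replicate Monte-Carlo noise.  Recorded per method:
bias β̂₀ − θ, an indicator that the 95% CI covers θ, log(τ̂²/τ²) (τ̂²
floored at 1e-12 so boundary fits remain finite), and ICĈₛ − ICC.
Non-converged fits are excluded from all summaries and reported in
`n_converged` — silent exclusion would bias coverage invisibly.  The
reference analysis always runs on the pre-deletion dataset.

### Problem sizes used by the shipped evaluation

The reduced grid in `reduced_condition_grid` crosses τ/θ ∈ {0.01, 1},
mean n ∈ {5, 30} and missingness ∈ {0.15, 0.45} at K = 30 studies with
λ = 3 effects per study and 200 paired replicates per condition, with
low CV spread (σ = 0.1) and ICC = 0.5.  These sizes were chosen so the
whole grid (8 conditions × 200 replicates × 5 model fits) completes in
a few minutes on a single core.

At this replicate budget the Monte-Carlo standard error of a
*per-condition* median bias is roughly 1.25·SE(β̂₀)/√200 ≈ 7·10⁻⁴ to
4·10⁻³ in lnRR units depending on the condition — orders of magnitude
above the ~10⁻⁴ scale of the true residual bias of the estimators.  The
across-condition medians reported by `median_bias_summary` therefore
measure the noise floor of this reduced design more than any systematic
bias; driving the Monte-Carlo error itself below 10⁻⁴ per condition
would need several tens of thousands of replicates per condition.
Consequently, what the grid demonstrates is that every method's bias is
statistically indistinguishable from zero at ~10⁻³ resolution and that
no method departs from the others — not that the bias is exactly zero.

## What the synthetic data do not emulate

Normal within-group responses only (no counts or other skewed raw data,
although the Geary utilities exist precisely because real data are often
overdispersed); missingness is strictly MCAR at the study level (no
informative missingness — the hybrid strategy's φ is motivated by that
scenario but it is not simulated); no correlation between effect sizes
beyond the shared study effect (no phylogeny, no shared-control
sampling covariance: V is always diagonal); no publication bias.
Passing tests on these data show the estimators and models are
implemented correctly and behave as designed under the stated
conditions; they do not certify performance under violations of those
assumptions.

## Known limitations

- No moderators/meta-regression; the fixed part is an intercept only.
- No non-diagonal V and no phylogenetic or other structured random
  effects.
- No multiple imputation; the pooled-CV strategies are single-imputation
  style by construction.
- φ is one scalar; datasets whose missing-SD studies have heterogeneous
  CV regimes would need a richer proportionality model.
- lnRR itself requires ratio-scale data with positive means; inputs
  violating this are rejected rather than transformed.
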