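# metarr — meta-analysis of log response ratios with missing SDs

Ecological and evolutionary meta-analyses overwhelmingly use the log
response ratio, lnRR = ln(m₁/m₂), to compare an experimental group mean
m₁ with a control mean m₂.  Its sampling variance needs both groups'
standard deviations — yet a large share of primary studies never report
them, and the common fallback of dropping those studies ("complete-case"
analysis) shrinks and can bias the evidence base.

`metarr` implements a family of strategies that keep every effect size by
exploiting a simple empirical fact: the coefficient of variation
CV = sd/m is far more stable across studies than the SD itself.  A
sample-size-weighted average CV, estimated from the studies that do
report SDs, stands in for the unknown CVs.  The package provides:

- **Effect sizes** — bias-corrected lnRR point estimates and first/second
  order sampling variances from own or pooled CVs, with
  v = CV₁²/n₁ + CV₂²/n₂ + CV₁⁴/(2n₁²) + CV₂⁴/(2n₂²) in the second-order
  form, plus the improved Geary screen
  (1/CV)·4n^{3/2}/(1+4n) ≥ 3 for the normality assumption behind these
  Taylor expansions.
- **Five strategies** for a dataset with missing SDs: *reference* (no
  missing data), *complete-case*, *missing-cases* (pooled-CV variance ṽ
  only where SDs are missing), *all-cases* (ṽ everywhere), and the
  weighted-regression-style *multiplicative* (V = φ·ṽ, φ estimated) and
  *hybrid* (φ·ṽ only on missing entries) strategies.
- **Models** — random-effects and multilevel REML,
  y_ij = β₀ + s_i + u_ij + m_ij with s_i ~ N(0, σ²ₛ), u_ij ~ N(0, σ²ᵤ),
  m_ij ~ N(0, V), V diagonal with known and/or φ-scaled entries;
  Wald z/t intervals for β₀; heterogeneity summaries τ² = σ²ₛ + σ²ᵤ,
  I² = τ²/(τ² + v̄) with the Higgins–Thompson typical sampling variance
  v̄, and the study-level ICCₛ = σ²ₛ/τ².
- **A simulation harness** that generates realistic synthetic
  meta-analytic datasets (small group sizes, lognormal between-study CV
  spread, study-level missingness imposed completely at random) and
  scores each strategy's bias, CI coverage, heterogeneity bias and ICC
  bias over replicated condition grids.

Everything is exposed both as scikit-learn style estimators
(`MissingSDTransformer`, `REMLModel`, `LnRRMetaAnalysis`) and as plain
functions (`apply_strategy`, `reml_fit`, …), plus a `metarr` command-line
tool.

## Worked example

```bash
metarr fixtures --out demo           # writes two small example datasets
metarr analyze --data demo/toy_20pct_missing.csv --out demo/out
```

prints (10 synthetic studies, 35 effect sizes, 20% of studies missing
SDs):

```
lnRR meta-analysis: tandem missing-SD report
==============================================
effects: 35   studies: 10
missing SDs: 20% of effect sizes
effects failing the improved Geary screen: 0

         method      beta0         SE     CI low    CI high       tau2       I2    ICC_s
  missing-cases   0.392775   0.101313   0.194204   0.591345   0.125244   0.8523   0.6449
      all-cases   0.382759   0.103583    0.17974   0.585777   0.127802   0.8441   0.6734

Methods agree qualitatively; the all-cases result can be presented with the comparison as support.
```

`beta0` is the overall mean lnRR (here: the experimental response is
e^0.38 ≈ 1.47 times the control), `tau2` the total heterogeneity beyond
sampling error, `I2` its share of the total variance, and `ICC_s` the
fraction of heterogeneity sitting between studies.  The report runs the
missing-cases and all-cases strategies in tandem and flags sign or
significance disagreement; agreement here means the pooled-CV
approximation is not driving the conclusion.  The same analysis is
available programmatically:

```python
from metarr import LnRRMetaAnalysis, load_frame
est = LnRRMetaAnalysis(strategy="all-cases").fit(load_frame("demo/toy_20pct_missing.csv"))
est.beta0_, est.ci_, est.tau2_, est.icc_s_
```

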