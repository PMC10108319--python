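"""Synthetic meta-analytic datasets and the estimator-evaluation harness.

The generator emulates the kind of data ecological meta-analyses see:
K studies, each contributing one or several effect sizes; true effects
scattered around an overall mean theta by study-level and effect-level
normal deviations (total heterogeneity tau2 split by an intra-class
correlation); small within-group sample sizes; and between-study
variation in the coefficient of variation of the raw response.  Group
summaries (observed mean, SD, n) are drawn from the exact sampling
distributions of normal data — mean ~ N(mu, sigma^2/n) and
SD^2 ~ sigma^2 chi2_{n-1}/(n-1) — which is equivalent in distribution to
simulating raw response vectors but much faster.

Missing SDs are imposed completely at random at the *study* level: a
randomly chosen fraction of studies loses both groups' SDs in every one
of their effects, mirroring how articles omit variance reporting.

`run_condition` evaluates the missing-SD strategies on replicated
datasets from one condition: bias of the overall mean, 95% CI coverage,
log-ratio bias of total heterogeneity and bias of the study-level ICC,
with the no-missing reference model always fitted to the pre-deletion
data.  Within a replicate every method sees identical data (a paired
design), so method contrasts are free of between-replicate noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, MetarrError
from .model import ModelSpec, REMLModel
from .strategies import StrategyName, apply_strategy

__all__ = [
    "SimulationConfig",
    "PerformanceSummary",
    "simulate_dataset",
    "impose_missingness",
    "run_condition",
    "summarize_grid",
    "evaluate_grid",
    "median_bias_summary",
    "reduced_condition_grid",
    "DEFAULT_METHODS",
]

#: The four missing-SD strategies evaluated against the reference.
DEFAULT_METHODS = ("missing-cases", "all-cases", "multiplicative", "hybrid")

#: Missingness beyond this fraction of studies is outside the range the
#: generator is meant to emulate; a warning (not an error) is raised.
MISSINGNESS_SOFT_LIMIT = 0.55

#: Floor applied to estimated tau2 inside the log-ratio heterogeneity bias.
_TAU2_FLOOR = 1e-12


@dataclass
class SimulationConfig:
    """One cell of the simulation grid.

    theta : true overall mean lnRR.
    tau_over_theta : heterogeneity ratio tau/theta; tau2 = (ratio*theta)^2.
    icc_true : share of tau2 sitting at the study level.
    k_studies : number of studies K.
    effects_per_study : "poisson" (several effects per study, Set I) or
        "one" (a single effect per study, Set II).
    lambda_effects : mean effects per study for "poisson" (drawn as
        1 + Poisson(lambda - 1), so every study has at least one effect
        and the mean is exactly lambda).
    mean_n : mean within-group sample size; n ~ 3 + Poisson(mean_n - 3)
        per group, guaranteeing n >= 3.
    mu2 : fixed control-group mean (ratio scale).
    cv_level : typical CV of the raw response.
    cv_heterogeneity : sigma of the multiplicative lognormal spread of
        study-level true CVs around cv_level (0.1 = low, 0.75 = high).
    missingness : fraction of studies whose SDs are deleted.
    seed : master seed for the replicate substreams.
    """

    theta: float = 0.3
    tau_over_theta: float = 1.0
    icc_true: float = 0.5
    k_studies: int = 30
    effects_per_study: str = "poisson"
    lambda_effects: float = 3.0
    mean_n: float = 5.0
    mu2: float = 10.0
    cv_level: float = 0.3
    cv_heterogeneity: float = 0.1
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.theta == 0 and self.tau_over_theta > 0:
            raise ConfigError("tau/theta is undefined for theta = 0")
        if self.tau_over_theta < 0:
            raise ConfigError("tau_over_theta must be >= 0")
        if not (0.0 <= self.icc_true <= 1.0):
            raise ConfigError("icc_true must lie in [0, 1]")
        if self.k_studies < 1:
            raise ConfigError("k_studies must be >= 1")
        if self.effects_per_study not in ("poisson", "one"):
            raise ConfigError(
                f"effects_per_study must be 'poisson' or 'one' "
                f"(got {self.effects_per_study!r})"
            )
        if self.effects_per_study == "poisson" and self.lambda_effects < 1:
            raise ConfigError("lambda_effects must be >= 1")
        if self.mean_n < 3:
            raise ConfigError("mean_n must be >= 3")
        if self.mu2 <= 0:
            raise ConfigError("mu2 must be > 0 (ratio-scale data)")
        if self.cv_level <= 0:
            raise ConfigError("cv_level must be > 0")
        if self.cv_heterogeneity < 0:
            raise ConfigError("cv_heterogeneity must be >= 0")
        if not (0.0 <= self.missingness <= 1.0):
            raise ConfigError("missingness must lie in [0, 1]")
        if self.missingness > MISSINGNESS_SOFT_LIMIT:
            warnings.warn(
                f"missingness {self.missingness} exceeds the "
                f"{MISSINGNESS_SOFT_LIMIT:.0%} range the generator emulates",
                stacklevel=2,
            )

    @property
    def tau2(self) -> float:
        return (self.tau_over_theta * self.theta) ** 2

    @property
    def levels(self) -> str:
        """Matching model: multilevel for Set I, random-effects for Set II."""
        return "ml" if self.effects_per_study == "poisson" else "re"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PerformanceSummary:
    """Replicate-aggregated performance of one method in one condition."""

    method: str
    median_bias_beta0: float
    range_bias_beta0: float
    coverage95: float
    bias_log_tau2: float
    bias_icc: float
    n_replicates: int
    n_converged: int


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one SD-complete meta-analytic dataset.

    Returns a DataFrame in the standard raw-summary schema plus
    diagnostic columns ``true_lnrr, true_cv1, true_cv2`` holding the
    per-effect true parameters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    k = config.k_studies
    if config.effects_per_study == "one":
        n_effects_per_study = np.ones(k, dtype=int)
    else:
        n_effects_per_study = 1 + rng.poisson(config.lambda_effects - 1.0, size=k)
    study_idx = np.repeat(np.arange(k), n_effects_per_study)
    n_total = int(n_effects_per_study.sum())

    tau2 = config.tau2
    s_i = rng.normal(0.0, math.sqrt(config.icc_true * tau2), size=k)
    u_ij = rng.normal(0.0, math.sqrt((1.0 - config.icc_true) * tau2),
                      size=n_total)
    true_lnrr = config.theta + s_i[study_idx] + u_ij

    # study-level true CVs, multiplicative lognormal spread per group
    sig = config.cv_heterogeneity
    cv1_study = config.cv_level * np.exp(rng.normal(0.0, sig, size=k))
    cv2_study = config.cv_level * np.exp(rng.normal(0.0, sig, size=k))
    cv1 = cv1_study[study_idx]
    cv2 = cv2_study[study_idx]

    n1 = 3 + rng.poisson(config.mean_n - 3.0, size=n_total)
    n2 = 3 + rng.poisson(config.mean_n - 3.0, size=n_total)

    mu2 = np.full(n_total, config.mu2)
    mu1 = config.mu2 * np.exp(true_lnrr)

    m1, sd1 = _observe_group(rng, mu1, cv1 * mu1, n1)
    m2, sd2 = _observe_group(rng, mu2, cv2 * mu2, n2)

    return pd.DataFrame({
        "study_id": np.char.add("S", (study_idx + 1).astype(str)),
        "effect_id": np.char.add("E", (np.arange(n_total) + 1).astype(str)),
        "m1": m1, "sd1": sd1, "n1": n1,
        "m2": m2, "sd2": sd2, "n2": n2,
        "true_lnrr": true_lnrr, "true_cv1": cv1, "true_cv2": cv2,
    })


def _observe_group(rng, mu, sigma, n):
    """Observed sample mean and SD of n normal draws with the given true
    moments, via their exact sampling distributions.  Nonpositive means
    are redrawn (the response is ratio-scale, so negative group means are
    outside the model's support)."""
    mean = rng.normal(mu, sigma / np.sqrt(n))
    for _ in range(1000):
        bad = mean <= 0
        if not bad.any():
            break
        mean[bad] = rng.normal(mu[bad], sigma[bad] / np.sqrt(n[bad]))
    else:  # pragma: no cover - pathological configuration
        raise ConfigError("could not draw positive group means; CV too large")
    sd = sigma * np.sqrt(rng.chisquare(n - 1) / (n - 1))
    return mean, sd


def impose_missingness(data: pd.DataFrame, proportion: float,
                       rng: np.random.Generator | int | None = None
                       ) -> pd.DataFrame:
    """Delete both groups' SDs for a random fraction of *studies*.

    round(proportion * K) studies are sampled without replacement and all
    of their effects lose sd1 and sd2 (study-level MCAR); no study is
    ever partially deleted.
    """
    if proportion < 0:
        raise ConfigError("missingness proportion must be >= 0")
    if proportion > MISSINGNESS_SOFT_LIMIT:
        warnings.warn(
            f"missingness {proportion} exceeds the "
            f"{MISSINGNESS_SOFT_LIMIT:.0%} range the generator emulates",
            stacklevel=2,
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = data.copy()
    studies = out["study_id"].unique()
    n_del = int(round(proportion * len(studies)))
    if n_del == 0:
        return out
    chosen = rng.choice(studies, size=n_del, replace=False)
    hit = out["study_id"].isin(chosen)
    out.loc[hit, ["sd1", "sd2"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------


def _model_spec_for(method: str, levels: str, ci_method: str) -> ModelSpec:
    phi = {"multiplicative": "all", "hybrid": "masked"}.get(method, "none")
    return ModelSpec(levels=levels, phi_mode=phi, ci_method=ci_method)


def run_condition(config: SimulationConfig,
                  methods: Sequence[str] = DEFAULT_METHODS,
                  n_replicates: int = 200,
                  ci_method: str = "z",
                  return_replicates: bool = False):
    """Evaluate methods on replicated datasets from one condition.

    Each replicate draws its own substream from ``config.seed`` and the
    replicate index only, so conditions sharing a master seed are paired
    replicate-by-replicate, as are methods within a replicate.  The
    reference model is always fitted to the pre-deletion dataset.

    Returns a list of :class:`PerformanceSummary` (one per method,
    reference first); with ``return_replicates=True`` also the
    per-replicate long-format DataFrame.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    all_methods = ["reference", *methods]
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([config.seed, rep])
        full = simulate_dataset(config, rng)
        missing = impose_missingness(full, config.missingness, rng)
        for method in all_methods:
            data = full if method == "reference" else missing
            try:
                strat = apply_strategy(data, method)
                spec = _model_spec_for(method, config.levels, ci_method)
                # the derivative-free polish refines the optimum at the
                # ~1e-7 level, far below replicate-level Monte-Carlo
                # noise; skip it in the harness for speed
                fit = REMLModel(levels=spec.levels, phi_mode=spec.phi_mode,
                                ci_method=spec.ci_method,
                                polish=False).fit(strat).result_
            except MetarrError:
                rows.append({"replicate": rep, "method": method,
                             "converged": False, "bias": np.nan,
                             "covered": np.nan, "log_tau2_ratio": np.nan,
                             "icc_bias": np.nan})
                continue
            icc_bias = np.nan
            if config.levels == "ml" and fit.icc_s is not None:
                icc_bias = fit.icc_s - config.icc_true
            rows.append({
                "replicate": rep,
                "method": method,
                "converged": True,
                "bias": fit.beta0 - config.theta,
                "covered": float(fit.ci_low <= config.theta <= fit.ci_high),
                "log_tau2_ratio": math.log(
                    max(fit.tau2_total, _TAU2_FLOOR) / max(config.tau2,
                                                           _TAU2_FLOOR)),
                "icc_bias": icc_bias,
            })
    reps = pd.DataFrame(rows)
    summaries = []
    for method in all_methods:
        sub = reps[reps["method"] == method]
        ok = sub[sub["converged"]]
        summaries.append(PerformanceSummary(
            method=method,
            median_bias_beta0=float(np.median(ok["bias"])),
            range_bias_beta0=float(ok["bias"].max() - ok["bias"].min()),
            coverage95=float(ok["covered"].mean()),
            bias_log_tau2=float(np.median(ok["log_tau2_ratio"])),
            bias_icc=float(np.nanmedian(ok["icc_bias"]))
            if np.isfinite(ok["icc_bias"]).any() else float("nan"),
            n_replicates=n_replicates,
            n_converged=int(len(ok)),
        ))
    if return_replicates:
        return summaries, reps
    return summaries


def summarize_grid(results: Mapping[str, Sequence[PerformanceSummary]]
                   ) -> pd.DataFrame:
    """Tidy long-format table of grid results.

    ``results`` maps a condition label to its per-method summaries; the
    output has one row per (condition, method, metric).
    """
    metrics = ("median_bias_beta0", "range_bias_beta0", "coverage95",
               "bias_log_tau2", "bias_icc", "n_replicates", "n_converged")
    rows = []
    for condition, summaries in results.items():
        for s in summaries:
            for metric in metrics:
                rows.append({"condition": condition, "method": s.method,
                             "metric": metric,
                             "value": getattr(s, metric)})
    return pd.DataFrame(rows, columns=["condition", "method", "metric",
                                       "value"])


def evaluate_grid(grid: Mapping[str, SimulationConfig],
                  methods: Sequence[str] = DEFAULT_METHODS,
                  n_replicates: int = 200,
                  ) -> dict[str, list[PerformanceSummary]]:
    """Run :func:`run_condition` over a labelled condition grid."""
    return {label: run_condition(cfg, methods=methods,
                                 n_replicates=n_replicates)
            for label, cfg in grid.items()}


def median_bias_summary(results: Mapping[str, Sequence[PerformanceSummary]]
                        ) -> pd.DataFrame:
    """Across-condition summary of the per-condition median bias of the
    overall mean, per method.

    Columns: ``median_bias`` — the median over conditions of the signed
    per-condition medians (the headline across-condition bias figure);
    ``median_abs_bias`` — the median over conditions of their absolute
    values; ``max_abs_bias`` — the worst condition.
    """
    rows = {}
    for summaries in results.values():
        for s in summaries:
            rows.setdefault(s.method, []).append(s.median_bias_beta0)
    out = pd.DataFrame({
        "method": list(rows),
        "median_bias": [float(np.median(b)) for b in rows.values()],
        "median_abs_bias": [float(np.median(np.abs(b))) for b in rows.values()],
        "max_abs_bias": [float(np.max(np.abs(b))) for b in rows.values()],
    }).set_index("method")
    return out


def reduced_condition_grid(seed: int = 0, k_studies: int = 30,
                           missingness: Sequence[float] = (0.15, 0.45),
                           ) -> dict[str, SimulationConfig]:
    """The reduced evaluation grid: theta = 0.3, tau/theta in {0.01, 1},
    mean n in {5, 30}, crossed with the given missingness levels, K
    studies with ~3 effects each (multilevel set).

    All conditions share the master seed, so replicates are paired across
    conditions as well as methods.
    """
    grid = {}
    for tot in (0.01, 1.0):
        for mean_n in (5, 30):
            for miss in missingness:
                label = f"tau_ratio={tot}|mean_n={mean_n}|miss={miss}"
                grid[label] = SimulationConfig(
                    theta=0.3, tau_over_theta=tot, mean_n=float(mean_n),
                    missingness=float(miss), k_studies=k_studies,
                    effects_per_study="poisson", lambda_effects=3.0,
                    seed=seed,
                )
    return grid
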