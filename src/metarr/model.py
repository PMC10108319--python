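"""Random-effects and multilevel meta-analytic models fitted by REML.

The multilevel model for the j-th effect size in the i-th study is

    y_ij = beta0 + s_i + u_ij + m_ij,
    s_i ~ N(0, sigma2_s),  u_ij ~ N(0, sigma2_u),  m_ij ~ N(0, V_ij),

where V_ij is either a known sampling variance v_ij or, for entries
flagged as proportional, phi * v~_ij with a single multiplicative scalar
phi estimated alongside the variance components (the weighted-regression
assumption that the supplied term is only proportional to the true
sampling variance).  The random-effects model drops u_ij (study-level
heterogeneity only).

Because studies are independent, the marginal covariance is block
diagonal with blocks D + sigma2_s * 11', D diagonal.  The restricted
log-likelihood is evaluated with the rank-one Woodbury identity and
grouped sums, so one evaluation costs O(N) regardless of study sizes.
Variance parameters are optimised on the log scale (floored at 1e-10)
from three dispersed starting points, followed by a derivative-free
polish; boundary solutions (zero heterogeneity) are reported as exact
zeros.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import (
    ConvergenceError,
    SingleEffectError,
    SingularityError,
    UndefinedHeterogeneityError,
)
from .strategies import StrategyResult

__all__ = [
    "ModelSpec",
    "FitResult",
    "REMLModel",
    "reml_fit",
    "wald_ci",
    "typical_sampling_variance",
    "i_squared",
    "icc_study",
]

_LOG2PI = math.log(2.0 * math.pi)

#: Variance components this close to the optimisation floor are reported as 0.
_ZERO_SNAP = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration.

    levels : "ml" (study + effect-within-study) or "re" (study only).
    phi_mode : "none" (all variances known), "all" (every diagonal entry
        is phi-scaled), "masked" (phi on the entries the strategy flagged).
    ci_method : "z" (normal quantile) or "t" (Student t, df = k - 1).
    """

    levels: str = "ml"
    phi_mode: str = "none"
    ci_method: str = "z"
    conf_level: float = 0.95

    def __post_init__(self):
        if self.levels not in ("ml", "re"):
            raise ValueError(f"levels must be 'ml' or 're' (got {self.levels!r})")
        if self.phi_mode not in ("none", "all", "masked"):
            raise ValueError(f"unknown phi_mode {self.phi_mode!r}")
        if self.ci_method not in ("z", "t"):
            raise ValueError(f"ci_method must be 'z' or 't' (got {self.ci_method!r})")
        if not (0.0 < self.conf_level < 1.0):
            raise ValueError("conf_level must be in (0, 1)")


@dataclass
class FitResult:
    """REML estimates and Wald inference for the overall mean."""

    beta0: float
    se_beta0: float
    ci_low: float
    ci_high: float
    sigma2_s: float
    sigma2_u: float
    phi: float | None
    tau2_total: float
    icc_s: float | None
    i2: float
    i2_study: float
    v_bar: float
    loglik_reml: float
    converged: bool
    n_effects: int
    n_studies: int
    levels: str = "ml"
    phi_mode: str = "none"
    ci_method: str = "z"
    conf_level: float = 0.95
    method: str | None = None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def to_row(self) -> dict:
        """Flat summary row (CSV-friendly)."""
        return {
            "method": self.method,
            "beta0": self.beta0,
            "se": self.se_beta0,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sigma2_s": self.sigma2_s,
            "sigma2_u": self.sigma2_u,
            "phi": self.phi,
            "i2": self.i2,
            "icc_s": self.icc_s,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Heterogeneity summaries
# ---------------------------------------------------------------------------


def typical_sampling_variance(vs: Sequence[float]) -> float:
    """Higgins–Thompson 'typical' within-study sampling variance,

        v_bar = (k - 1) * sum(w) / ((sum(w))^2 - sum(w^2)),  w = 1/v.

    Equals v when all sampling variances are equal; homogeneous of
    degree 1 in the variances.
    """
    v = np.asarray(list(vs), dtype=float)
    if v.size < 2:
        raise SingleEffectError("typical sampling variance needs >= 2 effects")
    if (v <= 0).any():
        raise SingularityError("sampling variances must be > 0")
    w = 1.0 / v
    scale = w.mean()
    w = w / scale  # scale invariance guards overflow
    sw = w.sum()
    # (sum w)^2 - sum w^2 = 2 * sum_{i<j} w_i w_j; the subtraction cancels
    # catastrophically when one weight dominates, so accumulate the
    # pairwise products from the small weights upward instead
    ws = np.sort(w)
    prefix = np.cumsum(ws)
    denom = 2.0 * float(np.dot(ws[1:], prefix[:-1]))
    return float((v.size - 1) * sw / denom / scale)


def i_squared(tau2_total: float, v_bar: float) -> float:
    """Heterogeneity share I^2 = tau2 / (tau2 + v_bar)."""
    if tau2_total < 0 or v_bar < 0:
        raise ValueError("inputs must be nonnegative")
    if tau2_total == 0 and v_bar == 0:
        raise UndefinedHeterogeneityError("both tau2 and v_bar are zero")
    return tau2_total / (tau2_total + v_bar)


def icc_study(sigma2_s: float, sigma2_u: float) -> float:
    """Intra-class correlation at the study level, sigma2_s / tau2."""
    if sigma2_s < 0 or sigma2_u < 0:
        raise ValueError("variance components must be nonnegative")
    if sigma2_s == 0 and sigma2_u == 0:
        raise UndefinedHeterogeneityError("total heterogeneity is zero")
    return sigma2_s / (sigma2_s + sigma2_u)


def wald_ci(fit: FitResult, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for the overall mean at the given level."""
    if not fit.converged:
        raise ConvergenceError("cannot form a CI from a non-converged fit")
    q = _quantile(fit.ci_method, level, fit.n_effects)
    return fit.beta0 - q * fit.se_beta0, fit.beta0 + q * fit.se_beta0


def _quantile(ci_method: str, level: float, k: int) -> float:
    a = 0.5 + level / 2.0
    if ci_method == "t":
        return float(stats.t.ppf(a, df=max(k - 1, 1)))
    return float(stats.norm.ppf(a))


# ---------------------------------------------------------------------------
# Restricted log-likelihood (study-block Woodbury, O(N) per evaluation)
# ---------------------------------------------------------------------------


def _profile_stats(sigma2_s, d, y, codes, k_studies):
    """Grouped-sum pieces of the GLS profile at fixed variance parameters.

    Returns (logdet, A, B, C): log|Sigma|, 1'Sigma^-1 1, 1'Sigma^-1 y and
    y'Sigma^-1 y summed over study blocks diag(d) + sigma2_s J.
    """
    inv_d = 1.0 / d
    s1 = np.bincount(codes, weights=inv_d, minlength=k_studies)
    sy = np.bincount(codes, weights=y * inv_d, minlength=k_studies)
    syy = float(np.dot(y * y, inv_d))
    t = 1.0 + sigma2_s * s1
    c = sigma2_s / t
    logdet = float(np.sum(np.log(d))) + float(np.sum(np.log(t)))
    a = float(np.sum(s1 - c * s1 * s1))
    b = float(np.sum(sy - c * s1 * sy))
    cc = syy - float(np.sum(c * sy * sy))
    return logdet, a, b, cc


def restricted_loglik(y, v, codes, k_studies, sigma2_s, sigma2_u=0.0,
                      phi=1.0, phi_mask=None) -> float:
    """Restricted log-likelihood of the (multilevel) meta-analytic model.

    ``v`` holds the supplied diagonal terms; entries where ``phi_mask``
    is true are multiplied by ``phi``.  Includes the full constant of the
    standard REML likelihood, loglik = -1/2 [(N-1) log 2pi - log(N)
    + log|Sigma| + log(1'Sigma^-1 1) + r'Sigma^-1 r] (the log N term is
    log|X'X| for the intercept-only design), so values are directly
    comparable with mainstream meta-analysis software.
    """
    d = v if phi_mask is None else np.where(phi_mask, phi * v, v)
    d = d + sigma2_u
    if (d <= 0).any() or not np.isfinite(d).all():
        return -np.inf
    logdet, a, b, cc = _profile_stats(sigma2_s, d, y, codes, k_studies)
    if a <= 0:
        return -np.inf
    quad = cc - b * b / a
    n = y.size
    return -0.5 * ((n - 1) * _LOG2PI - math.log(n) + logdet + math.log(a) + quad)


class REMLModel(BaseEstimator):
    """Scikit-learn style estimator for the REML meta-analytic model.

    Accepts a :class:`~metarr.strategies.StrategyResult` or a DataFrame
    with columns ``yi, vi, study_id`` (and ``phi_scaled`` for the masked
    phi mode).  Fitted attributes carry a trailing underscore; the full
    set is bundled in ``result_`` (:class:`FitResult`).

    Parameters mirror :class:`ModelSpec`; ``n_starts`` dispersed starting
    points guard against local optima and boundary solutions, and
    ``var_floor`` is the lower bound applied to variance parameters on
    the log scale.
    """

    def __init__(self, levels: str = "ml", phi_mode: str = "none",
                 ci_method: str = "z", conf_level: float = 0.95,
                 n_starts: int = 3, var_floor: float = 1e-10,
                 polish: bool = True, fix_sigma2_s: float | None = None,
                 fix_sigma2_u: float | None = None):
        self.levels = levels
        self.phi_mode = phi_mode
        self.ci_method = ci_method
        self.conf_level = conf_level
        self.n_starts = n_starts
        self.var_floor = var_floor
        self.polish = polish
        self.fix_sigma2_s = fix_sigma2_s
        self.fix_sigma2_u = fix_sigma2_u

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        spec = ModelSpec(self.levels, self.phi_mode, self.ci_method,
                         self.conf_level)
        yv, vv, codes, k_studies, mask, method = _coerce_model_input(X)
        if yv.size < 2:
            raise SingleEffectError("REML fitting needs at least 2 effects")
        if (vv <= 0).any():
            raise SingularityError("all diagonal variance terms must be > 0")

        phi_mode = spec.phi_mode
        if phi_mode == "masked":
            if mask is None:
                raise ValueError("phi_mode='masked' needs a phi_scaled mask")
            if not mask.any():
                phi_mode = "none"  # nothing to scale: phi drops out
            elif mask.all():
                phi_mode = "all"
        use_phi = phi_mode != "none"
        phi_mask = None
        if phi_mode == "all":
            phi_mask = np.ones(yv.size, dtype=bool)
        elif phi_mode == "masked":
            phi_mask = mask
        ml = spec.levels == "ml"
        lo = math.log(self.var_floor)

        # free parameters, in order, on the log scale
        free: list[str] = []
        if self.fix_sigma2_s is None:
            free.append("s2s")
        if ml and self.fix_sigma2_u is None:
            free.append("s2u")
        if use_phi:
            free.append("phi")
        if not free:
            raise ValueError("no free parameters to estimate")

        blo = np.array([math.log(1e-8) if name == "phi" else lo
                        for name in free])
        bhi = np.array([math.log(1e8) if name == "phi" else math.log(1e4)
                        for name in free])

        def unpack(params):
            vals = dict(zip(free, np.exp(np.clip(params, blo, bhi))))
            s2s = vals.get("s2s", self.fix_sigma2_s or 0.0)
            s2u = vals.get("s2u", (self.fix_sigma2_u or 0.0) if ml else 0.0)
            phi = vals.get("phi", 1.0)
            return s2s, s2u, phi

        def neg2(params):
            s2s, s2u, phi = unpack(params)
            ll = restricted_loglik(yv, vv, codes, k_studies, s2s, s2u, phi,
                                   phi_mask)
            return np.inf if ll == -np.inf else -2.0 * ll

        starts = _dispersed_starts(yv, vv, free, self.n_starts,
                                   self.var_floor)
        bounds = list(zip(blo, bhi))

        best = None
        any_success = False
        for x0 in starts:
            res = optimize.minimize(
                neg2, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("REML optimisation failed from every start",
                                   {"starts": len(starts)})
        if self.polish:
            res = optimize.minimize(
                neg2, np.clip(best.x, [b[0] for b in bounds],
                              [b[1] for b in bounds]),
                method="Nelder-Mead",
                options={"fatol": 1e-12, "xatol": 1e-9, "maxfev": 400},
            )
            if np.isfinite(res.fun) and res.fun <= best.fun:
                best = res
                any_success = True
        if not any_success and not np.isfinite(best.fun):
            raise ConvergenceError("REML optimisation did not converge",
                                   {"fun": float(best.fun)})

        s2s, s2u, phi = unpack(np.clip(best.x, math.log(1e-300), None))
        d = vv if phi_mask is None else np.where(phi_mask, phi * vv, vv)
        d = d + s2u
        logdet, a, b, cc = _profile_stats(s2s, d, yv, codes, k_studies)
        beta0 = b / a
        se = math.sqrt(1.0 / a)
        ll = -0.5 * ((yv.size - 1) * _LOG2PI - math.log(yv.size)
                     + logdet + math.log(a) + (cc - b * b / a))

        # report boundary solutions as exact zeros
        s2s_r = 0.0 if s2s <= _ZERO_SNAP else s2s
        s2u_r = 0.0 if (not ml or s2u <= _ZERO_SNAP) else s2u
        tau2 = s2s_r + s2u_r
        effective_v = vv if phi_mask is None else np.where(phi_mask, phi * vv, vv)
        v_bar = typical_sampling_variance(effective_v)
        q = _quantile(spec.ci_method, spec.conf_level, yv.size)

        self.result_ = FitResult(
            beta0=float(beta0),
            se_beta0=float(se),
            ci_low=float(beta0 - q * se),
            ci_high=float(beta0 + q * se),
            sigma2_s=float(s2s_r),
            sigma2_u=float(s2u_r),
            phi=float(phi) if use_phi else None,
            tau2_total=float(tau2),
            icc_s=(None if tau2 == 0 else float(s2s_r / tau2)),
            i2=float(tau2 / (tau2 + v_bar)),
            i2_study=float(s2s_r / (tau2 + v_bar)),
            v_bar=float(v_bar),
            loglik_reml=float(ll),
            converged=True,
            n_effects=int(yv.size),
            n_studies=int(k_studies),
            levels=spec.levels,
            phi_mode=spec.phi_mode,
            ci_method=spec.ci_method,
            conf_level=spec.conf_level,
            method=method,
        )
        # fitted attributes, sklearn style
        self.beta0_ = self.result_.beta0
        self.se_ = self.result_.se_beta0
        self.sigma2_s_ = self.result_.sigma2_s
        self.sigma2_u_ = self.result_.sigma2_u
        self.phi_ = self.result_.phi
        self.tau2_ = self.result_.tau2_total
        self.i2_ = self.result_.i2
        self.icc_s_ = self.result_.icc_s
        self.loglik_ = self.result_.loglik_reml
        return self

    def predict(self, X=None):
        """Predicted marginal mean (the overall effect) for each row of X
        (or a scalar when X is None)."""
        if X is None:
            return self.beta0_
        n = len(X)
        return np.full(n, self.beta0_)


def _coerce_model_input(X):
    """Accept StrategyResult or DataFrame; return (y, v, codes, K, mask,
    method-name)."""
    method = None
    if isinstance(X, StrategyResult):
        method = X.strategy
        df = X.table
    elif isinstance(X, pd.DataFrame):
        df = X
    else:
        raise TypeError("X must be a StrategyResult or DataFrame")
    y = df["yi"].to_numpy(float)
    v = df["vi"].to_numpy(float)
    codes, uniques = pd.factorize(df["study_id"].to_numpy())
    mask = df["phi_scaled"].to_numpy(bool) if "phi_scaled" in df else None
    return y, v, np.asarray(codes), len(uniques), mask, method


def _dispersed_starts(y, v, free, n_starts, floor):
    """Moment-based start plus dispersed variants on the log scale."""
    vary = float(np.var(y, ddof=1)) if y.size > 1 else 1e-3
    vary = max(vary, 1e-8)
    tau0 = max(vary - float(np.mean(v)), 0.05 * vary, floor * 10)
    n_var = sum(1 for name in free if name != "phi")
    base = []
    for name in free:
        base.append(1.0 if name == "phi" else tau0 / max(n_var, 1))
    base = np.log(np.asarray(base))
    var_slots = np.array([name != "phi" for name in free])
    starts = [base]
    scales = [2.5, -2.5, 5.0, -5.0]
    for i in range(max(0, n_starts - 1)):
        s = base.copy()
        s[var_slots] += scales[i % len(scales)]
        # the phi slot (if any) is dispersed in the opposite direction so
        # the starts also probe variance/phi trade-off basins
        s[~var_slots] -= scales[i % len(scales)]
        starts.append(s)
    return [np.clip(s, math.log(floor), None) for s in starts]


def reml_fit(result, spec: ModelSpec | None = None, **kwargs) -> FitResult:
    """Functional wrapper over :class:`REMLModel`.

    ``result`` is a StrategyResult (or a yi/vi/study_id frame); ``spec``
    a :class:`ModelSpec` (keyword overrides allowed).
    """
    if spec is None:
        spec = ModelSpec(**kwargs)
    model = REMLModel(levels=spec.levels, phi_mode=spec.phi_mode,
                      ci_method=spec.ci_method, conf_level=spec.conf_level)
    return model.fit(result).result_
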