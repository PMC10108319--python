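"""REML model: closed forms, an independent metafor cross-check,
invariances and the heterogeneity summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from metarr import (
    ModelSpec,
    REMLModel,
    i_squared,
    icc_study,
    reml_fit,
    typical_sampling_variance,
    wald_ci,
)
from metarr.exceptions import (
    SingleEffectError,
    SingularityError,
    UndefinedHeterogeneityError,
)

# Reference values for the yv_frame fixture computed independently with
# metafor 4.8-0: rma.mv(yi, vi, random = ~1|study/effect, method="REML")
# and rma(yi, vi, method="REML").
METAFOR_ML = dict(beta0=0.2080372193, se=0.0660673864,
                  sigma2_s=0.0023304425, sigma2_u=0.0193436349,
                  loglik=1.1770261894)
METAFOR_RE = dict(beta0=0.2062991878, se=0.0635062578,
                  tau2=0.0211232670, loglik=1.1696111347)


def test_multilevel_fit_matches_metafor(yv_frame):
    f = reml_fit(yv_frame, levels="ml")
    assert f.beta0 == pytest.approx(METAFOR_ML["beta0"], abs=1e-6)
    assert f.se_beta0 == pytest.approx(METAFOR_ML["se"], abs=1e-6)
    assert f.sigma2_s == pytest.approx(METAFOR_ML["sigma2_s"], abs=1e-6)
    assert f.sigma2_u == pytest.approx(METAFOR_ML["sigma2_u"], abs=1e-6)
    assert f.loglik_reml == pytest.approx(METAFOR_ML["loglik"], abs=1e-6)
    assert f.tau2_total == pytest.approx(f.sigma2_s + f.sigma2_u)
    assert f.icc_s == pytest.approx(f.sigma2_s / f.tau2_total)


def test_random_effects_fit_matches_metafor(yv_frame):
    df = yv_frame.assign(study_id=np.arange(len(yv_frame)))
    f = reml_fit(df, levels="re")
    assert f.beta0 == pytest.approx(METAFOR_RE["beta0"], abs=1e-6)
    assert f.se_beta0 == pytest.approx(METAFOR_RE["se"], abs=1e-6)
    assert f.sigma2_s == pytest.approx(METAFOR_RE["tau2"], abs=1e-6)
    assert f.loglik_reml == pytest.approx(METAFOR_RE["loglik"], abs=1e-6)
    assert f.sigma2_u == 0.0


def test_equal_variance_closed_form():
    """For the RE model with equal known variances, beta0 is the plain
    mean and tau2 = max(0, s^2 - v) exactly."""
    y = [0.1, 0.2, 0.3]
    s2 = np.var(y, ddof=1)  # 0.01
    for v in (0.005, 0.01, 0.02):
        df = pd.DataFrame({"yi": y, "vi": v, "study_id": range(3)})
        f = reml_fit(df, levels="re")
        assert f.beta0 == pytest.approx(0.2, abs=1e-8)
        assert f.sigma2_s == pytest.approx(max(0.0, s2 - v), abs=1e-6)
        assert f.se_beta0 == pytest.approx(
            math.sqrt((v + max(0.0, s2 - v)) / 3), rel=1e-4)


def test_phi_closed_form_with_fixed_variances():
    """With every diagonal term equal to 1 and the random variances fixed
    at 0, the REML estimate of phi is the sample variance of y (the
    weighted-regression residual-variance oracle)."""
    y = np.array([0.1, 0.5, 0.3, 0.9, -0.2])
    df = pd.DataFrame({"yi": y, "vi": 1.0, "study_id": range(5),
                       "phi_scaled": True})
    m = REMLModel(levels="re", phi_mode="all", fix_sigma2_s=0.0).fit(df)
    assert m.phi_ == pytest.approx(np.var(y, ddof=1), rel=1e-5)


def test_phi_scale_equivariance(yv_frame):
    """Multiplying all proportional variance terms by c divides phi by c
    and leaves beta0, SE, variance components and loglik unchanged."""
    df = yv_frame.assign(phi_scaled=True)
    f1 = reml_fit(df, levels="ml", phi_mode="all")
    c = 7.3
    f2 = reml_fit(df.assign(vi=df["vi"] * c), levels="ml", phi_mode="all")
    assert f2.phi == pytest.approx(f1.phi / c, rel=1e-4)
    assert f2.beta0 == pytest.approx(f1.beta0, abs=1e-6)
    assert f2.se_beta0 == pytest.approx(f1.se_beta0, rel=1e-4)
    assert f2.sigma2_s == pytest.approx(f1.sigma2_s, abs=1e-6)
    assert f2.sigma2_u == pytest.approx(f1.sigma2_u, abs=1e-6)
    assert f2.loglik_reml == pytest.approx(f1.loglik_reml, abs=1e-5)


def test_gls_consistency_of_beta0(yv_frame):
    """At the converged variance parameters, beta0 equals the precision
    weighted mean under the implied marginal covariance."""
    f = reml_fit(yv_frame, levels="ml")
    codes, _ = pd.factorize(yv_frame["study_id"])
    n = len(yv_frame)
    z = np.zeros((n, codes.max() + 1))
    z[np.arange(n), codes] = 1.0
    sigma = (f.sigma2_s * z @ z.T + f.sigma2_u * np.eye(n)
             + np.diag(yv_frame["vi"]))
    w = np.linalg.solve(sigma, np.ones(n))
    beta_gls = w @ yv_frame["yi"].to_numpy() / w.sum()
    assert f.beta0 == pytest.approx(beta_gls, abs=1e-8)
    assert f.se_beta0 == pytest.approx(1.0 / math.sqrt(w.sum()), rel=1e-8)


def test_masked_phi_degenerate_masks(yv_frame):
    """An all-false mask makes phi drop out; an all-true mask behaves as
    phi_mode='all'."""
    none_mask = yv_frame.assign(phi_scaled=False)
    f0 = reml_fit(none_mask, levels="ml", phi_mode="masked")
    f_plain = reml_fit(yv_frame, levels="ml")
    assert f0.phi is None
    assert f0.beta0 == pytest.approx(f_plain.beta0, abs=1e-8)
    all_mask = yv_frame.assign(phi_scaled=True)
    fa = reml_fit(all_mask, levels="ml", phi_mode="masked")
    fb = reml_fit(all_mask, levels="ml", phi_mode="all")
    assert fa.phi == pytest.approx(fb.phi, rel=1e-5)


def test_wald_ci_quantiles_and_nesting(yv_frame):
    f = reml_fit(yv_frame, levels="ml")
    lo, hi = wald_ci(f, 0.95)
    assert (lo, hi) == pytest.approx(
        (f.beta0 - 1.959964 * f.se_beta0, f.beta0 + 1.959964 * f.se_beta0),
        abs=1e-5)
    lo50, hi50 = wald_ci(f, 0.5)
    assert lo < lo50 < hi50 < hi
    ft = reml_fit(yv_frame, levels="ml", ci_method="t")
    assert ft.ci_high - ft.ci_low > f.ci_high - f.ci_low  # t wider than z


def test_typical_sampling_variance():
    assert typical_sampling_variance([0.02, 0.02, 0.02]) == pytest.approx(0.02)
    # direct evaluation of the Higgins-Thompson form
    v = np.array([0.01, 0.01, 0.04])
    w = 1 / v
    expected = (3 - 1) * w.sum() / (w.sum() ** 2 - (w ** 2).sum())
    assert typical_sampling_variance(v) == pytest.approx(expected)
    assert typical_sampling_variance(v * 3.0) == pytest.approx(expected * 3.0)
    with pytest.raises(SingleEffectError):
        typical_sampling_variance([0.01])


def test_i_squared_and_icc():
    assert i_squared(0.1, 0.1) == pytest.approx(0.5)
    assert i_squared(0.0, 0.1) == 0.0
    assert i_squared(0.1, 0.0) == 1.0
    with pytest.raises(UndefinedHeterogeneityError):
        i_squared(0.0, 0.0)
    assert icc_study(0.09, 0.0) == 1.0
    assert icc_study(0.0, 0.09) == 0.0
    assert icc_study(0.03, 0.06) == pytest.approx(1 / 3)
    with pytest.raises(UndefinedHeterogeneityError):
        icc_study(0.0, 0.0)


def test_parameter_recovery_multilevel(rng):
    """Fits to data simulated from the multilevel model recover the true
    (beta0, sigma2_s, sigma2_u) on average across replicates."""
    beta0, s2s, s2u, v = 0.3, 0.04, 0.02, 0.01
    k, per = 20, 3
    est = np.zeros((500, 3))
    for r in range(500):
        s = rng.normal(0, math.sqrt(s2s), k).repeat(per)
        u = rng.normal(0, math.sqrt(s2u), k * per)
        e = rng.normal(0, math.sqrt(v), k * per)
        df = pd.DataFrame({"yi": beta0 + s + u + e, "vi": v,
                           "study_id": np.arange(k).repeat(per)})
        f = reml_fit(df, levels="ml")
        est[r] = [f.beta0, f.sigma2_s, f.sigma2_u]
    mean = est.mean(axis=0)
    mc3 = 3 * est.std(axis=0, ddof=1) / math.sqrt(500)
    assert abs(mean[0] - beta0) < mc3[0]
    assert abs(mean[1] - s2s) < mc3[1]
    assert abs(mean[2] - s2u) < mc3[2]


def test_invalid_inputs():
    df = pd.DataFrame({"yi": [0.1, 0.2], "vi": [0.01, 0.0],
                       "study_id": [0, 1]})
    with pytest.raises(SingularityError):
        reml_fit(df, levels="re")
    one = pd.DataFrame({"yi": [0.1], "vi": [0.01], "study_id": [0]})
    with pytest.raises(SingleEffectError):
        reml_fit(one, levels="re")
    with pytest.raises(ValueError):
        ModelSpec(levels="bogus")


def test_estimator_is_sklearn_compatible(yv_frame):
    from sklearn.base import clone

    m = REMLModel(levels="ml", ci_method="t")
    m2 = clone(m)
    m2.fit(yv_frame)
    assert m2.get_params()["ci_method"] == "t"
    assert m2.result_.converged
    assert np.allclose(m2.predict(yv_frame), m2.beta0_)
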