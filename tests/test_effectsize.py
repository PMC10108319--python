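"""Unit and property tests for lnRR point estimates, sampling variances,
CV pooling and the improved Geary screen."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metarr import (
    EffectRecord,
    GroupSummary,
    PooledCV,
    cv,
    geary_criterion,
    geary_min_n,
    geary_pass,
    lnrr_corrected,
    lnrr_pooled,
    lnrr_raw,
    n_tilde,
    pooled_cv,
    var_individual_first,
    var_individual_second,
    var_pooled_first,
    var_pooled_second,
)
from metarr.exceptions import (
    DomainError,
    MissingSDError,
    NoCompleteRecordsError,
)

LN2 = math.log(2.0)


def g(mean, sd, n):
    return GroupSummary(mean=mean, sd=sd, n=n)


# ---------------------------------------------------------------------------
# construction / validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mean,sd,n", [(0.0, 1.0, 5), (-2.0, 1.0, 5),
                                       (1.0, -0.1, 5), (1.0, 1.0, 1)])
def test_group_summary_rejects_invalid_fields(mean, sd, n):
    with pytest.raises(DomainError):
        GroupSummary(mean, sd, n)


def test_record_sd_missing_flag_is_either_group():
    assert not EffectRecord("s", "e", g(1, 1, 5), g(1, 1, 5)).sd_missing
    assert EffectRecord("s", "e", g(1, None, 5), g(1, 1, 5)).sd_missing
    assert EffectRecord("s", "e", g(1, 1, 5), g(1, None, 5)).sd_missing


# ---------------------------------------------------------------------------
# coefficient of variation and raw/corrected/pooled points
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mean,sd,expected", [(10, 2, 0.2), (5, 0, 0.0),
                                              (4, 6, 1.5)])
def test_cv_is_sd_over_mean(mean, sd, expected):
    assert cv(g(mean, sd, 5)) == pytest.approx(expected)


def test_cv_missing_sd_raises():
    with pytest.raises(MissingSDError):
        cv(g(10, None, 5))


@pytest.mark.parametrize("m1,m2,expected", [(10, 5, LN2), (7, 7, 0.0)])
def test_lnrr_raw_values(m1, m2, expected):
    assert lnrr_raw(g(m1, 1, 5), g(m2, 1, 5)) == pytest.approx(expected)


def test_lnrr_corrected_examples():
    # equal CVs and equal n: correction cancels
    assert lnrr_corrected(g(10, 2, 10), g(5, 1, 10)) == pytest.approx(LN2)
    # CV1=0.2, CV2=0.4, n=10: ln2 + (0.04/10 - 0.16/10)/2
    assert lnrr_corrected(g(10, 2, 10), g(5, 2, 10)) == pytest.approx(
        LN2 + 0.5 * (0.004 - 0.016))
    # zero SDs reduce to the raw log ratio
    assert lnrr_corrected(g(10, 0, 10), g(5, 0, 10)) == pytest.approx(
        lnrr_raw(g(10, 0, 10), g(5, 0, 10)))


def test_lnrr_corrected_missing_sd_raises():
    with pytest.raises(MissingSDError):
        lnrr_corrected(g(10, None, 10), g(5, 1, 10))


def test_lnrr_pooled_examples():
    p = PooledCV(0.3, 0.3, 2, 2)
    assert lnrr_pooled(g(10, None, 10), g(5, None, 10), p) == pytest.approx(LN2)
    p0 = PooledCV(0.0, 0.0, 1, 1)
    assert lnrr_pooled(g(10, None, 7), g(5, None, 9), p0) == pytest.approx(LN2)
    # crossed indices: cv1_bar^2/n2 - cv2_bar^2/n1
    p2 = PooledCV(0.2, 0.4, 2, 2)
    assert lnrr_pooled(g(10, None, 5), g(5, None, 20), p2) == pytest.approx(
        LN2 + 0.5 * (0.04 / 20 - 0.16 / 5))


# ---------------------------------------------------------------------------
# sampling variances
# ---------------------------------------------------------------------------

def test_individual_variances_worked_values():
    assert var_individual_first(g(10, 2, 10), g(5, 1, 10)) == pytest.approx(0.008)
    assert var_individual_second(g(10, 2, 10), g(5, 1, 10)) == pytest.approx(
        0.008 + 2 * 0.0016 / 200)


def test_pooled_variances_worked_values():
    p = PooledCV(0.3, 0.3, 2, 2)
    assert var_pooled_first(g(9, None, 10), g(7, None, 10), p) == pytest.approx(0.018)
    assert var_pooled_second(g(9, None, 10), g(7, None, 10), p) == pytest.approx(
        0.018 + 2 * 0.0081 / 200)


def test_pooled_second_matches_individual_when_cvs_equal_pool():
    p = PooledCV(0.2, 0.25, 1, 1)
    g1, g2 = g(10, 2.0, 8), g(8, 2.0, 12)
    assert var_pooled_second(g1, g2, p) == pytest.approx(
        var_individual_second(g1, g2))


def test_doubling_n_scales_pooled_variance_parts():
    p = PooledCV(0.3, 0.3, 1, 1)
    first_10 = var_pooled_first(g(9, None, 10), g(7, None, 10), p)
    first_20 = var_pooled_first(g(9, None, 20), g(7, None, 20), p)
    assert first_20 == pytest.approx(first_10 / 2)
    quartic_10 = var_pooled_second(g(9, None, 10), g(7, None, 10), p) - first_10
    quartic_20 = var_pooled_second(g(9, None, 20), g(7, None, 20), p) - first_20
    assert quartic_20 == pytest.approx(quartic_10 / 4)


@given(m1=st.floats(0.1, 100), m2=st.floats(0.1, 100))
def test_lnrr_raw_antisymmetry(m1, m2):
    a, b = g(m1, 1.0, 5), g(m2, 1.0, 5)
    assert lnrr_raw(a, b) == pytest.approx(-lnrr_raw(b, a), abs=1e-12)


@given(n1=st.integers(2, 500), n2=st.integers(2, 500))
def test_unit_cv_variance_reduces_to_inverse_n_tilde(n1, n2):
    """With both CVs equal to 1 the first-order variance is 1/n~ with
    n~ = n1 n2 / (n1 + n2)."""
    v = var_individual_first(g(1.0, 1.0, n1), g(1.0, 1.0, n2))
    assert v == pytest.approx(1.0 / n_tilde(n1, n2), rel=1e-12)


@given(cv1=st.floats(0, 3), cv2=st.floats(0, 3),
       n1=st.integers(2, 100), n2=st.integers(2, 100))
def test_second_order_dominates_first_order(cv1, cv2, n1, n2):
    g1 = g(10.0, 10.0 * cv1, n1)
    g2 = g(8.0, 8.0 * cv2, n2)
    lo = var_individual_first(g1, g2)
    hi = var_individual_second(g1, g2)
    assert hi >= lo
    if cv1 == 0 and cv2 == 0:
        assert hi == lo


# ---------------------------------------------------------------------------
# CV pooling
# ---------------------------------------------------------------------------

def rec(study, effect, n1, cv1, n2=None, cv2=None):
    n2 = n2 if n2 is not None else n1
    cv2 = cv2 if cv2 is not None else cv1
    return EffectRecord(study, effect,
                        g(10.0, 10.0 * cv1, n1), g(10.0, 10.0 * cv2, n2))


def test_pooled_cv_two_single_effect_studies():
    p = pooled_cv([rec("s1", "e1", 10, 0.2), rec("s2", "e2", 30, 0.4)])
    assert p.cv1_bar == pytest.approx(0.35)  # (10*0.2 + 30*0.4) / 40
    assert p.n_studies_used == 2 and p.n_effects_used == 2


def test_pooled_cv_constant_cvs_return_constant():
    p = pooled_cv([rec("s1", "e1", 4, 0.27), rec("s1", "e2", 9, 0.27),
                   rec("s2", "e3", 30, 0.27)])
    assert p.cv1_bar == pytest.approx(0.27)
    assert p.cv2_bar == pytest.approx(0.27)


def test_pooled_cv_two_stage_example():
    # study A: (n=10, CV=0.2), (n=10, CV=0.4) -> within-study mean 0.3, N=20
    # study B: (n=20, CV=0.3) -> 0.3; across: (20*0.3 + 20*0.3)/40 = 0.3
    p = pooled_cv([rec("A", "e1", 10, 0.2), rec("A", "e2", 10, 0.4),
                   rec("B", "e3", 20, 0.3)])
    assert p.cv1_bar == pytest.approx(0.3)


def test_pooled_cv_partial_record_contributes_its_group():
    full = rec("s1", "e1", 10, 0.2)
    partial = EffectRecord("s2", "e2", g(10.0, None, 10), g(10.0, 4.0, 10))
    p = pooled_cv([full, partial])
    assert p.cv1_bar == pytest.approx(0.2)        # only the full record
    assert p.cv2_bar == pytest.approx(0.3)        # (0.2*10 + 0.4*10)/20


def test_pooled_cv_no_complete_records_raises():
    missing = EffectRecord("s", "e", g(10, None, 5), g(10, None, 5))
    with pytest.raises(NoCompleteRecordsError):
        pooled_cv([missing])


# ---------------------------------------------------------------------------
# improved Geary screen
# ---------------------------------------------------------------------------

def test_geary_criterion_threshold_values():
    assert geary_criterion(5, 226) == pytest.approx(3.00334, abs=1e-5)
    assert geary_criterion(5, 225) == pytest.approx(2.99667, abs=1e-5)
    assert geary_criterion(5, 225) < 3 <= geary_criterion(5, 226)
    assert geary_criterion(0.0, 10) == math.inf


@pytest.mark.parametrize("cv_value,expected", [(5.0, 226), (1.0, 10)])
def test_geary_min_n_known_values(cv_value, expected):
    assert geary_min_n(cv_value) == expected


@given(st.floats(math.log(0.01), math.log(10.0)))
@settings(max_examples=60, deadline=None)
def test_geary_min_n_brackets_the_threshold(log_cv):
    c = math.exp(log_cv)
    n = geary_min_n(c)
    assert geary_criterion(c, n) >= 3
    if n > 1:
        assert geary_criterion(c, n - 1) < 3


def test_geary_min_n_monotone_in_cv():
    grid = np.exp(np.linspace(math.log(0.01), math.log(10), 25))
    ns = [geary_min_n(c) for c in grid]
    assert all(b >= a for a, b in zip(ns, ns[1:]))


def test_geary_pass_requires_both_groups():
    ok = EffectRecord("s", "e", g(10, 2, 30), g(10, 2, 30))       # CV=0.2
    bad = EffectRecord("s", "e", g(10, 2, 30), g(10, 50, 30))     # CV=5
    assert geary_pass(ok)
    assert not geary_pass(bad)
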