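"""Log response ratio point estimates, sampling variances and the improved
Geary normality screen.

The log response ratio lnRR = ln(m1/m2) compares the means of two groups on
a ratio scale.  Because the log of a sample mean is a biased estimator of
the log of the population mean, small-sample corrections based on Taylor
expansions of ln(m) around the true mean are applied: a second-order
bias-corrected point estimate and first/second-order sampling variances
expressed through the coefficient of variation CV = sd/m.

When a study does not report SDs its CVs are unknown, but CVs tend to be
far more stable across studies than SDs.  This module therefore also
provides a sample-size-weighted average CV pooled across the SD-complete
records of a dataset, and variance formulas that substitute the pooled CV
for the study-specific one.  Squaring the weighted-average CV (rather than
averaging CV^2) keeps the pooled quantity robust to occasional outlying
CVs from skewed raw data.

All functions are pure and operate on scalars via the small dataclasses
below; the ``_arr``-suffixed helpers are vectorised counterparts used by
the strategy layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .exceptions import (
    DegenerateVarianceError,
    DomainError,
    MissingSDError,
    NoCompleteRecordsError,
)

__all__ = [
    "GroupSummary",
    "EffectRecord",
    "PooledCV",
    "EffectEstimate",
    "cv",
    "lnrr_raw",
    "lnrr_corrected",
    "lnrr_pooled",
    "var_individual_first",
    "var_individual_second",
    "var_pooled_first",
    "var_pooled_second",
    "pooled_cv",
    "n_tilde",
    "geary_criterion",
    "geary_min_n",
    "geary_pass",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one treatment group.

    Parameters
    ----------
    mean : float
        Arithmetic mean of the response; must be strictly positive because
        the response ratio requires ratio-scale data (a true zero).
    sd : float or None
        Sample standard deviation, or ``None`` when the study does not
        report it.  ``0.0`` is a valid observed SD, distinct from missing.
    n : int
        Number of replicates; at least 2.
    """

    mean: float
    sd: float | None
    n: int

    def __post_init__(self) -> None:
        if not (self.mean > 0):
            raise DomainError(
                f"group mean must be > 0 for lnRR (got {self.mean!r}); "
                "response ratios require ratio-scale data"
            )
        if self.sd is not None and self.sd < 0:
            raise DomainError(f"sd must be >= 0 (got {self.sd!r})")
        if int(self.n) != self.n or self.n < 2:
            raise DomainError(f"n must be an integer >= 2 (got {self.n!r})")

    @property
    def sd_missing(self) -> bool:
        return self.sd is None


@dataclass(frozen=True)
class EffectRecord:
    """One effect size's raw summary statistics.

    ``group1`` is conventionally the experimental group and ``group2`` the
    control/baseline.  A record with *either* group SD missing is treated
    as SD-missing as a whole, although its reported group still
    contributes to CV pooling.
    """

    study_id: str
    effect_id: str
    group1: GroupSummary
    group2: GroupSummary

    @property
    def sd_missing(self) -> bool:
        return self.group1.sd_missing or self.group2.sd_missing


@dataclass(frozen=True)
class PooledCV:
    """Sample-size-weighted average CV per group, pooled across the
    SD-reporting records of a dataset (two-stage: within study, then
    across studies)."""

    cv1_bar: float
    cv2_bar: float
    n_studies_used: int
    n_effects_used: int

    def __post_init__(self) -> None:
        if self.cv1_bar < 0 or self.cv2_bar < 0:
            raise DomainError("pooled CVs must be nonnegative")
        if self.n_studies_used < 1:
            raise DomainError("pooled CV requires at least one study")


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate plus sampling variance, tagged with the formulas
    that produced each component."""

    point: float
    variance: float
    estimator_tag: str  # RAW_EQ1 | CORRECTED_EQ4 | POOLED_EQ6
    variance_tag: str  # IND_EQ2 | IND_EQ5 | POOLED_EQ7 | POOLED_EQ15 | PROPORTIONAL


# ---------------------------------------------------------------------------
# Coefficients of variation
# ---------------------------------------------------------------------------


def cv(g: GroupSummary) -> float:
    """Coefficient of variation sd/mean of one group.

    Raises
    ------
    MissingSDError
        If the group's SD is missing.
    """
    if g.sd is None:
        raise MissingSDError("cannot compute CV: sd is missing")
    return g.sd / g.mean


def pooled_cv(records: Iterable[EffectRecord]) -> PooledCV:
    """Two-stage sample-size-weighted average CV per group.

    Within each study the CVs of its SD-reporting records are averaged
    with the group's own sample sizes as weights; the study-level averages
    are then averaged across studies weighted by each study's summed
    group sample size.  With one effect per study this reduces to the
    single-stage weighted mean sum(n_i * CV_i) / sum(n_i).

    A record with only one group's SD reported still contributes that
    group's CV to the pool for that group.

    Raises
    ------
    NoCompleteRecordsError
        If either group has no record reporting an SD.
    """
    recs = list(records)
    if not recs:
        raise NoCompleteRecordsError("no records given")

    bars = []
    for side in ("group1", "group2"):
        # study -> [sum(n*cv), sum(n)]
        acc: dict[str, list[float]] = {}
        for r in recs:
            g: GroupSummary = getattr(r, side)
            if g.sd is None:
                continue
            a = acc.setdefault(r.study_id, [0.0, 0.0])
            a[0] += g.n * (g.sd / g.mean)
            a[1] += g.n
        if not acc:
            raise NoCompleteRecordsError(
                f"every record is missing the SD of {side}; cannot pool CVs"
            )
        num = sum(w * (s / w) for s, w in acc.values())  # = sum of s
        den = sum(w for _, w in acc.values())
        bars.append(num / den)

    contributing = [r for r in recs if not (r.group1.sd_missing and r.group2.sd_missing)]
    return PooledCV(
        cv1_bar=bars[0],
        cv2_bar=bars[1],
        n_studies_used=len({r.study_id for r in contributing}),
        n_effects_used=len(contributing),
    )


# ---------------------------------------------------------------------------
# Point estimates
# ---------------------------------------------------------------------------


def lnrr_raw(g1: GroupSummary, g2: GroupSummary) -> float:
    """First-order (uncorrected) log response ratio ln(m1/m2)."""
    return math.log(g1.mean / g2.mean)


def lnrr_corrected(g1: GroupSummary, g2: GroupSummary) -> float:
    """Small-sample bias-corrected lnRR using the groups' own CVs.

    Adds the second-order Taylor correction term
    ``(CV1^2/n2 - CV2^2/n1) / 2`` to the raw log ratio.  Note the crossed
    sample-size indices, implemented exactly as the correction is printed
    in the source formulation (see docs/methods.md for discussion).
    """
    c1, c2 = cv(g1), cv(g2)
    return math.log(g1.mean / g2.mean) + 0.5 * (c1 * c1 / g2.n - c2 * c2 / g1.n)


def lnrr_pooled(g1: GroupSummary, g2: GroupSummary, p: PooledCV) -> float:
    """Bias-corrected lnRR with the pooled CVs substituted for the record's
    own (possibly unknown) CVs; sample sizes are the record's own."""
    b1, b2 = p.cv1_bar, p.cv2_bar
    return math.log(g1.mean / g2.mean) + 0.5 * (b1 * b1 / g2.n - b2 * b2 / g1.n)


# ---------------------------------------------------------------------------
# Sampling variances
# ---------------------------------------------------------------------------


def var_individual_first(g1: GroupSummary, g2: GroupSummary) -> float:
    """First-order sampling variance CV1^2/n1 + CV2^2/n2 from the record's
    own CVs."""
    c1, c2 = cv(g1), cv(g2)
    return c1 * c1 / g1.n + c2 * c2 / g2.n


def var_individual_second(g1: GroupSummary, g2: GroupSummary) -> float:
    """Second-order sampling variance: the first-order value plus
    CV1^4/(2 n1^2) + CV2^4/(2 n2^2)."""
    c1, c2 = cv(g1), cv(g2)
    return (
        c1 * c1 / g1.n
        + c2 * c2 / g2.n
        + c1**4 / (2.0 * g1.n**2)
        + c2**4 / (2.0 * g2.n**2)
    )


def var_pooled_first(g1: GroupSummary, g2: GroupSummary, p: PooledCV) -> float:
    """First-order sampling variance with pooled CVs; preferred over the
    second-order form when many effect sizes fail the Geary screen."""
    v = p.cv1_bar**2 / g1.n + p.cv2_bar**2 / g2.n
    if v == 0.0:
        raise DegenerateVarianceError("pooled CVs are both zero: variance is 0")
    return v


def var_pooled_second(g1: GroupSummary, g2: GroupSummary, p: PooledCV) -> float:
    """Second-order sampling variance with pooled CVs and the record's own
    sample sizes."""
    b1, b2 = p.cv1_bar, p.cv2_bar
    v = (
        b1 * b1 / g1.n
        + b2 * b2 / g2.n
        + b1**4 / (2.0 * g1.n**2)
        + b2**4 / (2.0 * g2.n**2)
    )
    if v == 0.0:
        raise DegenerateVarianceError("pooled CVs are both zero: variance is 0")
    return v


def n_tilde(n1: float, n2: float) -> float:
    """Combined sample size n1*n2/(n1+n2); its inverse is proportional to
    the lnRR sampling variance when both CVs equal 1."""
    return n1 * n2 / (n1 + n2)


# ---------------------------------------------------------------------------
# Improved Geary normality screen
# ---------------------------------------------------------------------------

#: Criterion threshold above which lnRR's normality assumption is tenable.
GEARY_THRESHOLD = 3.0


def geary_criterion(cv_value: float, n: int) -> float:
    """Improved Geary statistic (1/CV) * 4 n^{3/2} / (1 + 4 n).

    The screen passes when the value is at least 3; it is applied per
    group, and a record passes only if both groups pass.  A zero CV gives
    +inf (the screen always passes for noiseless data).
    """
    if cv_value < 0:
        raise DomainError(f"CV must be nonnegative (got {cv_value!r})")
    if n < 1:
        raise DomainError(f"n must be >= 1 (got {n!r})")
    if cv_value == 0.0:
        return math.inf
    return (1.0 / cv_value) * 4.0 * n**1.5 / (1.0 + 4.0 * n)


def geary_min_n(cv_value: float, n_max: int = 10_000_000) -> int:
    """Smallest integer sample size for which the improved Geary criterion
    reaches 3 at the given CV.

    The criterion grows like sqrt(n), so a solution always exists; the
    upward scan starts from an analytic lower bound (criterion < sqrt(n)/cv).
    """
    if cv_value <= 0:
        raise DomainError("geary_min_n requires cv > 0")
    # criterion(cv, n) <= sqrt(n)/cv, hence need n >= (3 cv)^2
    n = max(1, int((3.0 * cv_value) ** 2))
    while n > 1 and geary_criterion(cv_value, n - 1) >= GEARY_THRESHOLD:
        n -= 1
    while geary_criterion(cv_value, n) < GEARY_THRESHOLD:
        n += 1
        if n > n_max:  # pragma: no cover - defensive
            raise RuntimeError("geary_min_n scan exceeded n_max")
    return n


def geary_pass(record: EffectRecord) -> bool:
    """Whether both groups of a record pass the improved Geary screen.

    Exposed as a filter utility for sensitivity analyses; never applied
    implicitly by the strategy layer.
    """
    for g in (record.group1, record.group2):
        if g.sd is None:
            continue  # no CV to screen; do not fail the record for it
        if geary_criterion(g.sd / g.mean, g.n) < GEARY_THRESHOLD:
            return False
    return True


# ---------------------------------------------------------------------------
# Vectorised internals (array in, array out) used by the strategy layer
# ---------------------------------------------------------------------------


def _lnrr_corrected_arr(m1, cv1, n1, m2, cv2, n2) -> np.ndarray:
    return np.log(m1 / m2) + 0.5 * (cv1**2 / n2 - cv2**2 / n1)


def _var_second_arr(cv1, n1, cv2, n2) -> np.ndarray:
    return cv1**2 / n1 + cv2**2 / n2 + cv1**4 / (2.0 * n1**2) + cv2**4 / (2.0 * n2**2)


def _var_first_arr(cv1, n1, cv2, n2) -> np.ndarray:
    return cv1**2 / n1 + cv2**2 / n2


def _pooled_cv_frame(df) -> PooledCV:
    """Pooled CV from a raw-summary DataFrame (columns m1, sd1, n1, m2,
    sd2, n2, study_id); NaN SDs are missing."""
    bars = []
    for g in ("1", "2"):
        sd = df[f"sd{g}"].to_numpy(float)
        ok = ~np.isnan(sd)
        if not ok.any():
            raise NoCompleteRecordsError(
                f"every record is missing sd{g}; cannot pool CVs"
            )
        m = df[f"m{g}"].to_numpy(float)[ok]
        n = df[f"n{g}"].to_numpy(float)[ok]
        bars.append(float(np.sum(n * (sd[ok] / m)) / np.sum(n)))
    any_sd = (~np.isnan(df["sd1"].to_numpy(float))) | (~np.isnan(df["sd2"].to_numpy(float)))
    return PooledCV(
        cv1_bar=bars[0],
        cv2_bar=bars[1],
        n_studies_used=int(df.loc[any_sd, "study_id"].nunique()),
        n_effects_used=int(any_sd.sum()),
    )
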