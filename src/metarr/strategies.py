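"""Missing-SD handling strategies.

A meta-analytic dataset in which some studies do not report SDs can be
analysed in several ways.  Writing v for the second-order sampling
variance from a record's own CVs, and v~ for the variance from the pooled
(weighted-average) CVs with the record's own sample sizes:

======================  =======================  ==========================
strategy                variance, SD reported     variance, SD missing
======================  =======================  ==========================
reference               v                         (requires none missing)
complete-case           v (others dropped)        record dropped
missing-cases           v                         v~
all-cases               v~                        v~
multiplicative          phi * v~                  phi * v~
hybrid                  v                         phi * v~
======================  =======================  ==========================

Point estimates are shared by all strategies: the bias-corrected lnRR
from a record's own CVs when SDs are reported and from the pooled CVs
when they are not.  ``phi`` is a single proportionality scalar estimated
later by the model; the strategy layer only marks which diagonal entries
it multiplies.

``variance_order="first"`` swaps the second-order pooled variance for its
first-order form and the pooled-CV point correction for the raw log
ratio — advisable when many effect sizes fail the Geary normality screen,
because the first-order form does not rely on the second-order Taylor
expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import effectsize as es
from .effectsize import EffectEstimate, EffectRecord, PooledCV
from .exceptions import (
    DegenerateVarianceError,
    NoCompleteRecordsError,
    StrategyPreconditionError,
)
from .io import as_frame

__all__ = [
    "StrategyName",
    "StrategyResult",
    "MissingSDTransformer",
    "apply_strategy",
    "complete_case_filter",
    "STRATEGIES",
]


class StrategyName(str, Enum):
    REFERENCE = "reference"
    COMPLETE_CASE = "complete-case"
    MISSING_CASES = "missing-cases"
    ALL_CASES = "all-cases"
    MULTIPLICATIVE = "multiplicative"
    HYBRID = "hybrid"


#: Canonical strategy names accepted by the transformer and CLI.
STRATEGIES = tuple(s.value for s in StrategyName)

#: Strategies whose comparison the field recommends running in tandem.
MISSING_SD_METHODS = (
    StrategyName.MISSING_CASES,
    StrategyName.ALL_CASES,
    StrategyName.MULTIPLICATIVE,
    StrategyName.HYBRID,
)


@dataclass
class StrategyResult:
    """Per-effect point estimates, diagonal variance terms and the phi
    mask produced by one strategy.

    ``table`` has columns ``study_id, effect_id, yi, vi, phi_scaled``;
    ``vi`` enters the model either as a known sampling variance
    (``phi_scaled`` false) or as a proportional term multiplied by the
    estimated scalar phi (``phi_scaled`` true).
    """

    strategy: str
    variance_order: str
    table: pd.DataFrame
    pooled: PooledCV | None
    retained: list[str] = field(default_factory=list)

    @property
    def yi(self) -> np.ndarray:
        return self.table["yi"].to_numpy(float)

    @property
    def vi(self) -> np.ndarray:
        return self.table["vi"].to_numpy(float)

    @property
    def phi_scaled(self) -> np.ndarray:
        return self.table["phi_scaled"].to_numpy(bool)

    @property
    def study_ids(self) -> np.ndarray:
        return self.table["study_id"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        cols = ["study_id", "effect_id", "yi", "vi", "phi_scaled"]
        self.table[cols].to_csv(path, index=False)

    def estimates(self) -> list[EffectEstimate]:
        """Per-effect estimates tagged with the formulas that produced
        them (RAW_EQ1/CORRECTED_EQ4/POOLED_EQ6 points; IND_EQ5,
        POOLED_EQ7/EQ15 or PROPORTIONAL variances)."""
        out = []
        for row in self.table.itertuples(index=False):
            out.append(EffectEstimate(
                point=float(row.yi), variance=float(row.vi),
                estimator_tag=str(row.estimator_tag),
                variance_tag=("PROPORTIONAL" if row.phi_scaled
                              else str(row.variance_tag)),
            ))
        return out


class MissingSDTransformer(TransformerMixin, BaseEstimator):
    """Turn raw summary statistics into (yi, vi, phi-mask) per strategy.

    Parameters
    ----------
    strategy : str, default "all-cases"
        One of ``reference, complete-case, missing-cases, all-cases,
        multiplicative, hybrid``.
    variance_order : {"second", "first"}, default "second"
        Order of the Taylor expansion behind the pooled variance formula;
        "first" also replaces the pooled point correction with the raw
        log ratio.
    point_estimate : {"own", "pooled"}, default "own"
        Whether SD-complete records use their own CVs or the pooled CVs
        in the point-estimate bias correction (the choice makes little
        difference; "own" uses each record's data where available).

    Attributes
    ----------
    pooled_cv_ : PooledCV or None
        Weighted-average CVs estimated from the SD-reporting records of
        the dataset passed to :meth:`fit` (always the full input set,
        never a post-filter subset).
    result_ : StrategyResult
        Result for the fitted dataset (also returned by ``transform``).
    """

    def __init__(self, strategy: str = "all-cases",
                 variance_order: str = "second",
                 point_estimate: str = "own"):
        self.strategy = strategy
        self.variance_order = variance_order
        self.point_estimate = point_estimate

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X, y=None):
        df = as_frame(X)
        name = StrategyName(self.strategy)
        if self.variance_order not in ("second", "first"):
            raise ValueError(f"unknown variance_order {self.variance_order!r}")
        if self.point_estimate not in ("own", "pooled"):
            raise ValueError(f"unknown point_estimate {self.point_estimate!r}")

        sd1 = df["sd1"].to_numpy(float)
        sd2 = df["sd2"].to_numpy(float)
        complete = ~(np.isnan(sd1) | np.isnan(sd2))

        if name is StrategyName.REFERENCE and not complete.all():
            raise StrategyPreconditionError(
                "the reference strategy requires a dataset with no missing SDs"
            )
        if name is StrategyName.COMPLETE_CASE and complete.sum() < 2:
            raise StrategyPreconditionError(
                "complete-case analysis needs at least 2 SD-complete records"
            )
        if name not in (StrategyName.REFERENCE,) and not complete.any():
            raise NoCompleteRecordsError(
                "no SD-complete record to estimate pooled CVs from"
            )

        # Pooled CVs always come from the full input dataset.
        self.pooled_cv_ = es._pooled_cv_frame(df)
        self.result_ = self._build(df, complete, name)
        return self

    def transform(self, X) -> StrategyResult:
        """Strategy result for X (refits: pooled CVs always come from the
        dataset being transformed, per the strategies' definitions)."""
        self.fit(X)
        return self.result_

    # -- core dispatch ------------------------------------------------------
    def _build(self, df: pd.DataFrame, complete: np.ndarray,
               name: StrategyName) -> StrategyResult:
        p = self.pooled_cv_
        m1 = df["m1"].to_numpy(float)
        m2 = df["m2"].to_numpy(float)
        n1 = df["n1"].to_numpy(float)
        n2 = df["n2"].to_numpy(float)
        sd1 = df["sd1"].to_numpy(float)
        sd2 = df["sd2"].to_numpy(float)
        cv1 = np.where(complete, sd1 / m1, np.nan)
        cv2 = np.where(complete, sd2 / m2, np.nan)
        b1 = np.full_like(m1, p.cv1_bar)
        b2 = np.full_like(m1, p.cv2_bar)

        second = self.variance_order == "second"

        # --- point estimates (shared across the four missing-SD methods) ---
        raw = np.log(m1 / m2)
        own_pt = np.where(
            complete, es._lnrr_corrected_arr(m1, cv1, n1, m2, cv2, n2), np.nan
        )
        pooled_pt = (
            es._lnrr_corrected_arr(m1, b1, n1, m2, b2, n2) if second else raw
        )
        if self.point_estimate == "pooled":
            yi = pooled_pt.copy()
        else:
            yi = np.where(complete, own_pt, pooled_pt)

        # --- variances ------------------------------------------------------
        v_own = np.where(
            complete, es._var_second_arr(cv1, n1, cv2, n2), np.nan
        )
        v_pool = (
            es._var_second_arr(b1, n1, b2, n2)
            if second
            else es._var_first_arr(b1, n1, b2, n2)
        )

        phi = np.zeros(len(df), dtype=bool)
        keep = np.ones(len(df), dtype=bool)

        pooled_pt_tag = "POOLED_EQ6" if second else "RAW_EQ1"
        if self.point_estimate == "pooled":
            pt_tag = np.full(len(df), pooled_pt_tag, dtype=object)
        else:
            pt_tag = np.where(complete, "CORRECTED_EQ4", pooled_pt_tag)
        pool_v_tag = "POOLED_EQ7" if second else "POOLED_EQ15"
        v_tag = np.where(complete, "IND_EQ5", pool_v_tag)

        if name in (StrategyName.REFERENCE, StrategyName.COMPLETE_CASE):
            if name is StrategyName.COMPLETE_CASE:
                keep = complete
            yi = own_pt
            vi = v_own
            pt_tag = np.full(len(df), "CORRECTED_EQ4", dtype=object)
        elif name is StrategyName.MISSING_CASES:
            vi = np.where(complete, v_own, v_pool)
        elif name is StrategyName.ALL_CASES:
            vi = v_pool
            v_tag = np.full(len(df), pool_v_tag, dtype=object)
        elif name is StrategyName.MULTIPLICATIVE:
            vi = v_pool
            v_tag = np.full(len(df), pool_v_tag, dtype=object)
            phi[:] = True
        elif name is StrategyName.HYBRID:
            vi = np.where(complete, v_own, v_pool)
            phi = ~complete
        else:  # pragma: no cover
            raise ValueError(name)

        table = pd.DataFrame({
            "study_id": df["study_id"].to_numpy()[keep],
            "effect_id": df["effect_id"].to_numpy()[keep],
            "yi": yi[keep],
            "vi": vi[keep],
            "phi_scaled": phi[keep],
            "estimator_tag": pt_tag[keep],
            "variance_tag": v_tag[keep],
        })
        if (table["vi"].to_numpy() <= 0).any():
            raise DegenerateVarianceError(
                "a sampling variance of 0 was produced; a zero diagonal in V "
                "is singular (e.g. sd = 0 in both groups)"
            )
        return StrategyResult(
            strategy=name.value,
            variance_order=self.variance_order,
            table=table,
            pooled=p,
            retained=[str(e) for e in table["effect_id"]],
        )


def apply_strategy(records: pd.DataFrame | Iterable[EffectRecord],
                   strategy: str,
                   variance_order: str = "second",
                   point_estimate: str = "own") -> StrategyResult:
    """Functional wrapper over :class:`MissingSDTransformer`."""
    t = MissingSDTransformer(strategy=strategy, variance_order=variance_order,
                             point_estimate=point_estimate)
    return t.fit(records).result_


def complete_case_filter(records):
    """Records (or rows) with both SDs reported, in the original order."""
    if isinstance(records, pd.DataFrame):
        keep = ~(records["sd1"].isna() | records["sd2"].isna())
        return records.loc[keep]
    return [r for r in records if not r.sd_missing]
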