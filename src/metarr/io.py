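"""Reading and writing meta-analytic summary-statistics tables.

The on-disk format is a delimited text file with a header row and the
columns ``study_id, effect_id, m1, sd1, n1, m2, sd2, n2`` (one row per
effect size; group 1 = experimental, group 2 = control).  Empty cells or
the token ``NA`` in the SD columns denote a missing SD — a reported SD of
0 is valid data, distinct from missing.  Extra columns are preserved as
passthrough metadata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .effectsize import EffectRecord, GroupSummary
from .exceptions import SchemaError

REQUIRED_COLUMNS = ("study_id", "effect_id", "m1", "sd1", "n1", "m2", "sd2", "n2")

__all__ = [
    "REQUIRED_COLUMNS",
    "read_dataset",
    "write_dataset",
    "load_frame",
    "validate_frame",
    "records_to_frame",
    "frame_to_records",
]


def validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory dataset table; returns the (typed) frame.

    Raises :class:`SchemaError` naming the first missing column, or
    ``ValueError`` naming the offending row (1-based, excluding header)
    for value-level violations.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} is missing")
    df = df.copy()
    for col in ("m1", "sd1", "m2", "sd2"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("n1", "n2"):
        df[col] = pd.to_numeric(df[col], errors="raise")

    def _bad(mask: pd.Series, msg: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ValueError(f"row {row}: {msg}")

    for g in ("1", "2"):
        _bad(~(df[f"m{g}"] > 0), f"m{g} must be > 0 (lnRR requires ratio-scale data)")
        _bad(df[f"sd{g}"] < 0, f"sd{g} must be >= 0")
        _bad(df[f"n{g}"].isna() | (df[f"n{g}"] % 1 != 0) | (df[f"n{g}"] < 2),
             f"n{g} must be an integer >= 2")
        df[f"n{g}"] = df[f"n{g}"].astype(int)
    return df


def load_frame(path: str | Path) -> pd.DataFrame:
    """Read a dataset CSV into a validated DataFrame (NaN = missing SD)."""
    df = pd.read_csv(path, dtype={"study_id": str, "effect_id": str},
                     keep_default_na=False,
                     na_values=["", "NA"])
    return validate_frame(df)


def read_dataset(path: str | Path) -> list[EffectRecord]:
    """Read a dataset CSV into typed :class:`EffectRecord` objects."""
    return frame_to_records(load_frame(path))


def write_dataset(data: pd.DataFrame | Iterable[EffectRecord],
                  path: str | Path) -> None:
    """Write records or a dataset frame back to CSV (missing SDs as empty
    cells; full float precision)."""
    df = data if isinstance(data, pd.DataFrame) else records_to_frame(data)
    df.to_csv(path, index=False, na_rep="")


def frame_to_records(df: pd.DataFrame) -> list[EffectRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            EffectRecord(
                study_id=str(row.study_id),
                effect_id=str(row.effect_id),
                group1=GroupSummary(float(row.m1),
                                    None if pd.isna(row.sd1) else float(row.sd1),
                                    int(row.n1)),
                group2=GroupSummary(float(row.m2),
                                    None if pd.isna(row.sd2) else float(row.sd2),
                                    int(row.n2)),
            )
        )
    return recs


def records_to_frame(records: Iterable[EffectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "study_id": r.study_id,
            "effect_id": r.effect_id,
            "m1": r.group1.mean,
            "sd1": np.nan if r.group1.sd is None else r.group1.sd,
            "n1": r.group1.n,
            "m2": r.group2.mean,
            "sd2": np.nan if r.group2.sd is None else r.group2.sd,
            "n2": r.group2.n,
        })
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def as_frame(data: pd.DataFrame | Iterable[EffectRecord]) -> pd.DataFrame:
    """Normalise records-or-frame input to a validated DataFrame."""
    if isinstance(data, pd.DataFrame):
        return validate_frame(data)
    return records_to_frame(data)
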