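"""Cohort/estimates CSV readers and writers.

Cohort CSV schema: header ``id,age,sex,smoker,sbp,tc,ldl,hdl,weight,
cvd_history,diabetes,statin_use``; sex in {M, F}; booleans as 0/1;
decimal point; UTF-8; newline-terminated.  Numeric columns are written at
a declared precision so write-read-write round-trips byte-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS

__all__ = ["read_cohort_csv", "write_cohort_csv", "read_estimates_csv", "write_estimates_csv"]

_BOOL_COLUMNS = ["smoker", "cvd_history", "diabetes", "statin_use"]
_FLOAT_FORMAT = "%.10g"


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV violates the schema; names the offending row."""


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table; raises ``CohortSchemaError`` with
    the 1-based data row number on the first violation."""
    frame = pd.read_csv(path, dtype={"id": str, "sex": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing columns: {missing}")
    frame = frame[COHORT_COLUMNS]

    bad_sex = ~frame["sex"].isin(["M", "F"])
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0]) + 1
        raise CohortSchemaError(
            f"row {row}: sex must be 'M' or 'F', got {frame['sex'].iloc[row - 1]!r}"
        )
    for col in _BOOL_COLUMNS:
        vals = frame[col]
        bad = ~vals.isin([0, 1, True, False])
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CohortSchemaError(f"row {row}: {col} must be 0 or 1")
        frame[col] = vals.astype(bool)
    for col in ("age", "sbp", "tc", "ldl", "hdl", "weight"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CohortSchemaError(f"row {row}: {col} is not numeric")
        frame[col] = numeric.astype(float)
    bad_weight = frame["weight"] <= 0
    if bad_weight.any():
        row = int(np.flatnonzero(bad_weight)[0]) + 1
        raise CohortSchemaError(f"row {row}: weight must be positive")
    return frame


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = records.copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
    return path


def write_estimates_csv(records: pd.DataFrame, estimates: pd.DataFrame, path: str | Path) -> Path:
    """Write the cohort columns with the per-person estimate columns appended."""
    path = Path(path)
    combined = pd.concat([records.reset_index(drop=True), estimates.reset_index(drop=True)], axis=1)
    for col in _BOOL_COLUMNS:
        combined[col] = combined[col].astype(int)
    combined.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
    return path


def read_estimates_csv(path: str | Path) -> pd.DataFrame:
    """Read a combined cohort+estimates table written by :func:`write_estimates_csv`."""
    frame = pd.read_csv(path, dtype={"id": str, "sex": str})
    for col in _BOOL_COLUMNS:
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
    return frame
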