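"""Measurement-table I/O.

Two wide CSV dialects are accepted (RFC-4180, UTF-8, "." decimal, header
required), distinguished automatically from the header and never mixed
within a file:

* **raw** — eight edge measurements per subject, one (X1, X2) pair per
  projection and stage::

      subject_id, pre_max_x1_mm, pre_max_x2_mm, pre_min_x1_mm, pre_min_x2_mm,
                  post_max_x1_mm, post_max_x2_mm, post_min_x1_mm, post_min_x2_mm

* **averaged** — already-averaged diameters::

      subject_id, dmax_mm, dmin_mm, post_dmax_mm, post_dmin_mm

An optional ``group`` column (e.g. filter size) is carried through either
schema.  Millimetre units are hard-coded in the column names to prevent
unit drift.  Raw rows are collapsed with the edge mean (X1 + X2)/2; rows
with missing cells are dropped (complete-case) and counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .geometry import ValidationError

__all__ = [
    "RAW_COLUMNS",
    "AVERAGED_COLUMNS",
    "MeasurementTable",
    "read_measurement_table",
    "write_measurement_csv",
]

logger = logging.getLogger(__name__)

RAW_COLUMNS = (
    "pre_max_x1_mm",
    "pre_max_x2_mm",
    "pre_min_x1_mm",
    "pre_min_x2_mm",
    "post_max_x1_mm",
    "post_max_x2_mm",
    "post_min_x1_mm",
    "post_min_x2_mm",
)
AVERAGED_COLUMNS = ("dmax_mm", "dmin_mm", "post_dmax_mm", "post_dmin_mm")
_ID = "subject_id"


@dataclass
class MeasurementTable:
    """A validated per-subject diameter table in averaged (canonical) form."""

    data: pd.DataFrame  # subject_id, AVERAGED_COLUMNS, optional group
    schema: str  # 'raw' or 'averaged' (as read)
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.data)


def _detect_schema(columns) -> str:
    cols = set(columns)
    if _ID not in cols:
        raise ValidationError(f"missing required column '{_ID}'")
    if set(RAW_COLUMNS) <= cols:
        return "raw"
    if set(AVERAGED_COLUMNS) <= cols:
        return "averaged"
    raise ValidationError(
        "unrecognized measurement schema; expected either the raw columns "
        f"{list(RAW_COLUMNS)} or the averaged columns {list(AVERAGED_COLUMNS)} "
        f"(plus '{_ID}'), got {sorted(cols)}"
    )


def _coerce_numeric(df: pd.DataFrame, cols) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        fresh_nan = coerced.isna() & df[col].notna()
        if fresh_nan.any():
            row = int(np.flatnonzero(fresh_nan)[0])
            raise ValidationError(
                f"non-numeric value {df[col].iloc[row]!r} in column '{col}', "
                f"data row {row + 1}"
            )
        df[col] = coerced
    return df


def read_measurement_table(
    path: Union[str, Path], auto_sort: bool = False
) -> MeasurementTable:
    """Read and validate a measurement CSV in either dialect.

    Raw-schema rows are collapsed to diameters via the edge mean.  Rows
    with any missing measurement are dropped (complete-case) with a
    warning per row.  ``d_max < d_min`` on any row is an error naming the
    row unless ``auto_sort=True``, which reorders with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={_ID: str}, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    schema = _detect_schema(df.columns)
    value_cols = list(RAW_COLUMNS if schema == "raw" else AVERAGED_COLUMNS)
    df = _coerce_numeric(df, value_cols)

    if df[_ID].duplicated().any():
        dupes = df[_ID][df[_ID].duplicated()].tolist()
        raise ValidationError(f"duplicate subject ids: {dupes}")

    complete = df[value_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    for row in np.flatnonzero(~complete):
        logger.warning(
            "dropping incomplete row %d (subject %s): missing measurements",
            row + 1,
            df[_ID].iloc[row],
        )
    df = df.loc[complete].reset_index(drop=True)
    if df.empty:
        raise ValidationError(f"no complete rows left in {path}")

    if schema == "raw":
        out = pd.DataFrame({_ID: df[_ID]})
        out["dmax_mm"] = (df["pre_max_x1_mm"] + df["pre_max_x2_mm"]) / 2.0
        out["dmin_mm"] = (df["pre_min_x1_mm"] + df["pre_min_x2_mm"]) / 2.0
        out["post_dmax_mm"] = (df["post_max_x1_mm"] + df["post_max_x2_mm"]) / 2.0
        out["post_dmin_mm"] = (df["post_min_x1_mm"] + df["post_min_x2_mm"]) / 2.0
    else:
        out = df[[_ID, *AVERAGED_COLUMNS]].copy()
    if "group" in df.columns:
        out["group"] = df["group"].astype(str).values

    non_positive = (out[list(AVERAGED_COLUMNS)] <= 0).any(axis=1)
    if non_positive.any():
        row = int(np.flatnonzero(non_positive)[0])
        raise ValidationError(
            f"non-positive diameter for subject {out[_ID].iloc[row]!r} (data row {row + 1})"
        )

    swapped = out["dmax_mm"] < out["dmin_mm"]
    if swapped.any():
        row = int(np.flatnonzero(swapped)[0])
        if not auto_sort:
            raise ValidationError(
                f"d_max < d_min for subject {out[_ID].iloc[row]!r} (data row "
                f"{row + 1}); pass auto_sort=True to reorder"
            )
        logger.warning("auto-sorting %d row(s) with d_max < d_min", int(swapped.sum()))
        lo = out.loc[swapped, "dmax_mm"].copy()
        out.loc[swapped, "dmax_mm"] = out.loc[swapped, "dmin_mm"]
        out.loc[swapped, "dmin_mm"] = lo

    logger.info("read %d subjects (%s schema, %d dropped) from %s", len(out), schema, n_dropped, path)
    return MeasurementTable(data=out, schema=schema, n_dropped=n_dropped)


def write_measurement_csv(
    cohort: pd.DataFrame, path: Union[str, Path], schema: str = "raw"
) -> Path:
    """Write a simulated cohort (or canonical table) as a measurement CSV.

    ``schema='raw'`` writes the eight edge columns (requires them, i.e. a
    simulator output); ``schema='averaged'`` writes the four diameter
    columns.  Round-trips through :func:`read_measurement_table`.
    """
    path = Path(path)
    if schema == "raw":
        cols = [_ID, *RAW_COLUMNS]
    elif schema == "averaged":
        cols = [_ID, *AVERAGED_COLUMNS]
    else:
        raise ValidationError(f"schema must be 'raw' or 'averaged', got {schema!r}")
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table lacks columns for {schema} schema: {missing}")
    if "group" in cohort.columns:
        cols = cols + ["group"]
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort[cols].to_csv(path, index=False)
    return path
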