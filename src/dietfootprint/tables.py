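"""Reading, validating and writing the pipeline's tabular artifacts.

All artifacts are plain comma-separated UTF-8 text with a single header row
and ``.`` as the decimal separator:

* consumption tables: ``year,item,quantity,unit``
* emission-factor tables: ``food,gco2e_per_g``
* basket mappings: ``item,food,weight``
* footprint tables: ``year,group,gco2e_per_day``

Units in consumption tables are a closed enumeration; anything else raises
rather than being guessed at.  Validation is strict: bad rows are reported
by index, never silently dropped.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "VALID_UNITS",
    "read_consumption_table",
    "validate_consumption",
    "read_emission_factors",
    "validate_emission_factors",
    "read_mapping",
    "validate_mapping",
    "read_footprint_table",
    "write_results",
]

#: Closed set of units a consumption table may carry.
VALID_UNITS = frozenset(
    {"kg/person/year", "units/person/year", "g/person/day", "mL/person/day"}
)

CONSUMPTION_COLUMNS = ("year", "item", "quantity", "unit")
FACTOR_COLUMNS = ("food", "gco2e_per_g")
MAPPING_COLUMNS = ("item", "food", "weight")
FOOTPRINT_COLUMNS = ("year", "group", "gco2e_per_day")

#: Weight sums per item must match 1 to this tolerance.
WEIGHT_TOL = 1e-9


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    """Coerce a column to float, raising (not dropping) on unparseable cells."""
    values = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[values.isna() & df[column].notna()]
    if len(bad):
        raise ValidationError(
            f"{what}: unparseable {column!r} at row index(es) {list(bad[:10])}"
        )
    if values.isna().any():
        raise ValidationError(
            f"{what}: missing {column!r} at row index(es) "
            f"{list(df.index[values.isna()][:10])}"
        )
    return values.astype(float)


def validate_consumption(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a ``year,item,quantity,unit`` table and return a clean copy."""
    _require_columns(df, CONSUMPTION_COLUMNS, "consumption table")
    out = df.loc[:, list(CONSUMPTION_COLUMNS)].copy()
    out["year"] = _numeric(out, "year", "consumption table").astype(int)
    out["quantity"] = _numeric(out, "quantity", "consumption table")
    negative = out.index[out["quantity"] < 0]
    if len(negative):
        raise ValidationError(
            f"consumption table: negative quantity at row index(es) {list(negative[:10])}"
        )
    unknown = set(out["unit"].unique()) - VALID_UNITS
    if unknown:
        raise ValidationError(
            f"consumption table: unknown unit(s) {sorted(unknown)}; "
            f"expected one of {sorted(VALID_UNITS)}"
        )
    dup = out.duplicated(subset=["year", "item"])
    if dup.any():
        pairs = out.loc[dup, ["year", "item"]].itertuples(index=False, name=None)
        raise ValidationError(
            f"consumption table: duplicate (year, item) pairs: {list(pairs)[:10]}"
        )
    return out


def read_consumption_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a consumption CSV (``year,item,quantity,unit``)."""
    return validate_consumption(pd.read_csv(path))


def validate_emission_factors(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, FACTOR_COLUMNS, "emission-factor table")
    out = df.loc[:, list(FACTOR_COLUMNS)].copy()
    out["gco2e_per_g"] = _numeric(out, "gco2e_per_g", "emission-factor table")
    bad = out.index[out["gco2e_per_g"] <= 0]
    if len(bad):
        raise ValidationError(
            f"emission-factor table: non-positive factor at row index(es) {list(bad[:10])}"
        )
    if out["food"].duplicated().any():
        dups = sorted(out.loc[out["food"].duplicated(), "food"].unique())
        raise ValidationError(f"emission-factor table: duplicate food(s): {dups[:10]}")
    return out


def read_emission_factors(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate an emission-factor CSV (``food,gco2e_per_g``)."""
    return validate_emission_factors(pd.read_csv(path))


def validate_mapping(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an item→food basket mapping (``item,food,weight``).

    Weights must be non-negative and sum to 1 per item to 1e-9.
    """
    _require_columns(df, MAPPING_COLUMNS, "mapping table")
    out = df.loc[:, list(MAPPING_COLUMNS)].copy()
    out["weight"] = _numeric(out, "weight", "mapping table")
    bad = out.index[out["weight"] < 0]
    if len(bad):
        raise ValidationError(
            f"mapping table: negative weight at row index(es) {list(bad[:10])}"
        )
    sums = out.groupby("item")["weight"].sum()
    off = sums[(sums - 1.0).abs() > WEIGHT_TOL]
    if len(off):
        detail = {k: float(v) for k, v in off.head(10).items()}
        raise ValidationError(
            f"mapping table: weights do not sum to 1 for item(s) {detail}"
        )
    return out


def read_mapping(path: str | os.PathLike) -> pd.DataFrame:
    return validate_mapping(pd.read_csv(path))


def read_footprint_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a footprint CSV (``year,group,gco2e_per_day``)."""
    df = pd.read_csv(path)
    _require_columns(df, FOOTPRINT_COLUMNS, "footprint table")
    out = df.loc[:, list(FOOTPRINT_COLUMNS)].copy()
    out["year"] = _numeric(out, "year", "footprint table").astype(int)
    out["gco2e_per_day"] = _numeric(out, "gco2e_per_day", "footprint table")
    return out


def write_results(
    table: pd.DataFrame, path: str | os.PathLike, precision: int | None = None
) -> str:
    """Write a validated table as CSV; round-trips through the readers.

    Parameters
    ----------
    precision
        When given, numeric columns (other than ``year``) are formatted with
        this many decimals; otherwise full float repr is written so that a
        read-back is bit-identical.
    """
    out = table.copy()
    if precision is not None:
        for col in out.columns:
            if col != "year" and np.issubdtype(out[col].dtype, np.floating):
                out[col] = out[col].map(lambda v: f"{v:.{precision}f}")
    out.to_csv(path, index=False)
    return os.fspath(path)
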