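"""Reading and writing monitoring tables as delimited text.

CSV is the single interchange format.  A column-name mapping adapts
third-party exports (different header names) to the canonical schema
instead of hard-coding a dialect.  Timestamps are written ISO-8601;
temperature and moisture are rounded to 0.01, fluorescence to whole
instrument units, so a write/read round trip is lossless at the declared
precision.
"""

from __future__ import annotations

from os import PathLike
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import (
    MONITORING_COLUMNS,
    PROCESSED_COLUMNS,
    ConfigurationError,
    validate_monitoring,
)


def read_monitoring_csv(
    path: str | PathLike,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read and validate a monitoring CSV.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Optional mapping from canonical column name to the name used in the
        file, e.g. ``{"temperature_c": "Temp"}``; unmapped columns keep the
        canonical name.
    delimiter
        Field separator, default comma.

    Returns
    -------
    DataFrame sorted by (sensor_id, timestamp) with all record invariants
    enforced; see :func:`crustpam.datamodel.validate_monitoring`.
    """
    raw = pd.read_csv(path, sep=delimiter)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in MONITORING_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in raw.columns:
            raise ConfigurationError(
                f"column '{source}' (for '{canonical}') not found in {path}; "
                f"available: {', '.join(raw.columns)}"
            )
        rename[source] = canonical
    df = raw.rename(columns=rename)
    return validate_monitoring(df)


def write_monitoring_csv(
    records: pd.DataFrame, path: str | PathLike, delimiter: str = ","
) -> str | PathLike:
    """Write a validated monitoring table as delimited text.

    Rounds to the declared precision (0.01 for temperature/moisture/PAR,
    integer units for Ft/Fm) and formats timestamps ISO-8601.  Returns the
    path written.
    """
    df = validate_monitoring(records) if len(records) else _empty_table(records)
    out = df.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    for col in ("temperature_c", "moisture_pct", "par"):
        out[col] = out[col].round(2)
    for col in ("ft", "fm"):
        out[col] = out[col].round(0)
    out.to_csv(path, sep=delimiter, index=False, float_format="%.2f")
    return path


def _empty_table(records: pd.DataFrame) -> pd.DataFrame:
    cols = records.columns if len(records.columns) else MONITORING_COLUMNS
    missing = [c for c in MONITORING_COLUMNS if c not in cols]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")
    out = records[MONITORING_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    for col in MONITORING_COLUMNS[3:]:
        out[col] = pd.to_numeric(out[col])
    return out


def write_table_csv(df: pd.DataFrame, path: str | PathLike) -> str | PathLike:
    """Write a derived table (processed records, summaries, model output)."""
    out = df.copy()
    if "timestamp" in out.columns:
        out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
    out.to_csv(path, index=False)
    return path


def read_processed_csv(path: str | PathLike) -> pd.DataFrame:
    """Read a processed-record table written by the processing stage."""
    df = pd.read_csv(path)
    missing = [c for c in PROCESSED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing processed column(s): {', '.join(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["active"] = df["active"].astype(bool)
    return df


def records_equal(a: pd.DataFrame, b: pd.DataFrame, *, atol: float = 5.01e-3) -> bool:
    """Field-by-field comparison of two monitoring tables.

    Numeric fields compare within ``atol`` (default half the declared write
    precision, padded for decimal-to-binary representation slack);
    identifiers and timestamps compare exactly.
    """
    a = validate_monitoring(a)
    b = validate_monitoring(b)
    if len(a) != len(b):
        return False
    if not (a["timestamp"].values == b["timestamp"].values).all():
        return False
    for col in ("sensor_id", "treatment"):
        if not (a[col].values == b[col].values).all():
            return False
    for col in ("temperature_c", "moisture_pct", "par"):
        if not _close(a[col], b[col], atol):
            return False
    for col in ("ft", "fm"):
        if not _close(a[col], b[col], 0.5):
            return False
    return True


def _close(x: pd.Series, y: pd.Series, atol: float) -> bool:
    both_nan = x.isna() & y.isna()
    diff_ok = (x - y).abs() <= atol
    return bool((both_nan | diff_ok).all())
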