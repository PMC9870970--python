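"""Record and summary data model for 30-minute PAM monitoring campaigns.

Monitoring data live in pandas DataFrames with a fixed column schema; this
module declares the schema and enforces its invariants.  One row is one
30-minute observation from one sensor head: microclimate (lichen surface
temperature, relative moisture at the thallus, incident PAR) plus the raw
fluorescence pair (steady-state Ft and saturation-pulse maximal Fm).

Each sensor monitors one thallus in one microcosm, so ``sensor_id`` doubles
as the microcosm (random-effect) identifier downstream.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

#: Columns of a raw monitoring table, in canonical order.
MONITORING_COLUMNS = [
    "timestamp",
    "sensor_id",
    "treatment",
    "temperature_c",
    "moisture_pct",
    "par",
    "ft",
    "fm",
]

#: Extra columns added by fluorescence processing.
PROCESSED_COLUMNS = MONITORING_COLUMNS + ["period", "efficiency", "active"]

#: Allowed treatment labels.
TREATMENTS = ("control", "warming")

#: Allowed daily periods (split on incident PAR, not clock time).
PERIODS = ("diurnal", "nocturnal")

#: The sampling grid, minutes.
SAMPLING_INTERVAL_MIN = 30


class ValidationError(ValueError):
    """A monitoring table violates a declared invariant."""


class ConfigurationError(ValueError):
    """A configuration (column mapping, simulator or run config) is invalid."""


def _fail(msg: str, rows=None) -> None:
    if rows is not None and len(rows):
        shown = ", ".join(str(r) for r in rows[:5])
        more = f" (and {len(rows) - 5} more)" if len(rows) > 5 else ""
        msg = f"{msg} at row(s) {shown}{more}"
    raise ValidationError(msg)


def validate_monitoring(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a monitoring table against the record invariants.

    Checks presence and dtype of every schema column, physical ranges
    (moisture in [0, 100]; PAR, Ft, Fm non-negative), treatment labels,
    uniqueness of (sensor, timestamp) pairs and the strictly increasing
    30-minute timestamp grid within each sensor.  Ft/Fm may be NaN
    (sensor dropout leaves absent cells); microclimate may not.

    Returns the table sorted by (sensor_id, timestamp) with canonical
    column order.  Raises :class:`ValidationError` with offending row
    numbers otherwise.
    """
    missing = [c for c in MONITORING_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")
    df = df[MONITORING_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["sensor_id"] = df["sensor_id"].astype(str)
    df["treatment"] = df["treatment"].astype(str)

    bad_treat = ~df["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        _fail(
            f"treatment must be one of {TREATMENTS}",
            df.index[bad_treat].tolist(),
        )

    for col in ("temperature_c", "moisture_pct", "par", "ft", "fm"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            _fail(f"non-numeric value in column '{col}': {exc}", df.index[bad].tolist())

    for col in ("temperature_c", "moisture_pct", "par"):
        nan = df[col].isna()
        if nan.any():
            _fail(f"missing value in required column '{col}'", df.index[nan].tolist())

    checks = [
        ("moisture_pct", (df["moisture_pct"] < 0) | (df["moisture_pct"] > 100),
         "moisture_pct outside [0, 100]"),
        ("par", df["par"] < 0, "negative par"),
        ("ft", df["ft"] < 0, "negative ft"),
        ("fm", df["fm"] < 0, "negative fm"),
    ]
    for _, bad, msg in checks:
        bad = bad.fillna(False)
        if bad.any():
            _fail(msg, df.index[bad].tolist())

    dup = df.duplicated(subset=["sensor_id", "timestamp"], keep=False)
    if dup.any():
        _fail("duplicate (sensor_id, timestamp) pair", df.index[dup].tolist())

    df = df.sort_values(["sensor_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    # 30-minute grid: every within-sensor step is a positive multiple of 30 min.
    for sensor, grp in df.groupby("sensor_id", sort=False):
        deltas = grp["timestamp"].diff().dropna()
        if len(deltas) == 0:
            continue
        step = pd.Timedelta(minutes=SAMPLING_INTERVAL_MIN)
        off_grid = (deltas % step != pd.Timedelta(0)) | (deltas <= pd.Timedelta(0))
        if off_grid.any():
            _fail(
                f"sensor {sensor}: timestamps not strictly increasing on the "
                f"{SAMPLING_INTERVAL_MIN}-minute grid",
                deltas.index[off_grid].tolist(),
            )
    return df


def campaign_day_count(start: dt.date, end: dt.date) -> int:
    """Number of calendar days from ``start`` to ``end``, both inclusive.

    The reference campaign, 21 Sep 2016 through 25 May 2017, spans 247 days.
    """
    if isinstance(start, dt.datetime):
        start = start.date()
    if isinstance(end, dt.datetime):
        end = end.date()
    if start > end:
        raise ValueError(f"start date {start} is after end date {end}")
    return (end - start).days + 1


def day_grid(date: dt.date, records_per_day: int = 48) -> pd.DatetimeIndex:
    """Evenly spaced sampling timestamps covering one calendar day."""
    step_min = 24 * 60 // records_per_day
    start = pd.Timestamp(date)
    return pd.date_range(start, periods=records_per_day, freq=f"{step_min}min")


def campaign_grid(start: dt.date, end: dt.date, records_per_day: int = 48) -> pd.DatetimeIndex:
    """Sampling timestamps for a whole campaign (inclusive date range)."""
    n_days = campaign_day_count(start, end)
    step_min = 24 * 60 // records_per_day
    return pd.date_range(
        pd.Timestamp(start), periods=n_days * records_per_day, freq=f"{step_min}min"
    )


def hour_of_day(timestamps: pd.DatetimeIndex) -> np.ndarray:
    """Fractional hour of day (0..24) for each timestamp."""
    ts = pd.DatetimeIndex(timestamps)
    return (
        ts.hour.to_numpy()
        + ts.minute.to_numpy() / 60.0
        + ts.second.to_numpy() / 3600.0
    )
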