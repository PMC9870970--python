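"""Daily and seasonal activity statistics.

Aggregates processed records to one row per sensor x date x period
(diurnal/nocturnal): record and active counts, % activity (active records
over all records that period, so a filtered-out record still counts in the
denominator), the photosynthesis-permitting-light variant (records with
PAR at or above a 70 umol m-2 s-1 threshold), microclimate means, the mean
temperature during active records only, and the mean of positive
efficiency values only (the convention for daily Yield / Fv/Fm).  Groups
with no records yield no row — a day a sensor missed is absent, not a
fabricated zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .seasons import SeasonRule, assign_season  # noqa: F401  (re-export)

__all__ = [
    "SeasonRule",
    "assign_season",
    "summarize_day",
    "summarize_campaign",
    "proportion_active_days",
    "treatment_difference",
]

#: PAR threshold (umol m-2 s-1) above which net photosynthesis is attainable.
DEFAULT_LIGHT_THRESHOLD = 70.0

SUMMARY_COLUMNS = [
    "sensor_id", "treatment", "date", "period", "season",
    "n_records", "n_active", "pct_activity",
    "n_par_ge_threshold", "n_active_par_ge_threshold", "pct_activity_par",
    "mean_temperature", "mean_moisture", "mean_temperature_active",
    "mean_efficiency",
]


def _summary_row(grp: pd.DataFrame, light_threshold: float,
                 par_variant: str) -> dict:
    n = len(grp)
    active = grp["active"].to_numpy(bool)
    par_ok = grp["par"].to_numpy(float) >= light_threshold
    n_active = int(active.sum())
    n_par = int(par_ok.sum())
    n_active_par = int((active & par_ok).sum())
    if par_variant == "qualified":
        pct_par = 100.0 * n_active_par / n_par if n_par else np.nan
    else:  # qualified-active over all records
        pct_par = 100.0 * n_active_par / n
    eff = grp["efficiency"].to_numpy(float)
    pos_eff = eff[np.isfinite(eff) & (eff > 0)]
    t = grp["temperature_c"].to_numpy(float)
    return {
        "n_records": n,
        "n_active": n_active,
        "pct_activity": 100.0 * n_active / n,
        "n_par_ge_threshold": n_par,
        "n_active_par_ge_threshold": n_active_par,
        "pct_activity_par": pct_par,
        "mean_temperature": float(t.mean()),
        "mean_moisture": float(grp["moisture_pct"].mean()),
        "mean_temperature_active": float(t[active].mean()) if n_active else np.nan,
        "mean_efficiency": float(pos_eff.mean()) if len(pos_eff) else np.nan,
    }


def summarize_day(
    records: pd.DataFrame,
    light_threshold: float = DEFAULT_LIGHT_THRESHOLD,
    rule: SeasonRule | None = None,
    par_variant: str = "qualified",
) -> dict:
    """Summary statistics for one sensor x date x period group of records.

    ``par_variant`` controls the suitable-light activity percentage:
    ``"qualified"`` (default) divides active-at-PAR>=threshold counts by
    the PAR-qualified record count (the fraction of photosynthesis-
    permitting time that was used); ``"all"`` divides by all records.
    """
    if len(records) == 0:
        raise ValueError("empty group: no summary is defined")
    for col in ("sensor_id", "period"):
        if records[col].nunique() != 1:
            raise ValueError(f"records span multiple values of {col}")
    dates = pd.DatetimeIndex(records["timestamp"]).normalize()
    if dates.nunique() != 1:
        raise ValueError("records span multiple dates")
    rule = rule or SeasonRule()
    date = dates[0].date()
    row = {
        "sensor_id": records["sensor_id"].iloc[0],
        "treatment": records["treatment"].iloc[0],
        "date": date,
        "period": records["period"].iloc[0],
        "season": rule.assign(date),
    }
    row.update(_summary_row(records, light_threshold, par_variant))
    return row


def summarize_campaign(
    processed: pd.DataFrame,
    rule: SeasonRule | None = None,
    light_threshold: float = DEFAULT_LIGHT_THRESHOLD,
    par_variant: str = "qualified",
) -> pd.DataFrame:
    """One summary row per (sensor, date, period) with at least one record.

    Rows are ordered by sensor, date, then period (diurnal before
    nocturnal).  With the complete reference campaign this yields
    6 sensors x 247 days = 1,482 sensor-days, each contributing a diurnal
    and a nocturnal row.
    """
    rule = rule or SeasonRule()
    df = processed.copy()
    df["date"] = pd.DatetimeIndex(df["timestamp"]).normalize()
    rows = []
    for (sensor, date, period), grp in df.groupby(
        ["sensor_id", "date", "period"], sort=True
    ):
        row = {
            "sensor_id": sensor,
            "treatment": grp["treatment"].iloc[0],
            "date": date.date(),
            "period": period,
            "season": rule.assign(date.date()),
        }
        row.update(_summary_row(grp, light_threshold, par_variant))
        rows.append(row)
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if len(out):
        out = out.sort_values(
            ["sensor_id", "date", "period"], kind="mergesort"
        ).reset_index(drop=True)
    return out


def proportion_active_days(
    summaries: pd.DataFrame,
    cutoff: float = 50.0,
    groupby: tuple[str, ...] = ("season", "treatment"),
) -> pd.DataFrame:
    """Fraction of sensor-days whose % activity strictly exceeds ``cutoff``.

    Returns one row per group with ``n_days`` and ``proportion`` in [0, 1].
    Days at exactly the cutoff do not count (strict inequality).
    """
    rows = []
    for key, grp in summaries.groupby(list(groupby), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(groupby, key))
            | {
                "n_days": len(grp),
                "proportion": float((grp["pct_activity"] > cutoff).mean()),
            }
        )
    return pd.DataFrame(rows)


def treatment_difference(
    summaries: pd.DataFrame,
    variable: str,
    period: str | None = None,
    season: str | None = None,
) -> float:
    """Warming mean minus control mean of a summary field within a scope.

    ``period`` / ``season`` filter the summaries before averaging; either
    may be None for the whole series.  Raises if the scope leaves either
    treatment unrepresented.
    """
    df = summaries
    if period is not None:
        df = df[df["period"] == period]
    if season is not None:
        df = df[df["season"] == season]
    means = df.groupby("treatment")[variable].mean()
    for treatment in ("control", "warming"):
        if treatment not in means.index or df["treatment"].eq(treatment).sum() == 0:
            raise ValueError(
                f"scope (period={period}, season={season}) has no "
                f"'{treatment}' summaries"
            )
    return float(means["warming"] - means["control"])
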