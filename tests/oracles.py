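"""Independent brute-force re-implementations used as test oracles.

Deliberately written as plain per-record Python loops with no shared code
with the package, so they can certify the vectorised pipeline.
"""

from __future__ import annotations

import math


def oracle_process_row(par, ft, fm, *, ft_thr=10.0, fm_thr=50.0, min_yield=0.1,
                       par_day=0.0, formula="standard"):
    """Process one record: (period, efficiency-or-None, active)."""
    period = "diurnal" if par > par_day else "nocturnal"
    missing = ft is None or fm is None or ft != ft or fm != fm
    if missing or ft < ft_thr or fm < fm_thr:
        return period, None, False
    if formula == "standard":
        if fm == 0:
            return period, None, False
        eff = max(0.0, (fm - ft) / fm)
    else:
        if ft == 0:
            return period, None, False
        eff = (fm - ft) / ft
    return period, eff, eff >= min_yield


def oracle_process_table(records, **kwargs):
    """Per-record loop over a monitoring DataFrame; returns list of tuples."""
    out = []
    for row in records.itertuples(index=False):
        out.append(
            oracle_process_row(row.par, row.ft, row.fm, **kwargs)
        )
    return out


def oracle_daily_summaries(processed, light_threshold=70.0):
    """Recount every sensor x date x period group by brute force.

    Returns a dict keyed by (sensor_id, date, period) with the same fields
    as the package's DailySummary rows (means as float, absent as None).
    """
    groups: dict[tuple, list] = {}
    for row in processed.itertuples(index=False):
        key = (row.sensor_id, row.timestamp.date(), row.period)
        groups.setdefault(key, []).append(row)
    out = {}
    for key, rows in groups.items():
        n = len(rows)
        n_active = sum(1 for r in rows if r.active)
        n_par = sum(1 for r in rows if r.par >= light_threshold)
        n_active_par = sum(1 for r in rows if r.active and r.par >= light_threshold)
        temps = [r.temperature_c for r in rows]
        moists = [r.moisture_pct for r in rows]
        act_temps = [r.temperature_c for r in rows if r.active]
        pos_effs = [
            r.efficiency
            for r in rows
            if r.efficiency == r.efficiency and r.efficiency > 0
        ]
        out[key] = {
            "n_records": n,
            "n_active": n_active,
            "pct_activity": 100.0 * n_active / n,
            "n_par_ge_threshold": n_par,
            "n_active_par_ge_threshold": n_active_par,
            "pct_activity_par": (100.0 * n_active_par / n_par) if n_par else None,
            "mean_temperature": sum(temps) / n,
            "mean_moisture": sum(moists) / n,
            "mean_temperature_active": (
                sum(act_temps) / len(act_temps) if act_temps else None
            ),
            "mean_efficiency": (
                sum(pos_effs) / len(pos_effs) if pos_effs else None
            ),
        }
    return out


def close(a, b, tol=1e-9):
    if a is None or b is None or b != b:
        return (a is None or a != a) and (b is None or b != b)
    return math.isclose(a, b, rel_tol=tol, abs_tol=tol)
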