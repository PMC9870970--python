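"""Raw record -> processed record: noise filter, PSII efficiency, activity.

The monitoring device applies a saturation-pulse protocol every 30
minutes: steady-state fluorescence Ft under a weak measuring light, then
maximal fluorescence Fm during a ~1 s saturating flash.  Readings below
the instrument noise floors (10 units for Ft, 50 for Fm by default) are
basal noise from a dry thallus, not signal.  For retained readings the
PSII quantum-use efficiency is computed — called Yield when measured in
the light (PAR > 0) and Fv/Fm when measured in darkness; the arithmetic is
identical, only the period label differs.  Efficiencies below the activity
threshold (0.1 by default) are too weak to count as clear metabolic
activity, guarding against drifts in Ft and Fm unrelated to real
hydration.

Two efficiency formulas are available.  The ``standard`` saturation-pulse
formula (Fm - Ft) / Fm is the default: it is the definition the method's
literature uses and the only one consistent with the instrument's stated
0-0.8 output range.  The ``ft_denominator`` variant (Fm - Ft) / Ft is kept
selectable for fidelity experiments with sources that print that form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import validate_monitoring

__all__ = [
    "ProcessingParams",
    "classify_period",
    "passes_noise_filter",
    "compute_efficiency",
    "flag_activity",
    "process_records",
]


@dataclass(frozen=True)
class ProcessingParams:
    ft_noise_threshold: float = 10.0
    fm_noise_threshold: float = 50.0
    #: Efficiencies below this are removed as unclear activity (instrument
    #: drift rather than real hydration); the threshold value itself passes.
    min_yield: float = 0.1
    #: PAR strictly above this is diurnal; 0 separates day and night.
    par_day_threshold: float = 0.0
    #: "standard": (Fm - Ft) / Fm; "ft_denominator": (Fm - Ft) / Ft.
    efficiency_formula: str = "standard"

    def __post_init__(self):
        if self.ft_noise_threshold < 0 or self.fm_noise_threshold < 0:
            raise ValueError("noise thresholds must be >= 0")
        if not 0.0 <= self.min_yield <= 1.0:
            raise ValueError("min_yield must be in [0, 1]")
        if self.par_day_threshold < 0:
            raise ValueError("par_day_threshold must be >= 0")
        if self.efficiency_formula not in ("standard", "ft_denominator"):
            raise ValueError(
                "efficiency_formula must be 'standard' or 'ft_denominator'"
            )

    def with_(self, **kwargs) -> "ProcessingParams":
        return replace(self, **kwargs)


def classify_period(par, params: ProcessingParams | None = None):
    """'diurnal' where PAR exceeds the day threshold, else 'nocturnal'.

    Accepts a scalar or array; negative PAR raises.
    """
    params = params or ProcessingParams()
    arr = np.asarray(par, dtype=float)
    if np.any(arr < 0):
        raise ValueError("par must be >= 0")
    out = np.where(arr > params.par_day_threshold, "diurnal", "nocturnal")
    return out.item() if np.isscalar(par) or arr.ndim == 0 else out


def passes_noise_filter(ft, fm, params: ProcessingParams | None = None):
    """True where both readings clear the instrument noise floors (inclusive)."""
    params = params or ProcessingParams()
    ft = np.asarray(ft, dtype=float)
    fm = np.asarray(fm, dtype=float)
    ok = (ft >= params.ft_noise_threshold) & (fm >= params.fm_noise_threshold)
    ok = ok & ~np.isnan(ft) & ~np.isnan(fm)
    return bool(ok) if ok.ndim == 0 else ok


def compute_efficiency(ft, fm, params: ProcessingParams | None = None):
    """PSII quantum-use efficiency from a fluorescence pair.

    standard: (Fm - Ft) / Fm, clamped below at 0 — always in [0, 1).
    ft_denominator: (Fm - Ft) / Ft, unbounded above.
    A zero denominator yields NaN (undefined efficiency; the record is
    treated as filtered out downstream).
    """
    params = params or ProcessingParams()
    ft = np.asarray(ft, dtype=float)
    fm = np.asarray(fm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if params.efficiency_formula == "standard":
            eff = np.where(fm > 0, np.maximum(0.0, (fm - ft) / fm), np.nan)
        else:
            eff = np.where(ft > 0, (fm - ft) / ft, np.nan)
    return float(eff) if eff.ndim == 0 else eff


def flag_activity(efficiency, params: ProcessingParams | None = None):
    """True where efficiency reaches the activity threshold (inclusive)."""
    params = params or ProcessingParams()
    eff = np.asarray(efficiency, dtype=float)
    active = ~np.isnan(eff) & (eff >= params.min_yield)
    return bool(active) if active.ndim == 0 else active


def process_records(
    records: pd.DataFrame, params: ProcessingParams | None = None
) -> pd.DataFrame:
    """Validate and process a monitoring table, one output row per input.

    Adds:

    - ``period``: diurnal/nocturnal from incident PAR;
    - ``efficiency``: Yield (diurnal) or Fv/Fm (nocturnal) — identical
      arithmetic, the name follows the period; NaN when the noise filter
      fails, a fluorescence value is missing, or the denominator is zero;
    - ``active``: efficiency present and at or above ``min_yield``.

    A record failing the noise filter is inactive, not missing: it still
    counts in the daily activity denominator.
    """
    params = params or ProcessingParams()
    df = validate_monitoring(records)
    ft = df["ft"].to_numpy(float)
    fm = df["fm"].to_numpy(float)
    df["period"] = classify_period(df["par"].to_numpy(float), params)
    keep = passes_noise_filter(ft, fm, params)
    eff = np.where(keep, compute_efficiency(ft, fm, params), np.nan)
    df["efficiency"] = eff
    df["active"] = flag_activity(eff, params)
    return df
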