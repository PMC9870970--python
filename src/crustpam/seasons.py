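"""Season assignment for campaign dates.

The campaign runs autumn through spring; the default boundaries are
astronomical (the campaign starts 21 September, one day before the
equinox): autumn 21 Sep - 20 Dec, winter 21 Dec - 20 Mar, spring 21 Mar -
20 Jun.  Boundaries are configurable because conventions (astronomical vs
meteorological) shift results for days near 1 Dec / 1 Mar.  Summer dates
are outside the default rule and raise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASONS = ("autumn", "winter", "spring")


@dataclass(frozen=True)
class SeasonRule:
    """Maps calendar dates to season labels via (month, day) windows.

    ``windows`` is a tuple of ``(start, end, season)`` with start/end as
    (month, day) pairs, both inclusive; a window may wrap the year end
    (e.g. winter 21 Dec - 20 Mar).  Windows must not overlap.
    """

    windows: tuple = field(
        default=(
            ((9, 21), (12, 20), "autumn"),
            ((12, 21), (3, 20), "winter"),
            ((3, 21), (6, 20), "spring"),
        )
    )

    def assign(self, date: dt.date) -> str:
        """Season label for one date; raises for dates no window covers."""
        md = date.month * 100 + date.day
        for (sm, sd), (em, ed), season in self.windows:
            lo, hi = sm * 100 + sd, em * 100 + ed
            if (lo <= md <= hi) if lo <= hi else (md >= lo or md <= hi):
                return season
        raise ValueError(f"date {date} is not covered by the season rule")

    def assign_many(self, dates) -> pd.Series:
        """Vectorised :meth:`assign` over a date-like sequence."""
        idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
        md = idx.month.to_numpy() * 100 + idx.day.to_numpy()
        out = np.full(len(md), None, dtype=object)
        for (sm, sd), (em, ed), season in self.windows:
            lo, hi = sm * 100 + sd, em * 100 + ed
            hit = (md >= lo) & (md <= hi) if lo <= hi else (md >= lo) | (md <= hi)
            out[hit] = season
        if (out == None).any():  # noqa: E711
            bad = idx[out == None][:3].date  # noqa: E711
            raise ValueError(f"dates not covered by the season rule, e.g. {list(bad)}")
        return pd.Series(out, index=range(len(out)), dtype=object)


def assign_season(date: dt.date, rule: SeasonRule | None = None) -> str:
    """Season label for a calendar date under ``rule`` (default astronomical)."""
    return (rule or SeasonRule()).assign(date)
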