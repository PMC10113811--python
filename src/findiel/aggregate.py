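"""Hourly presence/absence aggregation and detection-day summaries.

Acoustic presence is binary per hour — at least one accepted 20 Hz pulse
detection in the hour — deliberately ignoring how many pulses occurred.  The
statistical analysis conditions on *detection days*: calendar days (UTC) with
presence in at least one hour.  Summaries here back the standard displays:
a day-of-year x hour-of-day presence matrix summed across years, and the mean
proportion of presence hours per detection day in each light regime.
"""

from __future__ import annotations

import warnings
from datetime import timedelta

import numpy as np
import pandas as pd

from .solar import REGIMES

__all__ = [
    "hourly_presence",
    "detection_days",
    "presence_matrix",
    "regime_proportions",
]


def _to_utc(values) -> pd.DatetimeIndex:
    """ISO strings (with or without fractional seconds) or datetimes -> UTC index."""
    values = list(values)
    if values and isinstance(values[0], str):
        return pd.DatetimeIndex(pd.to_datetime(values, utc=True, format="ISO8601"))
    return pd.DatetimeIndex(pd.to_datetime(values, utc=True))


def hourly_presence(event_times, hours) -> pd.DataFrame:
    """Binary presence per hour from accepted detection times.

    ``event_times`` are UTC instants of accepted detections; ``hours`` is the
    grid of UTC hour starts.  presence(h) = 1 iff at least one event falls in
    [h, h+1h) — hour-boundary events go to the later hour.  Events outside the
    grid raise a warning and are ignored.
    """
    hour_idx = _to_utc(hours)
    events = _to_utc(event_times)
    presence = np.zeros(len(hour_idx), dtype=np.int8)
    if len(events) and len(hour_idx):
        floors = events.floor("h")
        pos = hour_idx.get_indexer(floors)
        n_outside = int((pos < 0).sum())
        if n_outside:
            warnings.warn(f"{n_outside} detection(s) outside the hour grid were ignored")
        presence[np.unique(pos[pos >= 0])] = 1
    elif len(events):
        warnings.warn(f"{len(events)} detection(s) outside the (empty) hour grid were ignored")
    return pd.DataFrame(
        {
            "utc_hour": hour_idx,
            "presence": presence,
            "day_of_year": hour_idx.dayofyear if len(hour_idx) else [],
            "hour_of_day": hour_idx.hour if len(hour_idx) else [],
        }
    )


def _with_date(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["date"] = pd.to_datetime(table["utc_hour"], utc=True).dt.date
    return table


def detection_days(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Restrict an hourly table to detection days (>= 1 presence hour per site-date).

    Returns the conditioned table plus totals: detection days, presence hours,
    and retained hours.  Presence hours are conserved by the conditioning.
    """
    table = _with_date(table)
    if "site" not in table.columns:
        table["site"] = ""
    day_any = table.groupby(["site", "date"])["presence"].transform("max")
    kept = table[day_any == 1].reset_index(drop=True)
    totals = {
        "n_detection_days": int(kept.groupby(["site", "date"]).ngroups),
        "n_presence_hours": int(kept["presence"].sum()),
        "n_hours_retained": int(len(kept)),
    }
    return kept, totals


def presence_matrix(table: pd.DataFrame) -> np.ndarray:
    """366 x 24 grid of presence counts, summed over years ("presence overlapping").

    Cell (d-1, h) counts the years in which hour-of-day h of day-of-year d had
    presence.  Grid row sums therefore equal per-day presence-hour totals.
    """
    grid = np.zeros((366, 24), dtype=int)
    present = table[table["presence"] == 1]
    if len(present):
        doy = present["day_of_year"].to_numpy(dtype=int)
        hod = present["hour_of_day"].to_numpy(dtype=int)
        np.add.at(grid, (doy - 1, hod), 1)
    return grid


def regime_proportions(
    table: pd.DataFrame, denominator: str = "regime_hours"
) -> pd.DataFrame:
    """Mean (+- s.e.) proportion of presence hours per detection day by regime.

    For each detection day and regime, the proportion is presence hours in the
    regime divided by either that regime's hour count that day (default,
    ``denominator='regime_hours'`` — comparable across regimes of unequal
    length) or the day's total presence hours (``'presence_hours'``).  Days on
    which a regime does not occur contribute nothing to that regime's mean.
    """
    if denominator not in ("regime_hours", "presence_hours"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    table = _with_date(table)
    if table.empty:
        raise ValueError("no detection days supplied")
    if "site" not in table.columns:
        table["site"] = ""
    g = table.groupby(["site", "date", "regime"], observed=True)["presence"].agg(["sum", "count"]).reset_index()
    if denominator == "regime_hours":
        g["proportion"] = g["sum"] / g["count"]
    else:
        day_tot = g.groupby(["site", "date"])["sum"].transform("sum")
        g["proportion"] = g["sum"] / day_tot
    rows = []
    for regime in REGIMES:
        vals = g.loc[g["regime"] == regime, "proportion"].to_numpy(dtype=float)
        if len(vals) == 0:
            warnings.warn(f"regime {regime!r} never occurs in the table; summary omitted")
            continue
        rows.append(
            {
                "regime": regime,
                "mean_proportion": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                "n_days": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
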