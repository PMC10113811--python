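"""Solar altitude and diel light-regime classification.

Each 24 h UTC day is partitioned into four light regimes — dawn, day, dusk,
night — from the geometric altitude of the sun sampled at 1-min intervals:

* **dawn**: the hours of and between nautical-twilight start (first upward
  crossing of −12°) and sunrise (upward crossing of 0°);
* **day**: hours after sunrise and before sunset;
* **dusk**: the hours from sunset to nautical-twilight end;
* **night**: hours between twilight end and the next twilight start.

The entire hour containing a sun-condition change (sunrise, sunset, twilight
crossing) is promoted to the adjacent twilight class.  Altitudes come from the
NOAA/Meeus low-precision solar position algorithm (geometric, no refraction),
valid 1900–2100 to well under 0.1°.  Polar special cases (midnight sun, polar
night, all-day twilight) are handled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as date_cls
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

__all__ = [
    "GeoLocation",
    "RegimeConfig",
    "DayEvents",
    "REGIMES",
    "solar_altitude",
    "day_events",
    "classify_hour",
    "classify_series",
]

REGIMES = ("dawn", "day", "dusk", "night")


@dataclass(frozen=True)
class GeoLocation:
    """Site coordinates, degrees; latitude positive north, longitude positive east."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not abs(self.latitude) <= 90:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not abs(self.longitude) <= 180:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class RegimeConfig:
    """Altitude thresholds (degrees) and scan resolution for regime assignment."""

    twilight_altitude_deg: float = -12.0
    horizon_altitude_deg: float = 0.0
    sampling_minutes: int = 1

    def __post_init__(self) -> None:
        if not self.twilight_altitude_deg < self.horizon_altitude_deg:
            raise ValueError("twilight altitude must lie below the horizon altitude")


@dataclass
class DayEvents:
    """Solar event instants for one UTC date; any may be absent at polar latitudes."""

    date: date_cls
    twilight_start: datetime | None = None
    sunrise: datetime | None = None
    sunset: datetime | None = None
    twilight_end: datetime | None = None


def _julian_day(t: np.ndarray) -> np.ndarray:
    """UTC datetime64 array -> Julian day."""
    epoch = np.datetime64("1970-01-01T00:00:00", "s")
    return (t.astype("datetime64[s]") - epoch) / np.timedelta64(86400, "s") + 2440587.5


def _to_datetime64(t) -> np.ndarray:
    if isinstance(t, datetime):
        t = [t]
    arr = pd.to_datetime(list(t) if not isinstance(t, np.ndarray) else t, utc=True)
    return np.asarray(arr.tz_convert(None).values, dtype="datetime64[s]")


def solar_altitude(loc: GeoLocation, t) -> float | np.ndarray:
    """Geometric solar altitude in degrees at UTC instant(s) ``t``.

    Implements the NOAA solar position algorithm (Meeus truncation): solar
    declination and the equation of time from the Julian century, then the
    local hour angle from longitude and UTC clock time.  No atmospheric
    refraction is applied.
    """
    scalar = isinstance(t, datetime)
    t64 = _to_datetime64(t)
    years = t64.astype("datetime64[Y]").astype(int) + 1970
    if years.min() < 1900 or years.max() > 2100:
        raise ValueError("instant outside supported range 1900-2100")
    jd = _julian_day(t64)
    T = (jd - 2451545.0) / 36525.0
    rad = np.pi / 180.0

    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    ecc = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        np.sin(M * rad) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * M * rad) * (0.019993 - 0.000101 * T)
        + np.sin(3 * M * rad) * 0.000289
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega * rad)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(omega * rad)
    decl = np.arcsin(np.sin(eps * rad) * np.sin(app_long * rad)) / rad

    y = np.tan(eps * rad / 2.0) ** 2
    eot_min = 4.0 / rad * (
        y * np.sin(2 * L0 * rad)
        - 2.0 * ecc * np.sin(M * rad)
        + 4.0 * ecc * y * np.sin(M * rad) * np.cos(2 * L0 * rad)
        - 0.5 * y * y * np.sin(4 * L0 * rad)
        - 1.25 * ecc * ecc * np.sin(2 * M * rad)
    )

    day_sec = (t64 - t64.astype("datetime64[D]")) / np.timedelta64(1, "s")
    tst = np.mod(day_sec / 60.0 + eot_min + 4.0 * loc.longitude, 1440.0)
    hour_angle = tst / 4.0 - 180.0

    alt = np.arcsin(
        np.sin(loc.latitude * rad) * np.sin(decl * rad)
        + np.cos(loc.latitude * rad) * np.cos(decl * rad) * np.cos(hour_angle * rad)
    ) / rad
    return float(alt[0]) if scalar else alt


def _minute_grid(loc: GeoLocation, date: date_cls, cfg: RegimeConfig) -> tuple[np.ndarray, np.ndarray]:
    """Altitudes on the date's minute grid, including the closing midnight."""
    step = cfg.sampling_minutes
    n = 1440 // step
    start = np.datetime64(date.isoformat() + "T00:00:00", "s")
    times = start + np.arange(n + 1) * np.timedelta64(60 * step, "s")
    alts = solar_altitude(loc, times)
    return times, np.asarray(alts)


def _crossings(alts: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of upward / downward crossings of ``level`` between grid points.

    A crossing at index i means the level is passed between samples i-1 and i;
    the event time is attributed to sample i.
    """
    below = alts < level
    up = np.flatnonzero(below[:-1] & ~below[1:]) + 1
    down = np.flatnonzero(~below[:-1] & below[1:]) + 1
    return up, down


def day_events(loc: GeoLocation, date: date_cls | datetime, cfg: RegimeConfig | None = None) -> DayEvents:
    """Scan a UTC day at 1-min steps for twilight/sunrise/sunset crossings.

    Sunrise is the first upward crossing of the horizon, sunset the last
    downward; twilight start/end are the first upward and last downward
    crossings of the twilight altitude.  Absent crossings leave fields None.
    """
    cfg = cfg or RegimeConfig()
    if isinstance(date, datetime):
        date = date.date()
    times, alts = _minute_grid(loc, date, cfg)

    def _dt(idx: int) -> datetime:
        return pd.Timestamp(times[idx]).to_pydatetime().replace(tzinfo=timezone.utc)

    ev = DayEvents(date=date)
    up0, down0 = _crossings(alts, cfg.horizon_altitude_deg)
    up12, down12 = _crossings(alts, cfg.twilight_altitude_deg)
    if len(up0):
        ev.sunrise = _dt(up0[0])
    if len(down0):
        ev.sunset = _dt(down0[-1])
    if len(up12):
        ev.twilight_start = _dt(up12[0])
    if len(down12):
        ev.twilight_end = _dt(down12[-1])
    return ev


def _minute_states(alts: np.ndarray, cfg: RegimeConfig) -> np.ndarray:
    """Per-minute light state from altitude and local slope.

    Minutes at or above the horizon are day; at or below the twilight
    altitude, night; in between, dawn when the sun is ascending and dusk when
    descending.  ``alts`` has one trailing sample for the closing slope.
    """
    a = alts[:-1]
    rising = np.diff(alts) > 0
    states = np.full(len(a), 3, dtype=np.int8)  # night
    states[a >= cfg.horizon_altitude_deg] = 1  # day
    twil = (a > cfg.twilight_altitude_deg) & (a < cfg.horizon_altitude_deg)
    states[twil & rising] = 0  # dawn
    states[twil & ~rising] = 2  # dusk
    return states


_PRECEDENCE = (0, 2, 1, 3)  # dawn > dusk > day > night


def _hour_labels_for_day(loc: GeoLocation, date: date_cls, cfg: RegimeConfig) -> list[str]:
    _, alts = _minute_grid(loc, date, cfg)
    states = _minute_states(alts, cfg)
    per_hour = 60 // cfg.sampling_minutes
    labels = []
    for h in range(24):
        block = states[h * per_hour : (h + 1) * per_hour]
        present = set(block.tolist())
        code = next(c for c in _PRECEDENCE if c in present)
        labels.append(("dawn", "day", "dusk", "night")[code])
    return labels


def classify_hour(loc: GeoLocation, hour_start: datetime, cfg: RegimeConfig | None = None) -> str:
    """Light-regime label for the UTC hour starting at ``hour_start``."""
    cfg = cfg or RegimeConfig()
    if hour_start.tzinfo is None:
        hour_start = hour_start.replace(tzinfo=timezone.utc)
    hour_start = hour_start.astimezone(timezone.utc)
    labels = _hour_labels_for_day(loc, hour_start.date(), cfg)
    return labels[hour_start.hour]


def classify_series(
    loc: GeoLocation, hours, cfg: RegimeConfig | None = None, with_altitude: bool = False
) -> pd.DataFrame:
    """Classify many UTC hour starts; one label per hour.

    Returns a DataFrame with columns ``utc_hour``, ``regime`` and (optionally)
    ``sun_altitude_midhour_deg``.  Minute grids are computed once per distinct
    date, so long series stay fast.
    """
    cfg = cfg or RegimeConfig()
    idx = pd.to_datetime(list(hours), utc=True)
    if len(idx) == 0:
        cols = {"utc_hour": pd.Series([], dtype="datetime64[ns, UTC]"), "regime": pd.Series([], dtype=object)}
        if with_altitude:
            cols["sun_altitude_midhour_deg"] = pd.Series([], dtype=float)
        return pd.DataFrame(cols)
    cache: dict[date_cls, list[str]] = {}
    labels = []
    for ts in idx:
        d = ts.date()
        if d not in cache:
            cache[d] = _hour_labels_for_day(loc, d, cfg)
        labels.append(cache[d][ts.hour])
    out = pd.DataFrame({"utc_hour": idx, "regime": labels})
    if with_altitude:
        mid = idx + pd.Timedelta(minutes=30)
        out["sun_altitude_midhour_deg"] = np.asarray(solar_altitude(loc, mid))
    return out
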