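"""Hourly ambient-noise metric: 4 s band levels summarised by a low percentile.

Each hour of audio is split into successive non-overlapping 4 s windows; each
window is Fourier transformed (Hann taper, PSD scaling) and the PSD integrated
over 12-40 Hz to give a band level in dB.  The hour's 20th percentile of those
levels is the ambient metric: low enough that windows containing loud nearby
fin whale pulses (which can occupy half the hour during bouts of calling) do
not move it, so it tracks the background rather than the calls.

Levels are relative to full scale; an absolute calibration offset (dB re
1 uPa^2/Hz chain sensitivity) can be added via ``NoiseConfig.calibration_db``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy import signal

from .audio import AudioSegment

__all__ = ["NoiseConfig", "BandLevelSeries", "band_levels", "hourly_percentile", "regime_noise_summary"]


@dataclass(frozen=True)
class NoiseConfig:
    window_s: float = 4.0
    band_low: float = 12.0
    band_high: float = 40.0
    percentile: float = 20.0
    calibration_db: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("require 0 < band_low < band_high")
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must lie in (0, 100)")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")


@dataclass
class BandLevelSeries:
    """One band level per complete window; times are window starts in seconds."""

    times: np.ndarray
    levels_db: np.ndarray
    start_time: object  # UTC datetime of the segment start
    site: str = ""


def band_levels(audio: AudioSegment, cfg: NoiseConfig | None = None) -> BandLevelSeries:
    """Band level for every complete non-overlapping window.

    PSD via Hann-tapered DFT (density scaling, so the integral over frequency
    preserves variance); band power integrates the bins whose centres lie in
    [band_low, band_high]; level = 10 log10(power) + calibration.  A trailing
    partial window is discarded.
    """
    cfg = cfg or NoiseConfig()
    if cfg.band_high > audio.fs / 2:
        raise ValueError(f"band_high {cfg.band_high} Hz above Nyquist {audio.fs / 2} Hz")
    nper = int(round(cfg.window_s * audio.fs))
    if len(audio.data) < nper:
        raise ValueError("audio shorter than one analysis window")
    n_win = len(audio.data) // nper
    x = audio.data[: n_win * nper].reshape(n_win, nper)
    freqs, psd = signal.periodogram(x, fs=audio.fs, window="hann", detrend=False, scaling="density", axis=1)
    df = freqs[1] - freqs[0]
    in_band = (freqs >= cfg.band_low) & (freqs <= cfg.band_high)
    power = psd[:, in_band].sum(axis=1) * df
    levels = 10.0 * np.log10(np.maximum(power, 1e-30)) + cfg.calibration_db
    times = np.arange(n_win) * cfg.window_s
    return BandLevelSeries(times=times, levels_db=levels, start_time=audio.start_time, site=audio.site)


def hourly_percentile(series: BandLevelSeries, cfg: NoiseConfig | None = None) -> pd.DataFrame:
    """Per-hour percentile of the band levels (linear-interpolation definition).

    Returns columns utc_hour, n_windows, p_db.  Hours with no complete window
    are absent from the result; callers flag them as missing.
    """
    cfg = cfg or NoiseConfig()
    if len(series.levels_db) == 0:
        return pd.DataFrame(columns=["utc_hour", "n_windows", "p_db"])
    hour_index = (series.times // 3600).astype(int)
    rows = []
    for h in np.unique(hour_index):
        sel = series.levels_db[hour_index == h]
        rows.append(
            {
                "utc_hour": series.start_time + timedelta(hours=int(h)),
                "n_windows": int(len(sel)),
                "p_db": float(np.percentile(sel, cfg.percentile)),  # linear interpolation
            }
        )
    return pd.DataFrame(rows)


def regime_noise_summary(hourly: pd.DataFrame, level_col: str = "noise_p20_db") -> pd.DataFrame:
    """Per-regime mean/spread of hourly percentile noise levels.

    ``hourly`` must carry ``regime`` and the level column.  Regimes with zero
    hours are omitted.  Raw per-hour values stay in ``hourly`` for plotting.
    """
    df = hourly.dropna(subset=[level_col])
    out = (
        df.groupby("regime", observed=True)[level_col]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out
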