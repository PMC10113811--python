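"""Timestamped audio containers and PCM WAV input/output.

A moored acoustic recorder produces one WAV file per hour; :class:`AudioSegment`
is the in-memory unit that every detection and noise stage consumes.  Samples
are stored as float64 on a full-scale of +-1.0 regardless of the integer depth
on disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioSegment", "read_wav", "write_wav", "hour_filename", "parse_hour_filename"]

_FNAME_RE = re.compile(r"^(?P<site>.+)_(?P<stamp>\d{8}T\d{2})\.wav$")


@dataclass
class AudioSegment:
    """Mono waveform with sample rate, UTC start time and site metadata."""

    data: np.ndarray
    fs: float
    start_time: datetime
    site: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 1:
            raise ValueError(f"expected mono audio, got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.replace(tzinfo=timezone.utc)

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return len(self.data) / self.fs

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.duration)

    def time_axis(self) -> np.ndarray:
        return np.arange(len(self.data)) / self.fs


def hour_filename(site: str, start: datetime) -> str:
    """``<site>_<YYYYMMDDTHH>.wav`` naming for one-hour files."""
    return f"{site}_{start.strftime('%Y%m%dT%H')}.wav"


def parse_hour_filename(name: str) -> tuple[str, datetime]:
    """Recover site and UTC hour start from a filename; raises on mismatch."""
    m = _FNAME_RE.match(Path(name).name)
    if m is None:
        raise ValueError(f"filename {name!r} does not match <site>_<YYYYMMDDTHH>.wav")
    stamp = datetime.strptime(m.group("stamp"), "%Y%m%dT%H")
    return m.group("site"), stamp.replace(tzinfo=timezone.utc)


def write_wav(path: str | Path, segment: AudioSegment) -> Path:
    """Write PCM-16 mono WAV.  Samples beyond +-1 full scale raise."""
    peak = float(np.max(np.abs(segment.data))) if len(segment.data) else 0.0
    if peak > 1.0:
        raise ValueError(f"waveform peak {peak:.3f} exceeds full scale; rescale before writing")
    pcm = np.round(segment.data * 32767.0).astype(np.int16)
    path = Path(path)
    wavfile.write(path, int(round(segment.fs)), pcm)
    return path


def read_wav(path: str | Path, start_time: datetime | None = None, site: str | None = None) -> AudioSegment:
    """Read a mono PCM WAV (16/24/32-bit int or float) to full-scale float64.

    Start time and site default to values parsed from the
    ``<site>_<YYYYMMDDTHH>.wav`` filename convention when not supplied.
    """
    path = Path(path)
    fs, raw = wavfile.read(path)
    if raw.ndim != 1:
        raise ValueError(f"{path.name}: expected mono audio, got {raw.shape[1]} channels")
    if raw.dtype == np.int16:
        data = raw / 32768.0
    elif raw.dtype == np.int32:
        data = raw / 2147483648.0
    elif raw.dtype in (np.float32, np.float64):
        data = raw.astype(np.float64)
    elif raw.dtype == np.uint8:
        data = (raw.astype(np.float64) - 128.0) / 128.0
    else:
        raise ValueError(f"{path.name}: unsupported sample format {raw.dtype}")
    if start_time is None or site is None:
        try:
            fsite, fstart = parse_hour_filename(path.name)
        except ValueError:
            fsite, fstart = "", datetime(1970, 1, 1, tzinfo=timezone.utc)
        site = site if site is not None else fsite
        start_time = start_time if start_time is not None else fstart
    return AudioSegment(data=np.asarray(data, dtype=np.float64), fs=float(fs), start_time=start_time, site=site)
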