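"""Two-stage automatic detection of fin whale 20 Hz pulses.

Stage one correlates a spectrogram-domain template of the canonical 42->18 Hz
downsweep against the segment's PSD spectrogram (normalised 2-D correlation on
dB values, so scores are comparable across noise levels) and rejects
candidates whose guard-band (out-of-call-band) energy rivals their call-band
energy — the broadband-pulse noise rejection.  Stage two verifies each
surviving candidate in the time domain: the band-passed magnitude envelope
must rise a configurable number of dB above the local background and its
above-half-peak width must look like a ~1 s pulse.

All events — accepted and rejected, with reasons — are returned for audit.
Detection runs on audio decimated to ``SpectrogramParams.fs`` (default
250 Hz); recorder-rate input (e.g. 12 kHz) is FIR-decimated first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .audio import AudioSegment
from .scene import PulseTrainSpec

__all__ = [
    "SpectrogramParams",
    "Spectrogram",
    "Template",
    "DetectorConfig",
    "DetectionEvent",
    "compute_spectrogram",
    "build_template",
    "xcorr_detect",
    "broadband_reject",
    "envelope_verify",
    "detect",
    "events_to_frame",
]


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT parameters; frequency resolution is ``fs / nfft``."""

    fs: float = 250.0
    nfft: int = 256
    window: str = "hann"
    overlap_fraction: float = 0.5
    scaling: str = "density"

    def __post_init__(self) -> None:
        if self.nfft < 2:
            raise ValueError("nfft must be >= 2")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def freq_resolution(self) -> float:
        return self.fs / self.nfft

    @property
    def hop_s(self) -> float:
        return self.nfft * (1.0 - self.overlap_fraction) / self.fs


@dataclass
class Spectrogram:
    """PSD grid: ``psd[i, j]`` is power density at ``freqs[i]``, ``times[j]``."""

    times: np.ndarray
    freqs: np.ndarray
    psd: np.ndarray
    params: SpectrogramParams


@dataclass
class Template:
    """Zero-mean spectrogram-domain kernel tracing the canonical downsweep."""

    kernel: np.ndarray  # (n_rows, n_cols), zero mean
    row_freqs: np.ndarray
    hop_s: float
    band: tuple[float, float]  # call band (f_end, f_start) in Hz


@dataclass(frozen=True)
class DetectorConfig:
    """Stage thresholds.  All values are this toolkit's tunable defaults."""

    xcorr_threshold: float = 0.3
    min_separation_s: float = 7.0  # minimum stereotyped inter-pulse interval
    call_band: tuple[float, float] = (18.0, 42.0)
    guard_band: tuple[float, float] = (50.0, 100.0)
    broadband_ratio_max: float = 0.5
    envelope_band: tuple[float, float] = (15.0, 45.0)
    envelope_snr_min_db: float = 8.0
    envelope_duration_bounds_s: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.min_separation_s <= 0:
            raise ValueError("min_separation_s must be positive")
        if not (self.guard_band[0] >= self.call_band[1] or self.guard_band[1] <= self.call_band[0]):
            raise ValueError("guard band must be disjoint from the call band")


@dataclass
class DetectionEvent:
    """One candidate 20 Hz pulse with per-stage scores and flags."""

    time: float  # pulse onset, seconds from segment start
    xcorr_score: float
    broadband_ratio: float = np.nan
    envelope_snr_db: float = np.nan
    envelope_duration_s: float = np.nan
    accepted: bool = False
    reject_reason: str = "none"  # {none, broadband, envelope_snr, envelope_duration}
    column: int = field(default=-1, repr=False)
    footprint_s: float = field(default=1.5, repr=False)  # template span in time


def compute_spectrogram(audio: AudioSegment, params: SpectrogramParams | None = None) -> Spectrogram:
    """PSD spectrogram with the configured taper; bin spacing = fs/nfft."""
    params = params or SpectrogramParams(fs=audio.fs)
    if len(audio.data) < params.nfft:
        raise ValueError(f"audio ({len(audio.data)} samples) shorter than one {params.nfft}-sample window")
    freqs, times, psd = signal.spectrogram(
        audio.data,
        fs=audio.fs,
        window=params.window,
        nperseg=params.nfft,
        noverlap=int(params.overlap_fraction * params.nfft),
        detrend=False,
        scaling=params.scaling,
        mode="psd",
    )
    return Spectrogram(times=times, freqs=freqs, psd=psd, params=params)


def _to_db(psd: np.ndarray) -> np.ndarray:
    return 10.0 * np.log10(np.maximum(psd, 1e-30))


def build_template(spec: PulseTrainSpec | None = None, params: SpectrogramParams | None = None) -> Template:
    """Spectrogram-domain kernel from a clean rendering of the canonical pulse.

    The unit-amplitude downsweep is rendered, padded, and run through the same
    STFT as the detector; rows are restricted to the call band (+-2 Hz pad),
    pulse-active columns kept, and the patch made zero-mean so that template
    correlation is invariant to spectrogram dB offsets.
    """
    from .scene import generate_pulse

    spec = spec or PulseTrainSpec()
    params = params or SpectrogramParams()
    if (spec.f_start - spec.f_end) < 2 * params.freq_resolution:
        raise ValueError(
            f"frequency resolution {params.freq_resolution:.2f} Hz too coarse to trace "
            f"a {spec.f_start}->{spec.f_end} Hz sweep"
        )
    pulse = generate_pulse(spec, params.fs)
    pad = np.zeros(params.nfft)
    x = np.concatenate([pad, pulse, pad])
    freqs, _, psd = signal.spectrogram(
        x,
        fs=params.fs,
        window=params.window,
        nperseg=params.nfft,
        noverlap=int(params.overlap_fraction * params.nfft),
        detrend=False,
        scaling=params.scaling,
        mode="psd",
    )
    db = _to_db(psd)
    rows = np.flatnonzero((freqs >= spec.f_end - 2.0) & (freqs <= spec.f_start + 2.0))
    patch = db[rows, :]
    active = np.flatnonzero(patch.max(axis=0) >= patch.max() - 20.0)
    patch = np.clip(patch[:, active[0] : active[-1] + 1], patch.max() - 30.0, None)
    kernel = patch - patch.mean()
    if not np.any(kernel):
        raise ValueError("degenerate (all-zero) template kernel")
    return Template(kernel=kernel, row_freqs=freqs[rows], hop_s=params.hop_s, band=(spec.f_end, spec.f_start))


def _normalized_xcorr(spec: Spectrogram, template: Template) -> np.ndarray:
    """Normalised correlation score for every template start column."""
    rows = np.flatnonzero(
        (spec.freqs >= template.row_freqs[0] - 1e-9) & (spec.freqs <= template.row_freqs[-1] + 1e-9)
    )
    A = _to_db(spec.psd[rows, :])
    K = template.kernel
    if A.shape[0] != K.shape[0] or A.shape[1] < K.shape[1]:
        raise ValueError("spectrogram does not cover the template's frequency rows")
    n_pix = K.size
    # K is zero-mean, so patch-mean terms vanish from the numerator
    num = signal.correlate2d(A, K, mode="valid")[0]
    ones = np.ones_like(K)
    s1 = signal.correlate2d(A, ones, mode="valid")[0]
    s2 = signal.correlate2d(A**2, ones, mode="valid")[0]
    var = np.maximum(s2 - s1**2 / n_pix, 0.0)
    denom = np.sqrt(var) * np.linalg.norm(K)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(denom > 1e-12, num / np.maximum(denom, 1e-12), 0.0)
    return np.clip(score, -1.0, 1.0)


def _thin_peaks(peak_cols: np.ndarray, scores: np.ndarray, hop_s: float, min_sep_s: float) -> np.ndarray:
    """Greedy thinning: keep highest score first; exact ties go to earlier time."""
    order = np.lexsort((peak_cols, -scores))
    kept: list[int] = []
    for idx in order:
        if all(abs(peak_cols[idx] - peak_cols[k]) * hop_s >= min_sep_s for k in kept):
            kept.append(idx)
    return np.sort(np.asarray(kept, dtype=int))


def xcorr_detect(spec: Spectrogram, template: Template, config: DetectorConfig | None = None) -> list[DetectionEvent]:
    """Stage 1: template correlation peaks above threshold, thinned to the
    minimum inter-pulse separation."""
    config = config or DetectorConfig()
    score = _normalized_xcorr(spec, template)
    peaks, _ = signal.find_peaks(score, height=config.xcorr_threshold)
    if len(peaks) == 0:
        return []
    keep = _thin_peaks(peaks, score[peaks], template.hop_s, config.min_separation_s)
    events = []
    half_win = spec.params.nfft / (2.0 * spec.params.fs)
    footprint = template.kernel.shape[1] * template.hop_s + 2 * half_win
    for i in keep:
        col = int(peaks[i])
        onset = max(spec.times[col] - half_win, 0.0)
        events.append(
            DetectionEvent(
                time=float(onset), xcorr_score=float(score[peaks[i]]), column=col, footprint_s=footprint
            )
        )
    return events


def broadband_reject(
    spec: Spectrogram, events: list[DetectionEvent], config: DetectorConfig | None = None
) -> list[DetectionEvent]:
    """Stage 2: flag candidates whose guard-band PSD rivals their call-band PSD.

    ``broadband_ratio`` = mean guard-band PSD / mean call-band PSD at the
    event's time columns; zero call-band power counts as infinitely broadband.
    """
    config = config or DetectorConfig()
    lo, hi = config.guard_band
    if hi > spec.freqs[-1] + 1e-9:
        raise ValueError(f"guard band {config.guard_band} outside spectrogram range")
    guard_rows = (spec.freqs >= lo) & (spec.freqs <= hi)
    call_rows = (spec.freqs >= config.call_band[0]) & (spec.freqs <= config.call_band[1])
    for ev in events:
        # average over the template's full time footprint so off-centre
        # correlation peaks still see the offending energy
        lo_t, hi_t = ev.time - 0.25, ev.time + ev.footprint_s + 0.25
        cols = (spec.times >= lo_t) & (spec.times <= hi_t)
        if not np.any(cols):
            cols = np.argmin(np.abs(spec.times - ev.time))
        call = float(spec.psd[np.ix_(np.flatnonzero(call_rows), np.atleast_1d(np.flatnonzero(cols)))].mean())
        guard = float(spec.psd[np.ix_(np.flatnonzero(guard_rows), np.atleast_1d(np.flatnonzero(cols)))].mean())
        ev.broadband_ratio = np.inf if call <= 0 else guard / call
        if ev.broadband_ratio > config.broadband_ratio_max:
            ev.reject_reason = "broadband"
    return events


def _smooth_envelope(audio: AudioSegment, band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=audio.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, audio.data)
    env = np.abs(signal.hilbert(filtered))
    return uniform_filter1d(env, size=max(int(0.1 * audio.fs), 1))


def envelope_verify(
    audio: AudioSegment,
    events: list[DetectionEvent],
    config: DetectorConfig | None = None,
    pulse_duration_s: float = 1.0,
) -> list[DetectionEvent]:
    """Stage 3: time-domain envelope check of surviving candidates.

    Peak envelope within +-1 s of the candidate pulse centre must exceed the
    local background (median of the surrounding 30 s, excluding +-2 s around
    every candidate) by ``envelope_snr_min_db``; the above-half-peak width
    must fall inside ``envelope_duration_bounds_s``.
    """
    config = config or DetectorConfig()
    if config.envelope_band[1] >= audio.fs / 2:
        raise ValueError("envelope band extends beyond Nyquist")
    if not events:
        return events
    env = _smooth_envelope(audio, config.envelope_band)
    n = len(env)
    fs = audio.fs
    t_axis = np.arange(n) / fs
    exclude = np.zeros(n, dtype=bool)
    for ev in events:
        c = ev.time + pulse_duration_s / 2.0
        exclude |= np.abs(t_axis - c) <= 2.0
    if audio.duration < 30.0:
        warnings.warn("segment shorter than the 30 s background window; using whole segment")
    for ev in events:
        if ev.reject_reason != "none":
            continue
        center = ev.time + pulse_duration_s / 2.0
        lo = max(int((center - 1.0) * fs), 0)
        hi = min(int((center + 1.0) * fs) + 1, n)
        peak_idx = lo + int(np.argmax(env[lo:hi]))
        peak = env[peak_idx]
        b_lo = max(int((center - 15.0) * fs), 0)
        b_hi = min(int((center + 15.0) * fs), n)
        bg_mask = ~exclude[b_lo:b_hi]
        bg = np.median(env[b_lo:b_hi][bg_mask]) if np.any(bg_mask) else np.median(env)
        ev.envelope_snr_db = 20.0 * np.log10(peak / bg) if bg > 0 else np.inf
        half = peak / 2.0
        left = peak_idx
        while left > 0 and env[left - 1] >= half:
            left -= 1
        right = peak_idx
        while right < n - 1 and env[right + 1] >= half:
            right += 1
        ev.envelope_duration_s = (right - left + 1) / fs
        if ev.envelope_snr_db < config.envelope_snr_min_db:
            ev.reject_reason = "envelope_snr"
        elif not (
            config.envelope_duration_bounds_s[0] <= ev.envelope_duration_s <= config.envelope_duration_bounds_s[1]
        ):
            ev.reject_reason = "envelope_duration"
        else:
            ev.accepted = True
    return events


def _decimate_to(audio: AudioSegment, target_fs: float) -> AudioSegment:
    """Anti-aliased FIR decimation to the detection rate, in stages of <= 10."""
    q_total = audio.fs / target_fs
    if abs(q_total - round(q_total)) > 1e-9:
        raise ValueError(f"fs {audio.fs} is not an integer multiple of the detection rate {target_fs}")
    q_total = int(round(q_total))
    data = audio.data
    fs = audio.fs
    while q_total > 1:
        q = q_total
        while q > 10:
            for cand in (10, 8, 6, 5, 4, 3, 2):
                if q_total % cand == 0:
                    q = cand
                    break
            else:
                q = q_total
        data = signal.decimate(data, q, ftype="fir", zero_phase=True)
        fs /= q
        q_total //= q
    return AudioSegment(data=data, fs=fs, start_time=audio.start_time, site=audio.site)


def detect(
    audio: AudioSegment,
    config: DetectorConfig | None = None,
    params: SpectrogramParams | None = None,
    template_spec: PulseTrainSpec | None = None,
) -> list[DetectionEvent]:
    """Full detection chain: decimate, correlate, broadband-reject, envelope-verify.

    Returns every candidate with per-stage scores; ``accepted`` marks events
    that passed all stages.
    """
    config = config or DetectorConfig()
    params = params or SpectrogramParams()
    template_spec = template_spec or PulseTrainSpec()
    if audio.fs > params.fs:
        audio = _decimate_to(audio, params.fs)
    spec = compute_spectrogram(audio, params)
    template = build_template(template_spec, params)
    events = xcorr_detect(spec, template, config)
    events = broadband_reject(spec, events, config)
    events = envelope_verify(audio, events, config, pulse_duration_s=template_spec.pulse_duration)
    return events


def events_to_frame(events: list[DetectionEvent], audio: AudioSegment) -> pd.DataFrame:
    """Detections table with absolute UTC times (CSV schema of the detect stage)."""
    rows = [
        {
            "site": audio.site,
            "utc_time": (audio.start_time + timedelta(seconds=ev.time)).isoformat(),
            "time_s": ev.time,
            "xcorr_score": ev.xcorr_score,
            "broadband_ratio": ev.broadband_ratio,
            "envelope_snr_db": ev.envelope_snr_db,
            "accepted": ev.accepted,
            "reject_reason": ev.reject_reason,
        }
        for ev in events
    ]
    cols = ["site", "utc_time", "time_s", "xcorr_score", "broadband_ratio", "envelope_snr_db", "accepted", "reject_reason"]
    return pd.DataFrame(rows, columns=cols)
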