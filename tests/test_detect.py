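"""Detector stages: spectrogram scaling, template matching, broadband
rejection, envelope verification, and the composed chain."""

import collections
from datetime import datetime, timezone

import numpy as np
import pytest
from scipy import signal

from findiel import scene
from findiel.audio import AudioSegment
from findiel.detect import (
    DetectionEvent,
    DetectorConfig,
    SpectrogramParams,
    broadband_reject,
    build_template,
    compute_spectrogram,
    detect,
    envelope_verify,
    xcorr_detect,
)

START = datetime(2014, 3, 1, tzinfo=timezone.utc)


def _segment(data, fs=250.0):
    return AudioSegment(data=data, fs=fs, start_time=START, site="t")


class TestComputeSpectrogram:
    def test_recorder_rate_bin_spacing_rounds_to_059(self):
        """2048-point windows at 1200 Hz give 0.59 Hz resolution (2 d.p.)."""
        params = SpectrogramParams(fs=1200.0, nfft=2048)
        assert round(params.freq_resolution, 2) == 0.59
        rng = np.random.default_rng(0)
        spec = compute_spectrogram(_segment(rng.standard_normal(6000), fs=1200.0), params)
        assert np.diff(spec.freqs)[0] == pytest.approx(1200.0 / 2048)

    def test_all_zero_input_gives_zero_psd(self):
        spec = compute_spectrogram(_segment(np.zeros(2000)))
        assert not np.any(spec.psd)

    def test_white_noise_psd_integrates_to_variance(self):
        rng = np.random.default_rng(1)
        seg = _segment(rng.standard_normal(250 * 600))
        spec = compute_spectrogram(seg)
        total = np.trapezoid(spec.psd.mean(axis=1), spec.freqs)
        assert total == pytest.approx(1.0, rel=0.05)

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrogram(_segment(np.zeros(100)))


class TestBuildTemplate:
    def test_kernel_spans_about_one_second(self):
        tpl = build_template()
        assert tpl.kernel.shape[1] * tpl.hop_s == pytest.approx(1.0, abs=0.8)
        assert tpl.band == (18.0, 42.0)

    def test_kernel_is_zero_mean(self):
        tpl = build_template()
        assert tpl.kernel.mean() == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.norm(tpl.kernel) > 0

    def test_self_match_peaks_at_pulse_onset(self):
        fs = 250.0
        pulse = scene.generate_pulse(scene.PulseTrainSpec(), fs)
        x = np.zeros(int(60 * fs))
        onset = int(31.7 * fs)
        x[onset : onset + len(pulse)] = pulse
        spec = compute_spectrogram(_segment(x))
        events = xcorr_detect(spec, build_template())
        best = max(events, key=lambda e: e.xcorr_score)
        assert best.time == pytest.approx(31.7, abs=2 * spec.params.hop_s)

    def test_coarse_resolution_raises(self):
        with pytest.raises(ValueError, match="resolution"):
            build_template(params=SpectrogramParams(fs=250.0, nfft=16))


class TestXcorrDetect:
    def test_noise_free_pulses_found_at_true_onsets(self):
        fs = 250.0
        train = scene.PulseTrainSpec(ipi_min=15, ipi_max=15, ipi_mode="fixed")
        pulse = scene.generate_pulse(train, fs)
        x = np.zeros(int(160 * fs))
        onsets = 5.0 + np.arange(10) * 15.0
        for t0 in onsets:
            i0 = int(t0 * fs)
            x[i0 : i0 + len(pulse)] += pulse
        spec = compute_spectrogram(_segment(x))
        events = xcorr_detect(spec, build_template())
        assert len(events) == 10
        hop = spec.params.hop_s
        for ev, t0 in zip(sorted(events, key=lambda e: e.time), onsets):
            assert abs(ev.time - t0) <= 2 * hop + 1e-9

    def test_all_zero_spectrogram_yields_no_candidates(self):
        spec = compute_spectrogram(_segment(np.zeros(250 * 60)))
        assert xcorr_detect(spec, build_template()) == []

    def test_close_peaks_thinned_to_higher_score(self):
        fs = 250.0
        p = scene.generate_pulse(scene.PulseTrainSpec(), fs)
        x = np.zeros(int(60 * fs))
        x[int(20 * fs) : int(20 * fs) + len(p)] += p
        x[int(23 * fs) : int(23 * fs) + len(p)] += 0.5 * p  # weaker, 3 s later
        events = xcorr_detect(compute_spectrogram(_segment(x)), build_template())
        assert len(events) == 1
        assert events[0].time == pytest.approx(20.0, abs=1.1)

    def test_scores_bounded(self, pulse_scene_10min):
        seg, _ = pulse_scene_10min
        events = xcorr_detect(compute_spectrogram(seg), build_template())
        assert all(-1.0 <= e.xcorr_score <= 1.0 for e in events)


class TestBroadbandReject:
    def test_in_band_pulse_retained(self, pulse_scene_10min):
        seg, truth = pulse_scene_10min
        spec = compute_spectrogram(seg)
        events = broadband_reject(spec, xcorr_detect(spec, build_template()))
        near_pulse = [
            e for e in events if any(abs(e.time - t) < 1.0 for t in truth.pulse_times)
        ]
        assert near_pulse
        assert np.mean([e.reject_reason == "none" for e in near_pulse]) > 0.9
        assert all(e.broadband_ratio < 0.5 for e in near_pulse if e.reject_reason == "none")

    def test_flat_broadband_click_rejected(self, quiet_noise):
        tr = scene.TransientSpec(rate_per_hour=60, level_db=25)
        seg, truth = scene.render_scene(None, quiet_noise, tr, duration=600.0, seed=44)
        spec = compute_spectrogram(seg)
        events = broadband_reject(spec, xcorr_detect(spec, build_template()))
        near = [e for e in events if any(abs(e.time - t) < 1.0 for t in truth.transient_times)]
        assert near
        assert all(e.reject_reason == "broadband" for e in near)
        assert all(e.broadband_ratio > 0.5 for e in near)

    def test_silent_spectrogram_event_rejected_by_zero_power_rule(self):
        spec = compute_spectrogram(_segment(np.zeros(250 * 60)))
        events = [DetectionEvent(time=30.0, xcorr_score=0.5)]
        out = broadband_reject(spec, events)
        assert out[0].reject_reason == "broadband"
        assert np.isinf(out[0].broadband_ratio)


class TestEnvelopeVerify:
    def test_strong_pulse_accepted(self, quiet_noise):
        train = scene.PulseTrainSpec(snr_db=15.0, ipi_min=60, ipi_max=60, ipi_mode="fixed")
        seg, truth = scene.render_scene(train, quiet_noise, duration=300.0, seed=50)
        events = [DetectionEvent(time=float(t), xcorr_score=0.9) for t in truth.pulse_times]
        out = envelope_verify(seg, events)
        assert all(e.accepted for e in out)
        assert all(e.envelope_snr_db >= 8.0 for e in out)

    def test_candidate_on_pure_noise_rejected(self, noise_scene_10min):
        events = [DetectionEvent(time=t, xcorr_score=0.5) for t in (100.0, 300.0, 500.0)]
        out = envelope_verify(noise_scene_10min, events)
        assert all(e.reject_reason == "envelope_snr" for e in out)

    def test_long_tone_rejected_for_duration(self, quiet_noise):
        seg, _ = scene.render_scene(None, quiet_noise, duration=300.0, seed=51)
        t = seg.time_axis()
        tone = 0.05 * np.sin(2 * np.pi * 25.0 * t) * ((t > 100) & (t < 110))
        seg2 = _segment(seg.data + tone)
        out = envelope_verify(seg2, [DetectionEvent(time=104.0, xcorr_score=0.8)])
        assert out[0].reject_reason == "envelope_duration"
        assert out[0].envelope_duration_s > 2.0

    def test_short_segment_warns_and_still_runs(self, quiet_noise):
        seg, _ = scene.render_scene(None, quiet_noise, duration=20.0, seed=52)
        with pytest.warns(UserWarning, match="background"):
            envelope_verify(seg, [DetectionEvent(time=10.0, xcorr_score=0.5)])


class TestDetectChain:
    def test_determinism(self, pulse_scene_10min):
        seg, _ = pulse_scene_10min
        a = detect(seg)
        b = detect(seg)
        assert [(e.time, e.xcorr_score, e.accepted, e.reject_reason) for e in a] == [
            (e.time, e.xcorr_score, e.accepted, e.reject_reason) for e in b
        ]

    def test_stage_count_conservation(self, pulse_scene_10min):
        seg, _ = pulse_scene_10min
        events = detect(seg)
        counts = collections.Counter(e.reject_reason for e in events)
        n_accepted = sum(e.accepted for e in events)
        assert n_accepted == counts["none"]
        assert len(events) == n_accepted + counts["broadband"] + counts["envelope_snr"] + counts["envelope_duration"]
        assert all(e.reject_reason == "none" for e in events if e.accepted)

    def test_recall_monotone_in_snr(self, quiet_noise):
        """Recall over a seeded ensemble never decreases with pulse SNR."""
        recalls = []
        for snr in (3.0, 9.0, 15.0):
            hits = total = 0
            for seed in (60, 61):
                train = scene.PulseTrainSpec(snr_db=snr, ipi_min=20, ipi_max=20, ipi_mode="fixed")
                seg, truth = scene.render_scene(train, quiet_noise, duration=600.0, seed=seed)
                acc = [e for e in detect(seg) if e.accepted]
                hits += sum(any(abs(e.time - t) < 1.5 for e in acc) for t in truth.pulse_times)
                total += len(truth.pulse_times)
            recalls.append(hits / total)
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] >= 0.95

    def test_recorder_rate_input_is_decimated(self, quiet_noise):
        """12 kHz input is FIR-decimated and detected like native 250 Hz."""
        train = scene.PulseTrainSpec(snr_db=15.0, ipi_min=30, ipi_max=30, ipi_mode="fixed")
        seg, truth = scene.render_scene(train, quiet_noise, duration=120.0, fs=12000.0, seed=70)
        acc = [e for e in detect(seg) if e.accepted]
        assert sum(any(abs(e.time - t) < 1.5 for e in acc) for t in truth.pulse_times) >= 3
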