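"""Synthetic scene generator: pulse shapes, trains, noise calibration,
presence-series marginals and serial dependence."""

from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from findiel import scene
from findiel.noise import NoiseConfig, band_levels


class TestGeneratePulse:
    def test_length_and_sweep_endpoints(self):
        spec = scene.PulseTrainSpec()
        fs = 250.0
        pulse = scene.generate_pulse(spec, fs)
        assert len(pulse) == 250
        # instantaneous frequency from the analytic-signal phase derivative
        phase = np.unwrap(np.angle(signal.hilbert(pulse)))
        inst_f = np.gradient(phase) * fs / (2 * np.pi)
        core = slice(40, 210)  # away from taper edges
        expected = 42.0 - 24.0 * np.arange(250)[core] / fs  # linear 42 -> 18 ramp
        assert np.max(np.abs(inst_f[core] - expected)) < 1.5
        assert np.all(np.diff(inst_f[core]) < 1.0)  # monotone decreasing ramp

    def test_midpoint_instantaneous_frequency_is_30(self):
        pulse = scene.generate_pulse(scene.PulseTrainSpec(), 250.0)
        phase = np.unwrap(np.angle(signal.hilbert(pulse)))
        inst_f = np.gradient(phase) * 250.0 / (2 * np.pi)
        assert inst_f[125] == pytest.approx(30.0, abs=1.0)

    def test_zero_amplitude_is_silent(self):
        pulse = scene.generate_pulse(scene.PulseTrainSpec(), 250.0, amplitude=0.0)
        assert not np.any(pulse)

    def test_sampling_rate_too_low_raises(self):
        with pytest.raises(ValueError, match="[Ss]ampling"):
            scene.generate_pulse(scene.PulseTrainSpec(), fs=60.0)


class TestGeneratePulseTrain:
    def test_fixed_mode_is_arithmetic(self):
        spec = scene.PulseTrainSpec(ipi_min=10.0, ipi_max=10.0, ipi_mode="fixed")
        onsets = scene.generate_pulse_train(spec, 60.0, seed=0)
        assert np.allclose(onsets, [0, 10, 20, 30, 40, 50])

    def test_short_duration_conventions(self):
        spec_fixed = scene.PulseTrainSpec(ipi_min=10, ipi_max=10, ipi_mode="fixed")
        assert np.allclose(scene.generate_pulse_train(spec_fixed, 0.5, seed=0), [0.0])
        # uniform mode may place the first onset beyond a very short duration
        spec_u = scene.PulseTrainSpec()
        onsets = scene.generate_pulse_train(spec_u, 0.5, seed=3)
        assert len(onsets) in (0, 1)

    def test_deterministic_given_seed(self):
        spec = scene.PulseTrainSpec()
        a = scene.generate_pulse_train(spec, 3600.0, seed=5)
        b = scene.generate_pulse_train(spec, 3600.0, seed=5)
        assert np.array_equal(a, b)

    @settings(max_examples=30, derandomize=True)
    @given(
        ipi_min=st.floats(1.0, 20.0),
        spread=st.floats(0.0, 15.0),
        seed=st.integers(0, 2**20),
    )
    def test_every_interval_within_bounds(self, ipi_min, spread, seed):
        spec = scene.PulseTrainSpec(ipi_min=ipi_min, ipi_max=ipi_min + spread)
        onsets = scene.generate_pulse_train(spec, 1800.0, seed=seed)
        assert np.all(np.diff(onsets) >= ipi_min - 1e-9)
        assert np.all(np.diff(onsets) <= ipi_min + spread + 1e-9)
        assert np.all(onsets[:-1] < onsets[1:])


class TestRenderScene:
    def test_noise_only_truth_is_empty(self, quiet_noise):
        _, truth = scene.render_scene(None, quiet_noise, duration=60.0, seed=0)
        assert len(truth.pulse_times) == 0
        assert len(truth.transient_times) == 0

    def test_pulse_count_bookkeeping(self, quiet_noise):
        train = scene.PulseTrainSpec(ipi_min=360.0, ipi_max=360.0, ipi_mode="fixed")
        _, truth = scene.render_scene(train, quiet_noise, duration=3600.0, seed=0)
        assert len(truth.pulse_times) == 10

    def test_reproducible_bit_identical(self, quiet_noise):
        train = scene.PulseTrainSpec()
        a, _ = scene.render_scene(train, quiet_noise, duration=120.0, seed=9)
        b, _ = scene.render_scene(train, quiet_noise, duration=120.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_noise_band_level_matches_spec(self, quiet_noise):
        """Rendered in-band level agrees with the synthesis target within 1 dB."""
        seg, _ = scene.render_scene(None, quiet_noise, duration=600.0, seed=21)
        levels = band_levels(seg, NoiseConfig()).levels_db
        assert np.mean(levels) == pytest.approx(quiet_noise.base_level_db, abs=1.0)

    def test_sloped_noise_band_level_matches_spec(self):
        spec = scene.NoiseSpec(base_level_db=-35.0, spectral_slope_db_per_octave=-3.0)
        seg, _ = scene.render_scene(None, spec, duration=600.0, seed=22)
        levels = band_levels(seg, NoiseConfig()).levels_db
        assert np.mean(levels) == pytest.approx(-35.0, abs=1.0)

    def test_pulse_snr_calibration_within_1db(self, quiet_noise):
        """Realised in-band pulse SNR tracks snr_db within 1 dB."""
        fs, snr = 250.0, 12.0
        train = scene.PulseTrainSpec(snr_db=snr, ipi_min=30, ipi_max=30, ipi_mode="fixed")
        seg, truth = scene.render_scene(train, quiet_noise, duration=600.0, fs=fs, seed=31)
        clean, _ = scene.render_scene(None, quiet_noise, duration=600.0, fs=fs, seed=31)
        pulse_only = seg.data - clean.data
        # ambient in-band power by direct PSD integration over the pulse band
        f, psd = signal.welch(clean.data, fs=fs, nperseg=4096, detrend=False)
        amb_pow = np.trapezoid(psd[(f >= 18) & (f <= 42)], f[(f >= 18) & (f <= 42)])
        realised = []
        for t0 in truth.pulse_times[1:-1]:
            i0 = int(t0 * fs)
            p = np.mean(pulse_only[i0 : i0 + int(fs)] ** 2)
            realised.append(10 * np.log10(p / amb_pow))
        assert np.mean(realised) == pytest.approx(snr, abs=1.0)

    def test_clipping_raises_amplitude_error(self):
        loud = scene.NoiseSpec(base_level_db=10.0)
        with pytest.raises(ValueError, match="full scale"):
            scene.render_scene(None, loud, duration=10.0, seed=0)

    def test_diel_modulation_changes_hourly_levels(self):
        spec = scene.NoiseSpec(diel_amplitude_db=6.0, diel_phase_hours=12.0)
        start = datetime(2014, 3, 1, 0, tzinfo=timezone.utc)
        seg_night, _ = scene.render_scene(None, spec, start_time=start, duration=600.0, seed=4)
        seg_day, _ = scene.render_scene(
            None, spec, start_time=start.replace(hour=12), duration=600.0, seed=4
        )
        ln = np.mean(band_levels(seg_night, NoiseConfig()).levels_db)
        ld = np.mean(band_levels(seg_day, NoiseConfig()).levels_db)
        assert ld - ln == pytest.approx(6.0, abs=1.0)


class TestPresenceSeries:
    def test_marginal_rate_half_when_all_zero(self):
        spec = scene.PresenceSeriesSpec(ar1_rho=0.0, n_days=420, seed=0)  # 10080 hours
        df = scene.generate_presence_series(spec)
        n = len(df)
        se = np.sqrt(0.25 / n)
        assert abs(df["presence"].mean() - 0.5) < 3 * se

    def test_per_regime_marginal_calibration(self):
        """Empirical per-regime rates match logistic(intercept + effect)."""
        from scipy.special import expit

        eff = {"dawn": 0.5, "day": -1.0, "dusk": 0.0, "night": 1.0}
        spec = scene.PresenceSeriesSpec(
            regime_logit_effects=eff, intercept_logit=-0.2, ar1_rho=0.6, n_days=900, seed=2
        )
        df = scene.generate_presence_series(spec)
        for regime, grp in df.groupby("regime"):
            p = expit(-0.2 + eff[regime])
            se = np.sqrt(p * (1 - p) / len(grp))
            # AR1 dependence inflates the standard error; use a generous factor
            assert abs(grp["presence"].mean() - p) < 6 * se

    def test_large_negative_intercept_all_absent(self):
        spec = scene.PresenceSeriesSpec(intercept_logit=-30.0, n_days=10, seed=0)
        assert scene.generate_presence_series(spec)["presence"].sum() == 0

    def test_ar1_raises_binary_autocorrelation(self):
        base = dict(n_days=300)
        y0 = scene.generate_presence_series(scene.PresenceSeriesSpec(ar1_rho=0.0, seed=5, **base))["presence"]
        y8 = scene.generate_presence_series(scene.PresenceSeriesSpec(ar1_rho=0.8, seed=5, **base))["presence"]

        def lag1(y):
            y = np.asarray(y, dtype=float)
            return np.corrcoef(y[:-1], y[1:])[0, 1]

        assert lag1(y8) > 0.3
        assert lag1(y8) > lag1(y0)

    def test_missing_regime_level_raises(self):
        spec = scene.PresenceSeriesSpec(regime_logit_effects={"day": 0.0}, n_days=1, seed=0)
        with pytest.raises(ValueError, match="missing"):
            scene.generate_presence_series(spec, regimes=["day", "night"])

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            scene.PulseTrainSpec(f_start=10.0, f_end=20.0)
        with pytest.raises(ValueError):
            scene.PulseTrainSpec(ipi_min=5.0, ipi_max=2.0)
        with pytest.raises(ValueError):
            scene.PresenceSeriesSpec(ar1_rho=1.0)
        with pytest.raises(ValueError):
            scene.NoiseSpec(diel_amplitude_db=-1.0)
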