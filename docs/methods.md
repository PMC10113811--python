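# Methods

This note documents the models and conventions behind `findiel`: what each
stage computes, the assumptions it makes, the tunable parameters and their
defaults, and what the synthetic-data tests do and do not demonstrate.

## Synthetic acoustic scenes

The generator emulates the statistical structure of long-term hydrophone
recordings that matter to the downstream stages, not ocean physics.

**Pulses.** The 20 Hz fin whale pulse is modelled as a linear downsweep,
42 → 18 Hz over 1.0 s (backbeat variant 23 → 13 Hz), under a Tukey window
with 25 % taper. The linear sweep law and the Tukey envelope are modelling
conventions: the field literature specifies the band and duration of the
call but not its within-pulse envelope, and the taper merely limits spectral
splatter. Trains use either a fixed inter-pulse interval (first onset at 0)
or intervals drawn uniformly from [ipi_min, ipi_max] (defaults 7–26 s) with
the first onset uniform in [0, ipi_max).

**Ambient noise.** Gaussian noise is synthesised in the frequency domain
with a power-law PSD (slope in dB/octave, default 0), normalised so the
integral over the 12–40 Hz analysis band equals `base_level_db`
(default −40 dB re full scale² — leaving PCM-16 headroom for 25 dB
transients). A diel cycle is a slowly varying gain: a 24 h cosine with
peak-to-trough `diel_amplitude_db` peaking at `diel_phase_hours` UTC.

**SNR convention.** A pulse inserted at `snr_db` has mean-square level over
its duration equal to the ambient power integrated over the pulse's own band
(including the diel gain at that instant) times 10^(snr/10). Tests verify
the realised in-band SNR lands within 1 dB.

**Broadband transients.** Confusers for the detector's noise-rejection stage
are 0.2 s windowed linear sweeps spanning 10–120 Hz. A deterministic sweep
(rather than a filtered-noise burst) is used because a 0.2 s noise burst has
large realisation-to-realisation spectral variance — individual bursts can
come out call-band-heavy, which contradicts the confuser's defining property
of covering the full analysis band. `level_db` (default 20) scales the
burst's total power relative to ambient in-band power.

**Presence series.** Hourly binary presence uses a Gaussian copula: a latent
standard-normal AR1 series z_t with coefficient ρ is thresholded at the
normal quantile of p_t = logistic(intercept + effect[regime(t)]). Marginals
are therefore *exact* at any ρ while lag-1 dependence is tunable; the binary
series' autocorrelation is an attenuated function of ρ (e.g. ρ = 0.6 yields
working-correlation estimates near 0.4), which is why tests assert
monotonicity of the estimated α in ρ rather than equality.

What the generator does **not** emulate: propagation loss and multipath,
source-level and IPI drift within bouts, seasonal call-rate structure,
chorusing (overlapping distant whales), ice noise spectra, or recorder
self-noise. Passing detection tests on these scenes demonstrates the
detector logic operates as designed at known SNR, not field performance on
Antarctic recordings.

## Pulse detection

Detection runs at 250 Hz. Recorder-rate input (e.g. 12 kHz) is decimated by
zero-phase FIR stages of factor ≤ 10; the anti-alias transition band sits
above the 50–100 Hz guard band.

1. **Spectrogram**: Hann window, nfft 256 (≈ 1 Hz resolution), 50 % overlap
   (≈ 0.51 s hop), PSD scaling. (The recorder-rate *display* convention of
   2048-point Hann windows at 1200 Hz, 0.59 Hz resolution, is represented in
   `SpectrogramParams` but detection uses the decimated grid.)
2. **Template correlation**: the kernel is the dB spectrogram of a clean
   unit pulse, restricted to the call band ± 2 Hz, clipped 30 dB below its
   peak, and made zero-mean — so correlation is invariant to absolute dB
   offset. Scores are normalised 2-D correlations in [−1, 1]; local maxima
   above `xcorr_threshold` (0.3) are thinned greedily by descending score
   (ties: earlier time) to a minimum separation of 7 s, the shortest
   stereotyped IPI.
3. **Broadband rejection**: `broadband_ratio` = mean guard-band PSD
   (50–100 Hz) over the template's full time footprint divided by mean
   call-band PSD (18–42 Hz) there. Ratios above 0.5 flag `broadband`; zero
   call-band power counts as infinitely broadband. The footprint (not a
   fixed ± 1 s) matters because a correlation peak can sit at the kernel
   edge, a template-width away from the offending energy.
4. **Envelope verification**: band-pass 15–45 Hz (4th-order Butterworth,
   zero-phase), Hilbert magnitude envelope smoothed over 0.1 s. The peak
   within ± 1 s of the candidate pulse centre must exceed the local
   background (median of the surrounding 30 s, excluding ± 2 s around every
   candidate) by ≥ 8 dB, and the above-half-peak width must lie in
   [0.5, 2] s. Segments shorter than the background window fall back to the
   whole segment with a warning.

All thresholds are this package's defaults, exposed in `DetectorConfig`;
none are claimed to reproduce any particular historical detector. Every
candidate is returned with its stage scores and reject reason for audit.
At the defaults, seeded scenes give recall ≥ 0.95 at 12 dB SNR with ≤ 2
accepted false alarms per noise-only hour, and ≥ 90 % of transient-triggered
candidates flagged broadband (the acceptance suite re-measures these).

## Light regimes

Solar altitude is geometric (no refraction), from the NOAA/Meeus
low-precision algorithm (declination + equation of time from the Julian
century), valid 1900–2100; tests hold it within 0.2° of an independently
implemented Michalsky almanac routine. All clocks are UTC: recorder
timestamps are absolute and solar altitude is a function of UTC instants,
so no local-time convention is needed.

Each UTC date is scanned at 1-min steps. Events: sunrise = first upward
0°-crossing, sunset = last downward; twilight start/end = first upward /
last downward −12°-crossings; absent crossings leave events absent (polar
cases). Hour labels come from per-minute light states — day at or above the
horizon, night at or below −12°, otherwise dawn while the sun ascends and
dusk while it descends — with hour-level precedence dawn > dusk > day >
night over the minutes of the hour. This realises the interval rules
(dawn = twilight-start through sunrise, day strictly between, dusk = sunset
through twilight-end) including the promotion of the whole hour containing
sunrise/sunset, and extends them deterministically to the polar cases:
all-day sun → day; sun never above −12° → night; sun confined to the
twilight band → dawn before the altitude maximum, dusk after. The one
boundary convention worth noting: an event falling exactly on an hour
boundary at 1-min resolution promotes the hour *before* the boundary (which
contains the approach minutes), not the hour after.

## Ambient-noise metric

Hourly audio is cut into non-overlapping 4 s windows (trailing partial
window dropped; 900 windows per complete hour). Each window's PSD uses a
Hann taper with density scaling (so the frequency integral preserves
variance); band power integrates the bins whose centres lie in
[12, 40] Hz; level = 10·log10(power), relative to full scale (an absolute
calibration offset is a config field). The hour's statistic is the 20th
percentile under the linear-interpolation definition of percentiles — both
the taper and the interpolation rule are pinned here because they are
otherwise common sources of cross-implementation drift. A low percentile is
used precisely so that loud nearby pulses — which can occupy half the
windows during a calling bout — leave the statistic within 0.5 dB of the
pulse-free value; the acceptance suite verifies this and the pure-tone
Parseval closed form (unit 25 Hz sinusoid → −3.01 dB) to 0.3 dB.

## Presence aggregation

Presence is binary per hour ([h, h+1) half-open; boundary events belong to
the later hour), regardless of pulse count. Detection days are UTC calendar
dates with ≥ 1 presence hour per site; conditioning preserves presence
hours. The presence matrix is a 366 × 24 count grid summed over years. Per
detection day and regime, the presence proportion divides presence hours in
the regime by the regime's hour count that day (default): at high latitude
regime durations are grossly unequal (night can last 2 h in March), and
this denominator keeps regimes comparable. The alternative — dividing by
the day's total presence hours — is available as
`denominator="presence_hours"`. Days on which a regime does not occur
contribute nothing to that regime's mean; means and standard errors are
across contributing detection days.

## GEE estimation

The marginal model is binomial with logit link; clusters are detection days
with observations ordered by hour (the conditioning defines no other
grouping unit), and the working correlation is AR1 on the hour index, so
hours missing from a day widen the correlation as α^gap. Fitting iterates:

1. Pearson residuals r_t = (y_t − μ_t)/√(μ_t(1−μ_t)) at the current β;
2. moment update α̂ = Σ r_t r_{t+1} / ((K₁ − p)·φ̂) over within-cluster
   lag-1 pairs (K₁ pairs, p parameters, φ̂ the Pearson scale), clipped to
   (−0.99, 0.99);
3. the estimating-equation step β ← β + (Σ Dᵢᵀ Vᵢ⁻¹ Dᵢ)⁻¹ Σ Dᵢᵀ Vᵢ⁻¹ (yᵢ−μᵢ)
   with V_i = A_i^{1/2} R(α) A_i^{1/2}, solved per cluster by dense solves
   (clusters are ≤ 24 hours, so closed-form tridiagonal inverses buy
   nothing).

Convergence is a relative coefficient change below 1e-8 (cap 100
iterations), with step-halving against runaway steps; a constant response
or diverging coefficients raise an informative separation error. The
reported covariance is the robust sandwich B⁻¹MB⁻¹. Under an independence
working correlation the solution coincides with the pooled logistic MLE,
which the tests verify to 1e-6 against a hand-rolled Newton solver and
against the statsmodels GEE implementation (used strictly as a
cross-check, never as the fitter).

**Design choices where the convention was open.** The noise covariate
enters as regime-specific slopes (noise × regime interaction only, noise
mean-centred) — a full-rank reparameterisation of main-effect-plus-
interaction that directly reads as "the effect of noise in each light
regime" and leaves regime contrasts at mean noise equal to the dummy
differences. The reference level is night. Pairwise contrasts are reported
unadjusted at α = 0.05 (a Holm option exists, off by default). The compact
letter display assigns one letter per maximal clique of the
non-significance graph, so two regimes share a letter exactly when their
contrast is non-significant — verified by brute force over all 64
significance patterns on four levels.

**Diagnostics.** Durbin–Watson is pooled across clusters (numerators of
within-cluster successive differences summed over clusters, divided by the
total residual sum of squares), range [0, 4], ≈ 2 under independence; the
ACF is the standard biased sample estimator with r₀ = 1.

## Problem sizes used in the test and acceptance runs

Scenes are one hour at 250 Hz for detector operating-point measurements
(one 240-pulse hour, three noise-only hours, two transient hours) and
600 s for unit tests; the light-regime sweep covers 50 sites × 20 dates
including the poles; parameter recovery uses 200 replicates of 500-day
series (ρ = 0.6) and a 400-day series per ρ ∈ {0, 0.3, 0.6, 0.9}; the
end-to-end pipeline test simulates 48 hourly WAVs. These sizes make the
Monte-Carlo assertions stable at the stated tolerances while keeping the
default suite fast.

## Known limitations

- The detector is a functional implementation of the described stages, not
  a re-creation of any specific operational detector; manual review passes
  of the field workflow are out of scope.
- Noise levels are relative to digital full scale; absolute dB re 1 µPa
  requires an external calibration offset.
- The solar classifier's 1-min sampling means event times (and hence hour
  promotions) carry ± 1 min quantisation; altitudes at flagged twilight
  starts lie in [−12.5, −11.5]°.
- The GEE assumes presence hours are missing-at-random within detection
  days; systematic duty-cycle gaps would need the time index extended.
- Letter displays can require more than 26 letters only for many-level
  factors; with the four light regimes the maximum is four.
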