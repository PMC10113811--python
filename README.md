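# findiel

Diel (24 h) patterns in fin whale (*Balaenoptera physalus*) 20 Hz acoustic
presence, from raw hydrophone audio to statistics.

Fin whales produce a highly stereotyped ~1 s pulse sweeping from 42 Hz down to
18 Hz, repeated every 7–26 s, sometimes with a lower "backbeat" (23→13 Hz).
Long-term moored recorders log one WAV file per hour for months; the
scientific questions are *when* (by hour, by light regime) the whales are
acoustically present, and whether apparent diel patterns are artefacts of
diel cycles in ambient noise (and hence detection range). `findiel`
implements the full computational chain as a tested, reusable library and
CLI:

1. **Synthetic scenes** (`findiel.scene`) — pulse trains, coloured ambient
   noise with optional diel level cycles, and broadband transient confusers,
   rendered into hourly WAVs with exact ground truth, so every downstream
   stage is testable without any recordings.
2. **Pulse detection** (`findiel.detect`) — spectrogram cross-correlation
   against a template of the canonical downsweep, broadband-noise rejection
   (guard-band vs call-band energy), then time-domain envelope verification.
3. **Light regimes** (`findiel.solar`) — geometric solar altitude (NOAA/Meeus
   algorithm) at 1-min steps assigns every UTC hour to dawn, day, dusk or
   night using the nautical-twilight (−12°) and horizon (0°) crossings; the
   entire hour containing sunrise/sunset counts as dawn/dusk. Polar day,
   polar night and all-twilight days are handled explicitly.
4. **Ambient noise** (`findiel.noise`) — non-overlapping 4 s windows, PSD
   integrated over 12–40 Hz, summarised per hour by the 20th percentile: a
   noise metric deliberately insensitive to loud intermittent calls.
5. **Presence aggregation** (`findiel.aggregate`) — binary hourly presence,
   conditioning on *detection days* (days with ≥ 1 presence hour),
   day-of-year × hour presence matrices, per-regime presence proportions.
6. **Diel statistics** (`findiel.gee`) — a marginal logistic model of hourly
   presence estimated by generalized estimating equations.

## The statistical model

For hour *t* of detection day *i*, presence Y_it ∈ {0, 1} follows

    logit P(Y_it = 1) = β₀ + β_regime(it) + γ_regime(it) · (noise_it − mean noise)

with the four-level light-regime factor (night as reference), optional
regime-specific ambient-noise slopes γ, and hours within a detection day
forming a cluster with AR1 working correlation corr(e_t, e_s) = α^|t−s|.
α is re-estimated from lag-1 Pearson residual products each iteration, and
inference uses the robust (sandwich) covariance, so standard errors remain
valid if the AR1 structure is wrong. Pairwise regime contrasts (Wald tests
at α = 0.05, evaluated at mean noise) are summarised as a compact letter
display; Durbin–Watson and ACF diagnostics assess residual serial
correlation.

The API follows the model/results convention: build `PresenceGEE` from a
detection-day table (`PresenceGEE.from_dataframe`), call `.fit()`, and read
`params`, `bse`, `contrasts()`, `letters()`, `durbin_watson()`, `acf()` and
`summary()` off the results object.

## Worked example

```python
import numpy as np
from findiel import scene, fit_gee
from findiel.aggregate import detection_days, regime_proportions
from findiel.detect import detect

# 10 minutes of synthetic ocean with 20 Hz pulses at 12 dB SNR
train = scene.PulseTrainSpec(snr_db=12.0)
seg, truth = scene.render_scene(train, scene.NoiseSpec(), duration=600.0, seed=0)
acc = [e for e in detect(seg) if e.accepted]
print(f"true pulses: {len(truth.pulse_times)}, accepted detections: {len(acc)}")

# 300 days of hourly presence with night-biased calling and AR1 dependence
spec = scene.PresenceSeriesSpec(
    regime_logit_effects={"dawn": 0.3, "day": -0.8, "dusk": 0.2, "night": 0.8},
    intercept_logit=-0.3, ar1_rho=0.6, n_days=300, seed=1)
dd, totals = detection_days(scene.generate_presence_series(spec))
print(regime_proportions(dd).round(3).to_string(index=False))
res = fit_gee(dd)
print(res.summary())
print("letters:", res.letters())
```

prints

```
true pulses: 38, accepted detections: 37
regime  mean_proportion    se  n_days
  dawn            0.492 0.022     300
   day            0.258 0.010     300
  dusk            0.486 0.022     300
 night            0.611 0.015     300
Binomial GEE (logit link), working correlation: ar1
n_obs = 7200, clusters = 300, converged = True in 5 iterations
AR1 alpha = 0.3917, scale = 1.0026

term                  coef    rob.se       z    P>|z|      [95%       CI]
intercept           0.4649    0.0636    7.31   0.0000    0.3403    0.5895
regime[dawn]       -0.5288    0.0904   -5.85   0.0000   -0.7060   -0.3517
regime[day]        -1.5287    0.0786  -19.44   0.0000   -1.6828   -1.3745
regime[dusk]       -0.5116    0.0926   -5.53   0.0000   -0.6931   -0.3302

Durbin-Watson (pooled within clusters): 1.165
letters: {'dawn': 'a', 'day': 'b', 'dusk': 'a', 'night': 'c'}
```

The regime coefficients are logit differences from night: calling is most
likely at night, least likely in daytime (true night−day difference here is
1.6; estimated 1.53 ± 0.08), dawn and dusk are intermediate and mutually
indistinguishable (shared letter "a"). The working-correlation estimate
α ≈ 0.39 reflects the latent serial dependence (generator ρ = 0.6 on the
latent scale attenuates on the binary scale); the Durbin–Watson value well
below 2 shows the serial correlation the AR1 structure is there to absorb.

## Command line

```sh
findiel simulate --config cfg.yaml --out data/     # hourly WAVs + truth
findiel detect data/*.wav --out detections.csv
findiel classify --lat -62.38 --lon 81.80 --start 2014-02-10 --end 2014-04-21 --out regimes.csv
findiel noise data/*.wav --out noise.csv
findiel fit detection_days.csv --out report.json
findiel run --config cfg.yaml --out run/           # full chain + manifest
findiel validate data/*.wav hourly.csv
```

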