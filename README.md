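# respiradar

Contactless respiratory-rate-variability analysis for continuous-wave (CW)
Doppler radar, built around small-animal monitoring under anesthesia. A
24 GHz CW radar senses millimetre-scale chest-wall displacement without
touching the animal; this package provides everything needed to develop and
validate that measurement chain on the desk:

- **`radar_model`** — a physics-based simulator. Given a ground-truth
  breathing scenario (piecewise-constant rate schedule, cycle-to-cycle
  jitter, raised-cosine chest excursion of order 1 mm), it produces the
  quadrature baseband channels

  ```
  I(t) = A(t) sin(4π(d(t)+d₀)/λc + ∅),   Q(t) = A(t) cos(4π(d(t)+d₀)/λc + ∅)
  ```

  with carrier wavelength λc (default 24.15 GHz), standoff d₀, residual
  phase ∅, additive Gaussian channel noise, 1,092 Hz sampling and 10-bit ADC
  quantization — plus a co-registered laser-style displacement reference.
- **`pipeline`** — the instantaneous-rate estimator: 3.3 Hz zero-phase
  low-pass (radar channels only), breath-peak detection, per-interval
  frequency `f(t_l) = 1/(t_{l+1} − t_l)`, an interval-consistency quality
  index `q = exp(−(|ln α| + |ln β|)) ∈ (0, 1]`, removal of low-quality
  points, interpolation to a uniform grid, and `bpm = 60 f`. Channel
  selection (I vs Q) by mean quality handles operating-point nulls.
- **`stats`** — method-comparison statistics (Bland–Altman mean difference
  and 95 % limits of agreement, Pearson r, RMSE, MAPE) and anesthesia-depth
  group comparison (Kruskal–Wallis with Dunn post-hoc, Holm-adjusted).
- **`io` / CLI** — manifest-driven CSV reading for recorded data, synthetic
  fixture generation, and `simulate / analyze / validate / compare-groups`
  commands.

Intended users: groups building or evaluating non-contact vital-sign
sensors, and anyone needing a reproducible benchmark for breath-interval
signal-quality cleaning.

## Worked example

```bash
$ respiradar simulate --preset steady60 --seed 1 -o demo
wrote synthetic recording 'steady60' (seed 1) to demo

$ respiradar analyze --manifest demo/manifest.yaml -o demo_rates
channel Q: mean 59.8 bpm, median 59.9 bpm, mean quality 0.98

$ respiradar validate --manifest demo/manifest.yaml --no-plots -o demo_val
                                                value
Root mean square error (RMSE) [bpm]          0.166280
Mean absolute percentage error (MAPE) [%]    0.228029
Correlation coefficient                      0.989314
95% limit of agreement low [bpm]            -0.328187
95% limit of agreement high [bpm]            0.326423
Mean difference [bpm]                       -0.000882
Number of pairs                            117.000000
```

The `steady60` preset is two minutes of breathing at 60 bpm (±2 bpm
cycle jitter) with 5 %-of-amplitude channel noise. `analyze` ran the full
pipeline on both radar channels and kept the higher-quality one (Q here),
recovering the programmed rate to 0.2 bpm with near-perfect quality.
`validate` re-analyzed the same motion through the laser-style displacement
reference and paired the two rate series at 1 Hz: mean radar-vs-reference
difference −0.001 bpm with 95 % limits of agreement ±0.33 bpm — the radar
path and the direct displacement measurement see the same breathing.

The `isoflurane_step` preset emulates a four-level anesthesia protocol
(isoflurane 1.7 → 1.3 → 2.1 → 0.9 % at 8-min intervals, respiratory rates
near 90/85/55/80 bpm); `respiradar compare-groups` on it reproduces the
expected depth effect (deep anesthesia depresses the rate; Kruskal–Wallis
p ≪ 0.001 with Dunn stars per level pair).

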