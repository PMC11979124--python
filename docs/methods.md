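# Methods

## Measurement model

A CW radar at carrier frequency f_c (default 24.15 GHz, the midpoint of the
licence-free 24.05–24.25 GHz band; λc = c/f_c ≈ 12.4 mm) illuminates the
chest wall at nominal distance d₀. Quadrature demodulation of the
reflection gives two baseband channels,

    I(t) = A(t) sin θ(t),  Q(t) = A(t) cos θ(t),
    θ(t) = (4π/λc)(d(t) + d₀) + ∅,

with d(t) the chest displacement and ∅ the residual phase accumulated in
antennas, wiring and mixers. Because the phase swing of ~1 mm motion is
about 1 rad at 24 GHz, each channel is a (generally nonlinear) projection of
d(t); the static phase θ₀ = (4π/λc)d₀ + ∅ sets each channel's operating
point. Near θ₀ ≈ 0 (mod π) the I channel is in its linear region and Q is
near a null, and vice versa — which is why both channels are simulated and
the pipeline chooses between them.

The acquisition chain is modelled as additive Gaussian noise on each
channel (sd `noise_sd`, default 0.05 in units of the amplitude A = 1)
followed by a mid-rise uniform ADC: 10 bits over ±(A + 4·noise_sd). The
full-scale rule keeps clipping below ~3×10⁻⁵ per sample while using most of
the code range; level centres map to themselves so quantization is
idempotent. Sampling is 1,092 Hz.

`residual_phase_phi=None` draws ∅ uniformly from [0, 2π) per seed, so
ensembles of simulations cover all operating points reproducibly.

## Breathing-scenario generator

Ground truth is a piecewise-constant rate schedule (durations × rates in
bpm). Cycles are laid down sequentially; each cycle's rate is drawn
N(segment rate, `rate_jitter_sd`) truncated at 20 % of nominal, the
simplest model of cycle-to-cycle variability (default sd 2 bpm, a realistic
few-percent variability for an anesthetized rat breathing 50–100 bpm).
Within a cycle the excursion is a raised cosine scaled to
`displacement_amplitude` peak-to-peak (default 1 mm — chest-wall motion is
of millimetre order in rats; the true value is animal- and
posture-dependent, so it is a parameter, not a constant). `inhale_fraction`
skews the cycle; a plain sinusoid mode exists as the degenerate case.
Optional white displacement noise emulates reference-sensor noise.

What the generator does **not** emulate: cardiac motion, gross body
movement, RF clutter/multipath, amplitude fading beyond a slow drift, and
apnea. Passing tests therefore demonstrate correctness of the estimator on
clean quasi-periodic motion with realistic noise and quantization — not
robustness to motion artifacts in real recordings.

### Protocol presets

`isoflurane_step` is a four-level anesthesia protocol — 8 min each at
rates 90, 85, 55, 80 bpm, labelled with isoflurane concentrations
1.7/1.3/2.1/0.9 % (deeper anesthesia depresses breathing).
`rat_a_response` is the same protocol with within-level adaptation at the
baseline: the first 5 % of the 1.7 % level runs at 90 bpm before settling
at 85 bpm, so the 1.7 and 1.3 levels have nearly identical rate
distributions. That adaptation is what makes the baseline-vs-1.3 contrast
statistically indistinguishable, the pattern observed in vivo; with
strictly constant 90-vs-85 segments any rank test at realistic sample
sizes separates them.

## Rate pipeline

1. **Low-pass 3.3 Hz** (radar channels only; the displacement reference
   bypasses it). 4th-order Butterworth applied forward–backward, so
   attenuation is doubled and group delay is zero — peak times are not
   shifted. 3.3 Hz passes breathing fundamentals up to ~200 bpm and
   rejects cardiac components and wideband noise.
2. **Peak detection**: strict local maxima with minimum spacing 0.25 s
   (caps the detectable rate at 240 bpm) and minimum prominence 0.3× the
   MAD-based robust sd of the filtered signal (adapts to modulation depth,
   immune to outliers). Both configurable.
3. **Instantaneous frequency** f(t_l) = 1/(t_{l+1} − t_l).
4. **Quality index** at each interior peak:
   q(t_m) = exp(−(|ln α| + |ln β|)), α = (t_m − t_{m−1})·f(t_m),
   β = (t_{m+1} − t_m)·f(t_m). Two conventions for f(t_m) are provided.
   Under the *forward* convention (default, the literal reading of the
   frequency definition) β ≡ 1 and q reduces to the adjacent-interval
   ratio, exp(−|ln(Δt_{m−1}/Δt_m)|). The *centered* convention
   f = 2/(t_{m+1} − t_{m−1}) makes both factors informative. Both give
   q = 1 exactly iff the intervals are mutually consistent, and both score
   a 2:1 adjacent-interval ratio as 0.5. The convention used is recorded
   on every output series. First/last peaks lack a neighbour and are
   dropped.
5. **Cleanup**: points with q below 0.5 are removed (accepts interval
   ratios within a factor of two; a double-detected peak produces a
   spurious short interval whose q is far below that).
6. **Interpolation** of frequency and quality onto a uniform 10 Hz grid
   (well above rate-variability bandwidth), linear by default (monotone
   cubic optional), never extrapolating beyond the surviving events.
7. **bpm = 60 × Hz.**

**Channel selection.** I and Q are analyzed independently and the series
with the higher mean quality is kept (ties → Q). Limitation: at a
perfectly symmetric operating-point null the bad channel frequency-doubles
*cleanly* — its half-period peaks are regular, so the interval-consistency
index cannot flag them. In practice noise, jitter and any asymmetry of the
operating point break that regularity and the quality comparison picks the
good channel; joint arctangent demodulation of (I, Q), which would remove
the issue entirely, is deliberately out of scope since the channels are
processed separately by design.

## Statistics

Agreement uses differences reference − radar (configurable, recorded in
the report): Bland–Altman mean difference with 95 % limits of agreement
mean ± 1.96 sd (sample sd), Pearson r, RMSE, and MAPE with the radar series
as denominator by default (reference optional). Pairing resamples both
rate series onto their common overlap at 1 Hz — roughly one pair per breath
at anesthetized-rat rates; the 10 Hz pipeline grid is
interpolation-autocorrelated and would overstate n.

Group comparison across protocol levels: per-level bpm samples decimated
to 1 Hz (same reasoning), Kruskal–Wallis, then Dunn's pairwise rank
z-tests with tie correction and Holm adjustment (Bonferroni optional);
stars at 0.05/0.01/0.001. Dunn-with-Holm is the conventional
Kruskal–Wallis follow-up. Under a simulated null the KW rejection rate at
α = 0.05 calibrates to the nominal level (checked over 1,000 replicates).
Not implemented by choice: LoA confidence intervals and repeated-measures
corrections for within-subject autocorrelation.

## Numerical choices and degenerate inputs

- Trace CSVs use 9-significant-digit floats; on reading, timestamps within
  1 % per-sample jitter of the declared rate are snapped to the exact
  declared grid (text rounding is not treated as jitter), beyond that the
  values are resampled with a warning.
- Empty scenarios, non-positive durations/rates, non-monotone or
  non-uniform time grids, missing columns and NaN rows are rejected with
  stage- or row-identifying errors; fewer than two surviving quality-gated
  points warns and refuses interpolation.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs give bit-identical
  outputs.

## Problem sizes

The test suite runs desk-scale versions of the study conditions (60–120 s
constant-rate runs; protocol presets time-scaled ×0.25), chosen so each
segment still contains ≥50 breathing cycles. The acceptance script runs
the protocol analyses at full 32-min scale and the accuracy sweep at
20 × 60 s.
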