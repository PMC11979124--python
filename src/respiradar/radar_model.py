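"""Physics-based simulator for a 24 GHz CW Doppler radar observing breathing.

A continuous-wave radar transmits a single carrier; chest-wall motion ``d(t)``
(millimetre scale for a rat) phase-modulates the reflection.  Quadrature
demodulation yields two baseband channels

    I(t) = A(t) sin(4*pi*(d(t) + d0)/lambda_c + phi)
    Q(t) = A(t) cos(4*pi*(d(t) + d0)/lambda_c + phi)

where ``lambda_c`` is the carrier wavelength, ``d0`` the nominal standoff
distance and ``phi`` the residual phase accumulated in antennas, wiring and
mixers.  The simulator produces both the I/Q trace and a co-registered
laser-style displacement reference from a ground-truth respiration scenario,
then applies additive Gaussian noise and ADC quantization to emulate the
acquisition chain (1,092 Hz sampling, 10-bit resolution by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT",
    "RadarConfig",
    "RespirationScenario",
    "IQTrace",
    "ReferenceTrace",
    "generate_displacement",
    "simulate_iq",
    "quantize_adc",
    "simulate_recording",
    "SCENARIO_PRESETS",
    "get_preset",
]

SPEED_OF_LIGHT = 3.0e8  # m/s


@dataclass(frozen=True)
class RadarConfig:
    """Physical and acquisition constants of the simulated sensor.

    Parameters
    ----------
    carrier_frequency : float
        Carrier in Hz.  Default 24.15 GHz, the midpoint of the licence-free
        24.05-24.25 GHz band used by compact radar modules.
    nominal_distance_d0 : float
        Standoff distance radar-to-chest in metres (sets the static part of
        the demodulated phase and hence the operating point).
    residual_phase_phi : float or None
        Residual phase in radians.  ``None`` draws it uniformly from
        ``[0, 2*pi)`` using the simulation seed, which reproducibly
        randomises the I/Q operating point.
    amplitude : float
        Received amplitude ``A`` in arbitrary units (constant by default).
    amplitude_drift : float
        Optional fractional peak amplitude drift over the recording
        (a single slow half-cosine), 0 disables.
    sampling_rate : float
        ADC sampling rate in Hz (default 1092).
    adc_bits : int
        ADC resolution; 0 disables quantization, otherwise 1..16.
    noise_sd : float
        Additive Gaussian noise standard deviation on each of I and Q, in
        output units, applied after the physics and before quantization.
    """

    carrier_frequency: float = 24.15e9
    nominal_distance_d0: float = 0.2
    residual_phase_phi: float | None = None
    amplitude: float = 1.0
    amplitude_drift: float = 0.0
    sampling_rate: float = 1092.0
    adc_bits: int = 10
    noise_sd: float = 0.0

    @property
    def wavelength(self) -> float:
        """Carrier wavelength ``c / fc`` in metres."""
        return SPEED_OF_LIGHT / self.carrier_frequency

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0:
            raise ValueError("carrier_frequency must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (self.adc_bits == 0 or 1 <= self.adc_bits <= 16):
            raise ValueError("adc_bits must be 0 (disabled) or in 1..16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class RespirationScenario:
    """Ground-truth breathing programme: piecewise-constant rate schedule.

    ``segments`` is a sequence of ``(duration_s, rate_bpm)`` pairs.  Each
    breathing cycle draws its own rate from a Gaussian centred on the
    segment rate (sd ``rate_jitter_sd`` bpm, truncated to stay positive),
    the simplest model of cycle-to-cycle variability.  The chest excursion
    follows a raised-cosine cycle by default (smooth, bounded, one peak per
    breath); ``waveform='sine'`` gives a plain sinusoid.  ``inhale_fraction``
    skews the cycle (fraction of the period spent inhaling).
    """

    segments: tuple[tuple[float, float], ...]
    displacement_amplitude: float = 1.0e-3  # m, peak-to-peak chest excursion
    rate_jitter_sd: float = 2.0  # bpm
    displacement_noise_sd: float = 0.0  # m
    waveform: str = "raised_cosine"
    inhale_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple((float(d), float(r)) for d, r in self.segments))
        if len(self.segments) == 0:
            raise ValueError("empty scenario")
        for dur, rate in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if rate <= 0:
                raise ValueError("segment rates must be positive")
        if self.displacement_amplitude < 0:
            raise ValueError("displacement_amplitude must be non-negative")
        if not 0.05 <= self.inhale_fraction <= 0.95:
            raise ValueError("inhale_fraction must be in [0.05, 0.95]")
        if self.waveform not in ("raised_cosine", "sine"):
            raise ValueError("waveform must be 'raised_cosine' or 'sine'")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def rate_at(self, t: float) -> float:
        """Nominal (jitter-free) rate in bpm at time ``t`` seconds."""
        edge = 0.0
        for dur, rate in self.segments:
            edge += dur
            if t < edge:
                return rate
        return self.segments[-1][1]


@dataclass(frozen=True)
class IQTrace:
    """Two-channel baseband radar signal on a uniform time grid."""

    times: np.ndarray  # s
    i_channel: np.ndarray  # a.u.
    q_channel: np.ndarray  # a.u.

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.i_channel) == len(self.q_channel)):
            raise ValueError("times, i_channel, q_channel must have equal length")


@dataclass(frozen=True)
class ReferenceTrace:
    """Laser-style chest-wall displacement reference, metres on a uniform grid."""

    times: np.ndarray  # s
    displacement: np.ndarray  # m

    def __post_init__(self) -> None:
        if len(self.times) != len(self.displacement):
            raise ValueError("times and displacement must have equal length")


def _cycle_waveform(phase: np.ndarray, waveform: str, inhale_fraction: float) -> np.ndarray:
    """Normalised chest excursion over one breath, phase in [0, 1) -> [0, 1]."""
    f = inhale_fraction
    warped = np.where(phase < f, phase / (2.0 * f), 0.5 + (phase - f) / (2.0 * (1.0 - f)))
    if waveform == "raised_cosine":
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * warped))
    # sine mode: zero-mean, same peak-to-peak
    return 0.5 * np.sin(2.0 * np.pi * warped)


def generate_displacement(scenario: RespirationScenario, sampling_rate: float) -> ReferenceTrace:
    """Sample the ground-truth chest displacement ``d(t)`` on a uniform grid.

    Breathing cycles are laid down sequentially: each cycle's period is
    ``60 / rate_i`` where ``rate_i ~ N(segment rate, rate_jitter_sd)``
    truncated below at 20% of the nominal rate.  Within a cycle the
    displacement follows the scenario waveform scaled to
    ``displacement_amplitude`` peak-to-peak; optional white measurement
    noise is added on top.  Deterministic for a given scenario seed.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    rng = np.random.default_rng(scenario.seed)
    total = scenario.total_duration

    starts = [0.0]
    periods = []
    t = 0.0
    while t < total:
        nominal = scenario.rate_at(t)
        rate = nominal + rng.normal(0.0, scenario.rate_jitter_sd)
        rate = max(rate, 0.2 * nominal)
        period = 60.0 / rate
        periods.append(period)
        t += period
        starts.append(t)
    starts_arr = np.asarray(starts)
    periods_arr = np.asarray(periods)

    n = int(round(total * sampling_rate))
    times = np.arange(n) / sampling_rate
    idx = np.clip(np.searchsorted(starts_arr, times, side="right") - 1, 0, len(periods_arr) - 1)
    phase = (times - starts_arr[idx]) / periods_arr[idx]
    phase = np.clip(phase, 0.0, np.nextafter(1.0, 0.0))

    disp = scenario.displacement_amplitude * _cycle_waveform(
        phase, scenario.waveform, scenario.inhale_fraction
    )
    if scenario.displacement_noise_sd > 0:
        disp = disp + rng.normal(0.0, scenario.displacement_noise_sd, size=n)
    return ReferenceTrace(times=times, displacement=disp)


def quantize_adc(signal: np.ndarray, bits: int, full_scale: float) -> np.ndarray:
    """Mid-rise uniform quantization to ``2**bits`` levels over [-full_scale, full_scale].

    Out-of-range samples clip to the outermost level.  Level centres map to
    themselves, so the operation is idempotent, and in-range samples move by
    at most ``full_scale / 2**bits`` (half a step).  ``bits <= 0`` is an
    error: disabling quantization is an explicit caller decision
    (``RadarConfig.adc_bits = 0``), not a silent pass-through.
    """
    if bits <= 0:
        raise ValueError("bits must be >= 1; use adc_bits=0 in RadarConfig to disable quantization")
    if full_scale <= 0:
        raise ValueError("full_scale must be positive")
    x = np.asarray(signal, dtype=float)
    n_levels = 2**bits
    step = 2.0 * full_scale / n_levels
    k = np.clip(np.floor((x + full_scale) / step), 0, n_levels - 1)
    return -full_scale + (k + 0.5) * step


def _check_uniform(times: np.ndarray, rtol: float = 1e-6) -> float:
    dt = np.diff(times)
    if len(dt) == 0:
        return 0.0
    if dt.min() <= 0 or (dt.max() - dt.min()) > rtol * dt.mean():
        raise ValueError("non-uniform sampling")
    return float(dt.mean())


def simulate_iq(reference: ReferenceTrace, config: RadarConfig, seed: int = 0) -> IQTrace:
    """Demodulate the reference motion into baseband I/Q per the CW radar model.

    Computes ``theta = 4*pi*(d(t) + d0)/lambda_c + phi`` and returns
    ``I = A sin(theta)``, ``Q = A cos(theta)`` with additive Gaussian noise
    (``config.noise_sd``) and, when ``adc_bits > 0``, quantization over the
    full-scale range ``+/-(A + 4*noise_sd)``.  ``seed`` drives the noise and,
    when ``residual_phase_phi`` is None, the residual-phase draw.
    """
    if len(reference.times) == 0:
        raise ValueError("empty reference trace")
    _check_uniform(reference.times)

    rng = np.random.default_rng(seed)
    phi = config.residual_phase_phi
    if phi is None:
        phi = float(rng.uniform(0.0, 2.0 * np.pi))

    lam = config.wavelength
    theta = 4.0 * np.pi * (reference.displacement + config.nominal_distance_d0) / lam + phi

    n = len(reference.times)
    amp = np.full(n, config.amplitude)
    if config.amplitude_drift != 0.0:
        drift = 0.5 * config.amplitude_drift * (1.0 - np.cos(np.pi * np.arange(n) / max(n - 1, 1)))
        amp = amp * (1.0 - drift)

    i_ch = amp * np.sin(theta)
    q_ch = amp * np.cos(theta)
    if config.noise_sd > 0:
        i_ch = i_ch + rng.normal(0.0, config.noise_sd, size=n)
        q_ch = q_ch + rng.normal(0.0, config.noise_sd, size=n)
    if config.adc_bits > 0:
        full_scale = config.amplitude + 4.0 * config.noise_sd
        i_ch = quantize_adc(i_ch, config.adc_bits, full_scale)
        q_ch = quantize_adc(q_ch, config.adc_bits, full_scale)
    return IQTrace(times=reference.times.copy(), i_channel=i_ch, q_channel=q_ch)


def simulate_recording(
    scenario: RespirationScenario, config: RadarConfig, seed: int | None = None
) -> tuple[IQTrace, ReferenceTrace]:
    """Convenience wrapper: displacement plus its I/Q trace in one call.

    ``seed`` defaults to the scenario seed so that a scenario fully
    determines the recording.
    """
    if seed is None:
        seed = scenario.seed
    ref = generate_displacement(scenario, config.sampling_rate)
    iq = simulate_iq(ref, config, seed=seed)
    return iq, ref


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioPreset:
    """A named scenario plus the anesthesia-level schedule it emulates.

    ``schedule`` is a sequence of ``(duration_s, label)`` pairs partitioning
    the recording into protocol levels (e.g. isoflurane concentrations).
    """

    name: str
    scenario: RespirationScenario
    schedule: tuple[tuple[float, str], ...]
    description: str = ""


def _iso_schedule(level_duration: float) -> tuple[tuple[float, str], ...]:
    return tuple((level_duration, lab) for lab in ("iso-1.7", "iso-1.3", "iso-2.1", "iso-0.9"))


# The isoflurane presets emulate the anesthesia protocol used to exercise the
# method: 1.7% baseline then steps to 1.3, 2.1 and 0.9% at 8-min intervals,
# with respiratory rates near 90, 85, 55 and 80 bpm at those depths
# (deeper anesthesia depresses breathing).  `rat_a_response` additionally
# models the within-level adaptation seen at the 1.7% baseline: the rate
# starts near 90 bpm and settles to 85 bpm, so the 1.7 and 1.3 levels have
# nearly identical rate distributions.
SCENARIO_PRESETS: dict[str, ScenarioPreset] = {
    "steady60": ScenarioPreset(
        name="steady60",
        scenario=RespirationScenario(segments=((120.0, 60.0),), rate_jitter_sd=2.0, seed=0),
        schedule=((120.0, "baseline"),),
        description="Two minutes of steady breathing at 60 bpm.",
    ),
    "isoflurane_step": ScenarioPreset(
        name="isoflurane_step",
        scenario=RespirationScenario(
            segments=((480.0, 90.0), (480.0, 85.0), (480.0, 55.0), (480.0, 80.0)),
            rate_jitter_sd=2.0,
            seed=0,
        ),
        schedule=_iso_schedule(480.0),
        description="Four 8-min isoflurane levels (1.7/1.3/2.1/0.9%) at constant rates 90/85/55/80 bpm.",
    ),
    "rat_a_response": ScenarioPreset(
        name="rat_a_response",
        scenario=RespirationScenario(
            segments=((24.0, 90.0), (456.0, 85.0), (480.0, 85.0), (480.0, 55.0), (480.0, 80.0)),
            rate_jitter_sd=2.0,
            seed=0,
        ),
        schedule=_iso_schedule(480.0),
        description=(
            "Isoflurane protocol with within-level adaptation at the 1.7% baseline "
            "(90 bpm settling to 85 bpm), so the 1.7 and 1.3 levels overlap."
        ),
    ),
}


def get_preset(name: str, seed: int = 0, duration_scale: float = 1.0) -> ScenarioPreset:
    """Look up a scenario preset, reseeded and optionally time-scaled.

    ``duration_scale`` multiplies every segment and schedule duration,
    which is useful for quick desk-scale runs of the long protocols.
    """
    if name not in SCENARIO_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(SCENARIO_PRESETS))}"
        )
    if duration_scale <= 0:
        raise ValueError("duration_scale must be positive")
    preset = SCENARIO_PRESETS[name]
    scenario = replace(
        preset.scenario,
        segments=tuple((d * duration_scale, r) for d, r in preset.scenario.segments),
        seed=seed,
    )
    schedule = tuple((d * duration_scale, lab) for d, lab in preset.schedule)
    return ScenarioPreset(
        name=preset.name, scenario=scenario, schedule=schedule, description=preset.description
    )
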