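"""Ground-truth-annotated synthetic MEA recordings and idealized pressure cycles.

Real organoid recordings from the blast experiments are not publicly
deposited, so every downstream stage is exercised against synthetic
recordings that emulate their statistical structure:

* zero-mean Gaussian background noise of known SD;
* stereotyped biphasic single-unit spikes of consistent (negative) amplitude
  at Poisson times;
* sparse population spikes of larger, per-event-variable amplitude;
* an optional sub-10 Hz network oscillation shared across channels, whose
  cross-channel phase coherence is set by a single ``coupling`` knob in
  [0, 1] (1 = identical phases on every channel, 0 = fully independent
  phase drift).

Every injected event and oscillation parameter is returned in a
:class:`GroundTruth` record so detection recall/precision and synchrony
recovery can be scored exactly.  Generation is a pure function of
``(config, seed)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import Recording
from .dose import PressureWaveform

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "spike_template",
    "generate_recording",
    "generate_pressure_waveform",
    "STUDIED_LOADING_FREQS",
    "STUDIED_PEAKS",
]

#: Loading frequencies (Hz) and peak pressures (kPa) examined in the study
#: design this generator emulates.  Other values are allowed with a warning.
STUDIED_LOADING_FREQS = (500.0, 3000.0, 5000.0)
STUDIED_PEAKS = (250.0, 350.0)

#: Minimum separation between injected events on one channel (s), so each
#: ground-truth event corresponds to one unambiguous threshold excursion.
MIN_EVENT_SEPARATION = 0.002


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording.

    Defaults mirror the acquisition described for the real experiments:
    12 electrodes per well sampled at 10 kHz for 120 s.  Amplitudes are
    negative (extracellular spikes deflect negative); the population-spike
    amplitude is drawn per event from ``population_amplitude_range``
    (default 1.5-3x the single-unit amplitude) since population events vary
    in size while single-unit events are stereotyped.
    """

    n_channels: int = 12
    sampling_rate: float = 10_000.0  # Hz
    duration: float = 120.0          # s
    noise_sd: float = 2.5            # uV
    spike_amplitude: float = -25.0   # uV, negative deflection
    population_amplitude_range: tuple[float, float] | None = None  # uV (negative)
    spike_rate: float = 1.0          # events/s per channel
    population_rate: float = 0.1     # events/s per channel
    oscillation_amplitude: float = 20.0  # uV; 0 disables the oscillation
    oscillation_freq: float = 6.0    # Hz, inside the (0, 10) Hz band
    coupling: float = 0.8            # cross-channel phase coherence in [0, 1]
    phase_jitter_sd: float = 2.2     # rad; stationary SD of per-channel phase jitter
    phase_jitter_tau: float = 0.3    # s; correlation time of the phase jitter
    spike_template_ms: float = 1.0   # single-unit template width
    population_template_ms: float = 5.0

    def resolved_population_range(self) -> tuple[float, float]:
        if self.population_amplitude_range is not None:
            return self.population_amplitude_range
        a = abs(self.spike_amplitude)
        return (-3.0 * a, -1.5 * a)

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.sampling_rate <= 2 * 3500.0:
            raise ValueError(
                "sampling_rate must exceed twice the 3500 Hz acquisition band "
                f"edge, got {self.sampling_rate}"
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        lo, hi = self.resolved_population_range()
        if not (lo <= hi < 0) or abs(hi) <= abs(self.spike_amplitude) * (
            1 if self.spike_amplitude else 0
        ):
            if self.spike_amplitude != 0 and abs(hi) <= abs(self.spike_amplitude):
                raise ValueError(
                    "population_amplitude_range must exceed |spike_amplitude| "
                    f"in magnitude, got {lo, hi} vs {self.spike_amplitude}"
                )
            if not (lo <= hi < 0):
                raise ValueError(
                    f"population_amplitude_range must be negative, got {(lo, hi)}"
                )
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError(f"coupling must lie in [0, 1], got {self.coupling}")
        if self.oscillation_amplitude and not (0 < self.oscillation_freq <= 10.0):
            raise ValueError(
                f"oscillation_freq must lie in (0, 10] Hz, got {self.oscillation_freq}"
            )
        for name in ("spike_rate", "population_rate"):
            rate = getattr(self, name)
            if rate < 0:
                raise ValueError(f"{name} must be non-negative, got {rate}")
            if rate * self.duration > 1e7:
                raise ValueError(f"{name} x duration exceeds the 1e7 event guard")
        if self.duration * self.sampling_rate > 2**31:
            raise ValueError("duration x sampling_rate overflows the sample guard")


@dataclass
class GroundTruth:
    """Everything injected into a synthetic recording.

    ``spike_times_by_channel`` maps event class (``single_unit`` /
    ``population``) to {channel label: sorted event times in s, taken at the
    template's negative peak}.  ``population_amplitudes`` records the drawn
    per-event amplitude for the population class.
    """

    spike_times_by_channel: dict[str, dict[str, np.ndarray]]
    population_amplitudes: dict[str, np.ndarray]
    oscillation_freq: float
    oscillation_amplitude: float
    coupling: float
    seed: int
    channel_labels: list[str] = field(default_factory=list)

    def all_times(self, event_class: str) -> dict[str, np.ndarray]:
        return self.spike_times_by_channel[event_class]

    def n_events(self, event_class: str) -> int:
        return int(
            sum(t.size for t in self.spike_times_by_channel[event_class].values())
        )


def spike_template(
    sampling_rate: float, width_ms: float = 1.0, rebound: float = 0.25
) -> np.ndarray:
    """Stereotyped biphasic extracellular spike shape, peak-normalized to -1.

    A sharp negative lobe followed by a smaller positive rebound, ~1 ms total
    width for single units.  The real spike waveform parameters are not
    published; this shape is a convention chosen for its resemblance to
    textbook extracellular action potentials.
    """
    width_s = width_ms / 1e3
    n = max(int(round(width_s * sampling_rate)), 3)
    t = np.arange(n) / sampling_rate
    neg_center, neg_sd = 0.25 * width_s, 0.08 * width_s
    pos_center, pos_sd = 0.60 * width_s, 0.15 * width_s
    shape = -np.exp(-0.5 * ((t - neg_center) / neg_sd) ** 2) + rebound * np.exp(
        -0.5 * ((t - pos_center) / pos_sd) ** 2
    )
    return shape / abs(shape.min())


def _poisson_times(
    rng: np.random.Generator, rate: float, duration: float, min_gap: float
) -> np.ndarray:
    """Homogeneous Poisson event times on [0, duration), thinned to min_gap."""
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    if times.size < 2:
        return times
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= min_gap:
            keep.append(i)
    return times[keep]


def _inject(trace: np.ndarray, template: np.ndarray, peak_idx_in_template: int,
            times: np.ndarray, amplitudes: np.ndarray, fs: float) -> np.ndarray:
    """Add amplitude-scaled templates so the negative peak lands at each time."""
    kept_times = []
    n = trace.size
    for t, a in zip(times, amplitudes):
        peak_sample = int(round(t * fs))
        start = peak_sample - peak_idx_in_template
        stop = start + template.size
        if start < 0 or stop > n:
            continue  # too close to an edge to fit the full template
        trace[start:stop] += abs(a) * template
        kept_times.append(peak_sample / fs)
    return np.asarray(kept_times)


def generate_recording(
    config: SynthConfig, seed: int
) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic MEA recording plus its exact ground truth.

    The same ``(config, seed)`` always yields a bit-identical recording.
    Events whose template would overhang the recording edge are dropped from
    both the signal and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    labels = [f"ch{i + 1:02d}" for i in range(config.n_channels)]

    samples = rng.normal(0.0, config.noise_sd, size=(config.n_channels, n_samples))

    su_template = spike_template(fs, config.spike_template_ms)
    pop_template = spike_template(fs, config.population_template_ms)
    su_peak = int(np.argmin(su_template))
    pop_peak = int(np.argmin(pop_template))
    pop_lo, pop_hi = config.resolved_population_range()

    su_times: dict[str, np.ndarray] = {}
    pop_times: dict[str, np.ndarray] = {}
    pop_amps: dict[str, np.ndarray] = {}
    for ch, label in enumerate(labels):
        times = _poisson_times(
            rng, config.spike_rate, config.duration, MIN_EVENT_SEPARATION
        )
        amps = np.full(times.size, config.spike_amplitude)
        su_times[label] = _inject(
            samples[ch], su_template, su_peak, times, amps, fs
        )

        times = _poisson_times(
            rng, config.population_rate, config.duration, MIN_EVENT_SEPARATION
        )
        amps = rng.uniform(abs(pop_hi), abs(pop_lo), size=times.size) * -1.0
        kept = _inject(samples[ch], pop_template, pop_peak, times, amps, fs)
        pop_times[label] = kept
        pop_amps[label] = amps[: kept.size]

    if config.oscillation_amplitude > 0:
        t = np.arange(n_samples) / fs
        common_phase = 2 * np.pi * config.oscillation_freq * t
        # Per-channel phase jitter is a mean-reverting (Ornstein-Uhlenbeck)
        # walk with stationary SD phase_jitter_sd and correlation time
        # phase_jitter_tau, scaled by (1 - coupling).  Mean reversion keeps
        # the jitter bounded, so the pair synchrony index varies smoothly
        # and monotonically with the coupling knob (~exp(-((1-c)*sd)^2)
        # asymptotically) instead of collapsing to the null for any c < 1.
        ar = np.exp(-1.0 / (config.phase_jitter_tau * fs))
        step_sd = config.phase_jitter_sd * np.sqrt(1.0 - ar**2)
        for ch in range(config.n_channels):
            steps = rng.normal(0.0, step_sd, size=n_samples)
            jitter = lfilter([1.0], [1.0, -ar], steps)
            phase = common_phase + (1.0 - config.coupling) * jitter
            samples[ch] += config.oscillation_amplitude * np.sin(phase)

    recording = Recording(
        samples=samples, sampling_rate=fs, channel_labels=labels
    )
    truth = GroundTruth(
        spike_times_by_channel={"single_unit": su_times, "population": pop_times},
        population_amplitudes=pop_amps,
        oscillation_freq=config.oscillation_freq,
        oscillation_amplitude=config.oscillation_amplitude,
        coupling=config.coupling,
        seed=seed,
        channel_labels=labels,
    )
    return recording, truth


def generate_pressure_waveform(
    loading_freq: float,
    peak: float,
    duration: float = 0.008,
    sampling_rate: float = 1_000_000.0,
) -> PressureWaveform:
    """Idealized raised-cosine pressure burst.

    ``p(t) = (peak / 2) * (1 - cos(2 pi f t))`` on [0, duration]: complete
    non-negative cycles with minimum 0 and maximum ``peak``, no negative
    phase.  Its time average is ``peak / 2`` regardless of loading
    frequency, which makes exposures at different frequencies equivalent in
    mean pressure.  Values outside the studied parameter set (500/3000/5000
    Hz, 250/350 kPa) are permitted with a warning — the parameter space is
    intentionally tunable.
    """
    if loading_freq <= 0:
        raise ValueError("loading_freq must be positive")
    if sampling_rate < 20 * loading_freq:
        raise ValueError(
            f"sampling_rate must be >= 20 x loading_freq "
            f"({20 * loading_freq:.0f} Hz), got {sampling_rate}"
        )
    if loading_freq not in STUDIED_LOADING_FREQS:
        warnings.warn(
            f"loading_freq {loading_freq} Hz is outside the studied set "
            f"{STUDIED_LOADING_FREQS}", stacklevel=2
        )
    if peak not in STUDIED_PEAKS:
        warnings.warn(
            f"peak {peak} kPa is outside the studied set {STUDIED_PEAKS}",
            stacklevel=2,
        )
    n = int(round(duration * sampling_rate))
    t = np.arange(n + 1) / sampling_rate
    pressure = (peak / 2.0) * (1.0 - np.cos(2 * np.pi * loading_freq * t))
    pressure = np.clip(pressure, 0.0, None)  # guard tiny negative round-off
    return PressureWaveform(
        time=t,
        pressure=pressure,
        loading_freq=loading_freq,
        nominal_peak=peak,
        duration=duration,
    )
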