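"""Pressure-exposure dosimetry.

The tabletop blast chamber delivers an idealized, strictly non-negative
pressure cycle (no negative phase, unlike ultrasound).  This module
quantifies an exposure by its peak, duration and integrated overpressure
(trapezoidal rule, reported in kPa*ms), and implements the quasi-hydrostatic
timescale argument: pressure changes homogenize across the ~30 mm chamber at
the speed of sound in water (~1480 m/s), i.e. in ~20 us, so the chamber's
characteristic frequency (~50 kHz) is an order of magnitude above the
fastest loading frequency (5 kHz) and every organoid sees the same pressure
simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PressureWaveform",
    "DoseMetrics",
    "ChamberSpec",
    "integrate_overpressure",
    "homogenization_time",
    "characteristic_frequency",
    "quasi_hydrostatic_check",
]


@dataclass
class PressureWaveform:
    """Sampled pressure loading cycle.

    ``time`` is in seconds (strictly increasing), ``pressure`` in kPa and
    non-negative everywhere.  ``loading_freq`` and ``nominal_peak`` record
    the generating parameters for bookkeeping; ``duration`` is the loading
    window in seconds.
    """

    time: np.ndarray
    pressure: np.ndarray
    loading_freq: float
    nominal_peak: float
    duration: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.pressure = np.asarray(self.pressure, dtype=np.float64)
        if self.time.shape != self.pressure.shape:
            raise ValueError("time and pressure must have the same shape")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(self.pressure < -1e-12):
            raise ValueError("pressure must be non-negative (no negative phase)")


@dataclass(frozen=True)
class DoseMetrics:
    """Scalar dose summary of one exposure.

    ``integrated_overpressure`` is the time integral of pressure in kPa*ms;
    by construction it equals ``mean_pressure * duration`` (duration in ms).
    """

    peak: float                     # kPa
    integrated_overpressure: float  # kPa*ms
    mean_pressure: float            # kPa
    duration: float                 # s


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry/acoustics of the pressure chamber.

    Defaults: 30 mm chamber filled with aqueous medium (sound speed
    ~1480 m/s).
    """

    length: float = 0.030       # m
    sound_speed: float = 1480.0  # m/s

    def __post_init__(self) -> None:
        if self.length <= 0 or self.sound_speed <= 0:
            raise ValueError("chamber length and sound speed must be positive")


def integrate_overpressure(waveform: PressureWaveform) -> DoseMetrics:
    """Integrated blast overpressure by the trapezoidal rule.

    Returns the integral of pressure over time in kPa*ms, the peak sample,
    the mean pressure (integral / duration) and the sampled duration.
    """
    if waveform.time.size < 2:
        raise ValueError("waveform must have at least 2 samples")
    integral_kpa_s = float(np.trapezoid(waveform.pressure, waveform.time))
    duration = float(waveform.time[-1] - waveform.time[0])
    return DoseMetrics(
        peak=float(np.max(waveform.pressure)),
        integrated_overpressure=integral_kpa_s * 1e3,
        mean_pressure=integral_kpa_s / duration,
        duration=duration,
    )


def homogenization_time(chamber: ChamberSpec = ChamberSpec()) -> float:
    """Time (s) for a pressure change to traverse the chamber: length / c.

    Default chamber: 0.030 m / 1480 m/s ~= 20 us.
    """
    return chamber.length / chamber.sound_speed


def characteristic_frequency(chamber: ChamberSpec = ChamberSpec()) -> float:
    """Reciprocal of the homogenization time (Hz); ~50 kHz by default."""
    return 1.0 / homogenization_time(chamber)


def _round_one_sig_fig(x: float) -> float:
    if x == 0:
        return 0.0
    exponent = np.floor(np.log10(abs(x)))
    return float(np.round(x / 10**exponent) * 10**exponent)


def quasi_hydrostatic_check(
    chamber: ChamberSpec, loading_freq: float
) -> tuple[bool, float]:
    """Is the loading slow enough that the chamber stays pressure-uniform?

    Returns ``(passes, ratio)`` where ``ratio`` is the exact
    characteristic-frequency / loading-frequency ratio.  The pass/fail
    verdict uses the characteristic frequency rounded to one significant
    figure (49.3 kHz -> 50 kHz) and requires the rounded ratio >= 10, the
    conventional order-of-magnitude separation for treating the loading as
    quasi-hydrostatic.
    """
    if loading_freq <= 0:
        raise ValueError("loading_freq must be positive")
    f_char = characteristic_frequency(chamber)
    ratio = f_char / loading_freq
    rounded_ratio = _round_one_sig_fig(f_char) / loading_freq
    return bool(rounded_ratio >= 10.0), ratio
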