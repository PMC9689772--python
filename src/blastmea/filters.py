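"""Signal conditioning: second-order Butterworth band-pass / low-pass filters.

Three named presets cover the analysis bands used throughout the pipeline:

* ``single_unit``  — 100-3500 Hz band-pass (single-unit event detection)
* ``population``   — 1-3500 Hz band-pass (population-spike detection)
* ``oscillation``  — low-pass at 10 Hz (network-oscillation band; a "0 Hz
  low cut" is treated as a pure low-pass, since a true 0 Hz band edge is
  degenerate)

Filtering is zero-phase (forward-backward second-order sections), so
detected event times are not shifted; the effective magnitude response is
therefore |H(f)|^2 of the designed filter.  Edges are handled by odd-reflect
padding; the first and last ``UNTRUSTED_EDGE_S`` seconds should not be
trusted for event detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Recording

__all__ = ["FilterSpec", "apply_filter", "standard_specs", "UNTRUSTED_EDGE_S"]

#: Leading/trailing span (s) where filter transients may corrupt detection.
UNTRUSTED_EDGE_S = 0.050


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description.

    ``low_cut == 0`` means a pure low-pass at ``high_cut`` (kind is forced
    to ``low_pass``); otherwise a band-pass between the two corners.
    """

    low_cut: float            # Hz; 0 => low-pass
    high_cut: float           # Hz
    order: int = 2
    name: str = ""

    def __post_init__(self) -> None:
        if self.low_cut < 0:
            raise ValueError(f"low_cut must be >= 0, got {self.low_cut}")
        if self.high_cut <= self.low_cut:
            raise ValueError(
                f"high_cut ({self.high_cut}) must exceed low_cut ({self.low_cut})"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")

    @property
    def kind(self) -> str:
        return "low_pass" if self.low_cut == 0 else "band_pass"

    def sos(self, sampling_rate: float) -> np.ndarray:
        """Second-order-section coefficients for a given sampling rate."""
        nyquist = sampling_rate / 2.0
        if self.high_cut >= nyquist:
            raise ValueError(
                f"high_cut {self.high_cut} Hz is at/above the Nyquist limit "
                f"{nyquist} Hz for sampling rate {sampling_rate} Hz"
            )
        if self.kind == "low_pass":
            return sps.butter(
                self.order, self.high_cut, btype="lowpass",
                fs=sampling_rate, output="sos",
            )
        return sps.butter(
            self.order, [self.low_cut, self.high_cut], btype="bandpass",
            fs=sampling_rate, output="sos",
        )

    def magnitude_response(
        self, freqs: np.ndarray, sampling_rate: float, zero_phase: bool = True
    ) -> np.ndarray:
        """|H(f)| of the designed filter; squared when applied zero-phase."""
        _, h = sps.sosfreqz(
            self.sos(sampling_rate), worN=np.atleast_1d(freqs), fs=sampling_rate
        )
        mag = np.abs(h)
        return mag**2 if zero_phase else mag

    def describe(self) -> str:
        label = self.name or self.kind
        return f"{label}:{self.low_cut}-{self.high_cut}Hz,order{self.order}"


def apply_filter(recording: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase Butterworth filtering of every channel.

    Output has the same shape as the input; the filter is applied forward
    and backward (``sosfiltfilt``) so the group delay cancels and event
    times stay aligned with ground truth.  Padding is 3x the filter's
    settling length (capped by trace length).
    """
    sos = spec.sos(recording.sampling_rate)
    # settling length of the sections, as used by sosfiltfilt's default
    default_pad = 3 * (2 * sos.shape[0] + 1)
    padlen = min(3 * default_pad, recording.n_samples - 1)
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=-1, padlen=padlen)
    return recording.with_samples(filtered, filter_applied=spec.describe())


def standard_specs() -> dict[str, FilterSpec]:
    """The pipeline's named filter presets."""
    return {
        "single_unit": FilterSpec(100.0, 3500.0, order=2, name="single_unit"),
        "population": FilterSpec(1.0, 3500.0, order=2, name="population"),
        "oscillation": FilterSpec(0.0, 10.0, order=2, name="oscillation"),
    }
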