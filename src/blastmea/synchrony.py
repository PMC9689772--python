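"""Phase synchrony between electrode pairs via complex Morlet wavelets.

The instantaneous phase of each of two neighboring channels is extracted by
convolving the raw epoch with a complex Morlet wavelet centered at a probe
frequency (default 10 Hz, the top of the network-oscillation band).  The
synchrony index is the phase-locking value: the modulus of the sample-mean
unit phasor of the phase-angle difference,

    PLV = | mean_t exp(i * (phi_a(t) - phi_b(t))) |,

bounded in [0, 1]; 1 iff the phase difference is constant over the epoch
(so a constant offset between channels still counts as perfect locking),
and O(1/sqrt(n)) for unrelated phases.  Samples within 3 wavelet SDs of the
epoch edges are discarded before averaging to avoid convolution edge bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ActiveElectrodeMask, ElectrodeMap, Recording
from .spectral import EpochSelection

__all__ = [
    "PhaseSeries",
    "SynchronyResult",
    "morlet_wavelet",
    "morlet_phase",
    "synchrony_index",
    "pair_select",
]

DEFAULT_PROBE_FREQ = 10.0   # Hz
DEFAULT_N_CYCLES = 7        # time-frequency trade-off: ~0.11 s Gaussian SD at 10 Hz
DEFAULT_EPOCH_LENGTH = 2.0  # s
EDGE_TRIM_SDS = 3.0


@dataclass
class PhaseSeries:
    """Instantaneous phase of one channel at the probe frequency.

    ``phases`` are radians wrapped to (-pi, pi], one per epoch sample;
    ``edge_trim`` is the number of samples at each end that fall within the
    wavelet's edge-bias zone and are excluded from synchrony averaging.
    """

    channel: str
    probe_freq: float
    phases: np.ndarray
    epoch: EpochSelection
    edge_trim: int = 0


@dataclass(frozen=True)
class SynchronyResult:
    """Phase-locking value for one channel pair; ``index`` in [0, 1]."""

    channel_pair: tuple[str, str]
    index: float
    probe_freq: float
    epoch: EpochSelection


def morlet_wavelet(
    probe_freq: float, n_cycles: int, sampling_rate: float
) -> np.ndarray:
    """Complex Morlet wavelet: Gaussian envelope times e^{i 2 pi f t}.

    The Gaussian SD is ``n_cycles / (2 pi f)`` seconds; support spans
    +/- 4 SD.  Amplitude normalization is immaterial for phase extraction.
    """
    sd = n_cycles / (2 * np.pi * probe_freq)
    half = int(np.ceil(4 * sd * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    envelope = np.exp(-(t**2) / (2 * sd**2))
    return envelope * np.exp(2j * np.pi * probe_freq * t)


def morlet_phase(
    recording: Recording,
    channel: str,
    epoch: EpochSelection,
    probe_freq: float = DEFAULT_PROBE_FREQ,
    n_cycles: int = DEFAULT_N_CYCLES,
) -> PhaseSeries:
    """Per-sample phase of one channel's raw epoch at the probe frequency."""
    if probe_freq >= recording.sampling_rate / 2:
        raise ValueError(
            f"probe_freq {probe_freq} Hz must be below Nyquist "
            f"({recording.sampling_rate / 2} Hz)"
        )
    if n_cycles < 3:
        raise ValueError(f"n_cycles must be >= 3, got {n_cycles}")
    epoch = EpochSelection(epoch.start, epoch.length, channel, epoch.seed)
    trace = recording.channel(channel)[epoch.slice_for(recording)]
    wavelet = morlet_wavelet(probe_freq, n_cycles, recording.sampling_rate)
    if trace.size < wavelet.size:
        raise ValueError(
            f"epoch of {trace.size} samples is shorter than the wavelet "
            f"support ({wavelet.size} samples at {probe_freq} Hz, "
            f"{n_cycles} cycles)"
        )
    analytic = sps.fftconvolve(trace.astype(np.complex128), wavelet, mode="same")
    sd_samples = n_cycles / (2 * np.pi * probe_freq) * recording.sampling_rate
    return PhaseSeries(
        channel=channel,
        probe_freq=probe_freq,
        phases=np.angle(analytic),
        epoch=epoch,
        edge_trim=int(np.ceil(EDGE_TRIM_SDS * sd_samples)),
    )


def synchrony_index(a: PhaseSeries, b: PhaseSeries) -> SynchronyResult:
    """Phase-locking value of the phase difference between two channels.

    Invariant to adding a common constant to both phase series; exactly 1
    when the phase difference is constant.  Edge-biased samples (the larger
    of the two series' trims, each end) are excluded.
    """
    if a.phases.size != b.phases.size:
        raise ValueError(
            f"phase series lengths differ: {a.phases.size} vs {b.phases.size}"
        )
    if a.probe_freq != b.probe_freq:
        raise ValueError("phase series have different probe frequencies")
    if (a.epoch.start, a.epoch.length) != (b.epoch.start, b.epoch.length):
        raise ValueError("phase series come from different epochs")
    trim = max(a.edge_trim, b.edge_trim)
    if 2 * trim >= a.phases.size:
        raise ValueError("epoch too short: edge trimming leaves no samples")
    sl = slice(trim, a.phases.size - trim) if trim else slice(None)
    diff = a.phases[sl] - b.phases[sl]
    plv = float(np.abs(np.mean(np.exp(1j * diff))))
    return SynchronyResult(
        channel_pair=(a.channel, b.channel),
        index=min(plv, 1.0),
        probe_freq=a.probe_freq,
        epoch=a.epoch,
    )


def pair_select(
    electrode_map: ElectrodeMap,
    mask: ActiveElectrodeMask,
    override: tuple[str, str] | None = None,
) -> tuple[str, str]:
    """Closest pair of active electrodes on the grid.

    Mirrors the convention of picking two neighboring channels over the
    organoid: among active electrodes, the pair at minimum grid distance,
    ties broken by lowest channel order in the map.  An explicitly
    configured pair overrides the geometric choice.
    """
    if override is not None:
        for label in override:
            if not mask.is_active(label):
                raise ValueError(f"configured channel {label!r} is not active")
        return tuple(override)  # type: ignore[return-value]
    order = {label: i for i, label in enumerate(electrode_map.positions)}
    active = [lab for lab in electrode_map.positions if mask.is_active(lab)]
    if len(active) < 2:
        raise ValueError(
            f"pair selection requires >= 2 active channels, got {len(active)}"
        )
    best: tuple[float, int, int, str, str] | None = None
    for i, la in enumerate(active):
        for lb in active[i + 1:]:
            key = (
                electrode_map.distance_um(la, lb),
                order[la],
                order[lb],
                la,
                lb,
            )
            if best is None or key < best:
                best = key
    assert best is not None
    return best[3], best[4]
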