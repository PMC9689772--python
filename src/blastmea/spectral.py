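"""Epoch power spectra, band peak power and spectrograms.

Network oscillations are quantified on a randomly selected epoch (default
5 s out of the 120 s recording): the epoch is demeaned and transformed with
a discrete Fourier transform (untapered periodogram), and the *band peak
power* is the power at the largest local maximum of the PSD strictly inside
the (0, 10) Hz band (DC excluded).  Group values are reported normalized to
the mean of the matching control group, so controls average to 1 by
construction.  Spectrograms (1 s Hann window, 50% overlap, ~1 Hz
resolution) visualize the band over the whole recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ActiveElectrodeMask, Recording

__all__ = [
    "EpochSelection",
    "PowerSpectrum",
    "SpectrogramResult",
    "select_epoch",
    "compute_psd",
    "normalize_to_control",
    "compute_spectrogram",
    "OSCILLATION_BAND",
]

#: Open frequency interval (Hz) for network-oscillation peak power.
OSCILLATION_BAND = (0.0, 10.0)

#: Spectral epoch length in seconds.
DEFAULT_EPOCH_LENGTH = 5.0

#: Minimum PSD peak prominence, as a fraction of the in-band maximum.
PEAK_PROMINENCE_FRACTION = 0.05


@dataclass(frozen=True)
class EpochSelection:
    """A window of one channel: ``[start, start + length)`` seconds."""

    start: float
    length: float
    channel: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"epoch start must be >= 0, got {self.start}")
        if self.length <= 0:
            raise ValueError(f"epoch length must be positive, got {self.length}")

    def slice_for(self, recording: Recording) -> slice:
        if self.start + self.length > recording.duration + 1e-9:
            raise ValueError(
                f"epoch [{self.start}, {self.start + self.length}) s exceeds "
                f"the {recording.duration} s recording"
            )
        i0 = int(round((self.start - recording.t0) * recording.sampling_rate))
        n = int(round(self.length * recording.sampling_rate))
        return slice(i0, i0 + n)


@dataclass
class PowerSpectrum:
    """One-sided PSD of a demeaned epoch (uV^2/Hz on a [0, Nyquist] grid).

    ``band_peak_power`` is the power at the most powerful local maximum
    strictly inside ``band``; if the in-band PSD has no local maximum the
    in-band maximum is used instead and ``peak_is_local_max`` is False.
    ``degenerate`` flags an all-zero epoch.
    """

    freqs: np.ndarray
    power: np.ndarray
    band_peak_power: float
    band_peak_freq: float
    source: EpochSelection
    band: tuple[float, float] = OSCILLATION_BAND
    peak_is_local_max: bool = True
    degenerate: bool = False


@dataclass
class SpectrogramResult:
    """Short-time power over sliding windows: power[freq, time] >= 0."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    channel: str


def select_epoch(
    recording: Recording,
    length: float = DEFAULT_EPOCH_LENGTH,
    seed: int | None = None,
    channel: str | None = None,
) -> EpochSelection:
    """Uniform-random epoch start in ``[0, duration - length]``.

    Reproducible under ``seed``; a recording exactly as long as the epoch
    forces start 0.
    """
    if recording.duration + 1e-9 < length:
        raise ValueError(
            f"recording ({recording.duration} s) is shorter than the "
            f"requested {length} s epoch"
        )
    span = max(recording.duration - length, 0.0)
    rng = np.random.default_rng(seed)
    start = float(rng.uniform(0.0, span)) if span > 0 else 0.0
    if channel is None:
        channel = recording.channel_labels[0]
    return EpochSelection(start=start, length=length, channel=channel, seed=seed)


def compute_psd(
    recording: Recording,
    epoch: EpochSelection,
    band: tuple[float, float] = OSCILLATION_BAND,
) -> PowerSpectrum:
    """Untapered one-sided periodogram of the demeaned epoch.

    Satisfies Parseval: ``sum(power) * df`` equals the epoch variance.  Band
    peak power is found with ``scipy.signal.find_peaks`` restricted to the
    open interval ``band`` (DC bin excluded), requiring prominence of at
    least 5% of the in-band maximum.
    """
    trace = recording.channel(epoch.channel)[epoch.slice_for(recording)]
    if np.isnan(trace).any():
        raise ValueError(f"NaN samples in channel {epoch.channel!r}")
    freqs, power = sps.periodogram(
        trace,
        fs=recording.sampling_rate,
        window="boxcar",
        detrend="constant",
        scaling="density",
    )
    if not power.any():
        return PowerSpectrum(
            freqs=freqs, power=power, band_peak_power=0.0, band_peak_freq=np.nan,
            source=epoch, band=band, peak_is_local_max=False, degenerate=True,
        )

    in_band = (freqs > band[0]) & (freqs < band[1])
    band_power = power[in_band]
    band_freqs = freqs[in_band]
    if band_power.size == 0:
        raise ValueError(f"no PSD bins strictly inside {band} Hz")
    prominence = PEAK_PROMINENCE_FRACTION * float(band_power.max())
    peaks, _ = sps.find_peaks(band_power, prominence=prominence)
    if peaks.size:
        best = peaks[np.argmax(band_power[peaks])]
        peak_power, peak_freq, is_local = band_power[best], band_freqs[best], True
    else:
        best = int(np.argmax(band_power))
        peak_power, peak_freq, is_local = band_power[best], band_freqs[best], False
    return PowerSpectrum(
        freqs=freqs, power=power, band_peak_power=float(peak_power),
        band_peak_freq=float(peak_freq), source=epoch, band=band,
        peak_is_local_max=is_local,
    )


def normalize_to_control(
    values: np.ndarray, control_values: np.ndarray
) -> np.ndarray:
    """Divide each value by the mean of the control group.

    The normalized control group averages exactly 1 by construction.  Raises
    if the control mean is not positive (normalization undefined).
    """
    values = np.asarray(values, dtype=np.float64)
    control = np.asarray(control_values, dtype=np.float64)
    if control.size == 0:
        raise ValueError("control group is empty")
    mean = float(control.mean())
    if mean <= 0:
        raise ValueError(f"control mean must be positive, got {mean}")
    return values / mean


def compute_spectrogram(
    recording: Recording,
    channel: str,
    mask: ActiveElectrodeMask | None = None,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> SpectrogramResult:
    """Short-time power of one channel (Hann window, 50% overlap default)."""
    if mask is not None and not mask.is_active(channel):
        raise ValueError(f"channel {channel!r} is not an active electrode")
    nperseg = int(round(window_s * recording.sampling_rate))
    noverlap = int(round(overlap * nperseg))
    freqs, times, power = sps.spectrogram(
        recording.channel(channel),
        fs=recording.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    return SpectrogramResult(
        times=times + recording.t0, freqs=freqs, power=power, channel=channel
    )
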