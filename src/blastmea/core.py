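"""Core containers shared by every analysis stage.

A :class:`Recording` is the substrate of the whole pipeline: a channels x
time matrix of extracellular voltage (microvolts) with a sampling rate and
channel labels.  :class:`ElectrodeMap` describes the physical electrode grid
of one MEA well (12 gold electrodes, 100 um diameter, 700 um pitch) and
:class:`ActiveElectrodeMask` records which electrodes are in contact with
the organoid — inactive electrodes are excluded from every analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Recording",
    "ElectrodeMap",
    "ActiveElectrodeMask",
    "default_electrode_map",
]


@dataclass
class Recording:
    """Multi-channel voltage time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    sampling_rate : float
        Samples per second (Hz); the acquisition system samples at 10 kHz.
    channel_labels : list of str
        One identifier per channel, e.g. ``ch01`` .. ``ch12``.
    t0 : float
        Recording start time in seconds (default 0).
    filter_history : list of str
        Names/descriptions of filters already applied, appended by
        ``apply_filter``.  Detection stages use this to verify the caller
        conditioned the signal with the intended band.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    t0: float = 0.0
    filter_history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError(
                f"samples must be 2-D (channels x time), got {self.samples.ndim}-D"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the trace of one channel by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray, *, filter_applied: str | None = None) -> "Recording":
        """Copy of this recording with new samples (same metadata)."""
        history = list(self.filter_history)
        if filter_applied is not None:
            history.append(filter_applied)
        return replace(self, samples=samples, filter_history=history)


@dataclass(frozen=True)
class ElectrodeMap:
    """Physical layout of one MEA well.

    ``positions`` maps channel label -> (row, col) grid coordinate; physical
    distance between two electrodes is the Euclidean grid distance times
    ``pitch_um``.
    """

    positions: dict[str, tuple[int, int]]
    pitch_um: float = 700.0
    electrode_diameter_um: float = 100.0
    wells: int = 24

    def __post_init__(self) -> None:
        if len(set(self.positions.values())) != len(self.positions):
            raise ValueError("electrode grid positions must be unique")
        if self.pitch_um <= self.electrode_diameter_um:
            raise ValueError("electrode pitch must exceed electrode diameter")

    def distance_um(self, a: str, b: str) -> float:
        (ra, ca), (rb, cb) = self.positions[a], self.positions[b]
        return self.pitch_um * float(np.hypot(ra - rb, ca - cb))


@dataclass
class ActiveElectrodeMask:
    """Per-channel flag: electrode in contact with the organoid.

    Channels not in contact are excluded from all summaries, mirroring the
    visual-mapping step used when organoids are plated.
    """

    active: dict[str, bool]

    def __post_init__(self) -> None:
        if not any(self.active.values()):
            raise ValueError("at least one active electrode is required")

    def active_labels(self) -> list[str]:
        return [label for label, ok in self.active.items() if ok]

    def is_active(self, label: str) -> bool:
        return self.active.get(label, False)

    @classmethod
    def all_active(cls, labels: list[str]) -> "ActiveElectrodeMask":
        return cls({label: True for label in labels})


def default_electrode_map(n_channels: int = 12) -> ElectrodeMap:
    """12-electrode well layout as a 3 x 4 grid at 700 um pitch."""
    n_cols = 4
    positions = {
        f"ch{i + 1:02d}": (i // n_cols, i % n_cols) for i in range(n_channels)
    }
    return ElectrodeMap(positions=positions)
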