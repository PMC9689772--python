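"""Threshold-based event detection on filtered MEA traces.

Two event classes are detected, each on its own filtered view of the
recording:

* ``single_unit`` — stereotyped extracellular action potentials; detected on
  the 100-3500 Hz band at 5x the estimated noise SD.
* ``population``  — large, variable-amplitude population spikes; detected on
  the 1-3500 Hz band at 15x the estimated noise SD.

Detection is per active electrode with a per-channel threshold.  Only
negative-going excursions are detected (all observed event amplitudes are
negative); each event is timestamped at its negative-peak sample.  The noise
SD is estimated robustly (median absolute value / 0.6745) so embedded spikes
do not inflate the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ActiveElectrodeMask, Recording

__all__ = [
    "DetectedEvent",
    "EventSummary",
    "estimate_noise_sd",
    "detect_events",
    "summarize_events",
    "THRESHOLD_MULTIPLIERS",
    "DEAD_TIMES",
]

#: k in threshold = k x noise SD, per event class.
THRESHOLD_MULTIPLIERS = {"single_unit": 5.0, "population": 15.0}

#: Minimum separation between distinct events (s); excursions closer than
#: this are merged, keeping the larger |amplitude|.  Chosen from the event
#: template widths (~1 ms single-unit, ~5 ms population).
DEAD_TIMES = {"single_unit": 0.001, "population": 0.010}

#: Filter preset expected on the recording for each event class.
EXPECTED_FILTER = {"single_unit": "single_unit", "population": "population"}


@dataclass(frozen=True)
class DetectedEvent:
    """One threshold-crossing event.

    ``time`` is seconds at the negative peak; ``amplitude`` the signed peak
    voltage in uV (negative).
    """

    channel: str
    time: float
    amplitude: float
    event_class: str


@dataclass
class EventSummary:
    """Per-recording event statistics, pooled over active electrodes.

    ``events_per_minute`` and ``mean_amplitude`` are keyed by event class;
    a class with no events has rate 0 and mean amplitude ``None``.
    """

    channels: list[str]
    n_events: dict[str, int]
    events_per_minute: dict[str, float]
    mean_amplitude: dict[str, float | None]
    duration: float


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust noise-SD estimate: ``median(|x|) / 0.6745`` (uV).

    For zero-mean Gaussian noise this equals the SD; unlike the sample SD it
    is barely perturbed by embedded spikes, which occupy few samples but
    carry large amplitudes.  An all-constant trace returns 0 with a warning.
    """
    trace = np.asarray(trace, dtype=np.float64)
    est = float(np.median(np.abs(trace - np.median(trace))) / 0.6745)
    if est == 0.0:
        warnings.warn("degenerate (constant) trace: noise SD estimate is 0",
                      stacklevel=2)
    return est


def _detect_channel(
    trace: np.ndarray,
    threshold: float,
    dead_samples: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-excursion detection on one trace.

    Marks samples below ``-threshold``, groups contiguous runs, takes each
    run's minimum as a candidate event, then merges candidates closer than
    ``dead_samples`` keeping the more negative peak.  Returns (peak sample
    indices, peak amplitudes).
    """
    below = trace < -threshold
    if not below.any():
        return np.empty(0, dtype=np.intp), np.empty(0)
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [below.size]))

    peaks, amps = [], []
    for s, e in zip(starts, ends):
        i = s + int(np.argmin(trace[s:e]))
        peaks.append(i)
        amps.append(trace[i])

    merged_peaks: list[int] = []
    merged_amps: list[float] = []
    for i, a in zip(peaks, amps):
        if merged_peaks and i - merged_peaks[-1] < dead_samples:
            if a < merged_amps[-1]:  # more negative peak wins
                merged_peaks[-1], merged_amps[-1] = i, a
        else:
            merged_peaks.append(i)
            merged_amps.append(a)
    return np.asarray(merged_peaks, dtype=np.intp), np.asarray(merged_amps)


def detect_events(
    recording: Recording,
    mask: ActiveElectrodeMask,
    event_class: str,
    k: float | None = None,
    dead_time: float | None = None,
    check_filter: bool = True,
) -> list[DetectedEvent]:
    """Detect events of one class on every active channel.

    The recording must already be filtered with the class's standard preset
    (100-3500 Hz for ``single_unit``, 1-3500 Hz for ``population``); the
    filter history recorded by ``apply_filter`` is checked as a guard.  The
    per-channel threshold is ``k x`` the robust noise SD of that channel
    (k defaults to 5 for single-unit, 15 for population events).
    """
    if event_class not in THRESHOLD_MULTIPLIERS:
        raise ValueError(
            f"event_class must be one of {sorted(THRESHOLD_MULTIPLIERS)}, "
            f"got {event_class!r}"
        )
    if check_filter:
        expected = EXPECTED_FILTER[event_class]
        applied = [h.split(":")[0] for h in recording.filter_history]
        if not applied:
            warnings.warn(
                f"recording has no filter history; expected the {expected!r} "
                "preset to have been applied", stacklevel=2,
            )
        elif expected not in applied:
            raise ValueError(
                f"recording was filtered with {applied}, not the {expected!r} "
                f"preset required for {event_class} detection"
            )
    if k is None:
        k = THRESHOLD_MULTIPLIERS[event_class]
    if dead_time is None:
        dead_time = DEAD_TIMES[event_class]
    dead_samples = max(int(round(dead_time * recording.sampling_rate)), 1)

    events: list[DetectedEvent] = []
    for label in recording.channel_labels:
        if not mask.is_active(label):
            continue
        trace = recording.channel(label)
        noise_sd = estimate_noise_sd(trace)
        if noise_sd == 0.0:
            continue
        peaks, amps = _detect_channel(trace, k * noise_sd, dead_samples)
        events.extend(
            DetectedEvent(
                channel=label,
                time=recording.t0 + p / recording.sampling_rate,
                amplitude=float(a),
                event_class=event_class,
            )
            for p, a in zip(peaks, amps)
        )
    events.sort(key=lambda ev: (ev.time, ev.channel))
    return events


def summarize_events(
    events: list[DetectedEvent],
    duration: float,
    mask: ActiveElectrodeMask,
) -> EventSummary:
    """Pooled per-class event rate (events/min) and mean signed amplitude.

    Rates pool all active channels into one per-recording value.  Events on
    masked channels indicate a pipeline ordering bug and raise.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    bad = sorted({ev.channel for ev in events if not mask.is_active(ev.channel)})
    if bad:
        raise ValueError(f"events reference masked channels: {bad}")

    classes = sorted({ev.event_class for ev in events} | set(THRESHOLD_MULTIPLIERS))
    n_events: dict[str, int] = {}
    rate: dict[str, float] = {}
    mean_amp: dict[str, float | None] = {}
    minutes = duration / 60.0
    for cls in classes:
        cls_amps = [ev.amplitude for ev in events if ev.event_class == cls]
        n_events[cls] = len(cls_amps)
        rate[cls] = len(cls_amps) / minutes
        mean_amp[cls] = float(np.mean(cls_amps)) if cls_amps else None
    return EventSummary(
        channels=mask.active_labels(),
        n_events=n_events,
        events_per_minute=rate,
        mean_amplitude=mean_amp,
        duration=duration,
    )
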