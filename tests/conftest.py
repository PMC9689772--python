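"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from blastmea import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(
    traces: np.ndarray, sampling_rate: float = 10_000.0
) -> Recording:
    traces = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    labels = [f"ch{i + 1:02d}" for i in range(traces.shape[0])]
    return Recording(samples=traces, sampling_rate=sampling_rate, channel_labels=labels)


def brute_force_detect(
    trace: np.ndarray, threshold: float, dead_samples: int
) -> tuple[list[int], list[float]]:
    """Independent event-detection oracle: plain python scan.

    Mark every sample below -threshold, group runs that are contiguous or
    within the dead time of the previous event's peak, take each group's
    minimum.
    """
    peaks: list[int] = []
    amps: list[float] = []
    in_run = False
    run_min_idx = -1
    runs: list[int] = []  # candidate peak index per excursion
    for i, x in enumerate(trace):
        if x < -threshold:
            if not in_run:
                in_run = True
                run_min_idx = i
            elif x < trace[run_min_idx]:
                run_min_idx = i
        else:
            if in_run:
                runs.append(run_min_idx)
                in_run = False
    if in_run:
        runs.append(run_min_idx)
    for idx in runs:
        if peaks and idx - peaks[-1] < dead_samples:
            if trace[idx] < amps[-1]:
                peaks[-1] = idx
                amps[-1] = trace[idx]
        else:
            peaks.append(idx)
            amps.append(float(trace[idx]))
    return peaks, amps


def match_events(
    true_times: np.ndarray, detected_times: np.ndarray, tol: float = 0.001
) -> int:
    """Greedy one-to-one matching of detected to true event times."""
    true_times = np.sort(np.asarray(true_times))
    detected = sorted(detected_times)
    matched = 0
    used = np.zeros(len(detected), dtype=bool)
    det = np.asarray(detected)
    for t in true_times:
        if det.size == 0:
            break
        diffs = np.abs(det - t)
        diffs[used] = np.inf
        j = int(np.argmin(diffs))
        if diffs[j] <= tol:
            used[j] = True
            matched += 1
    return matched


def recall_precision(
    truth_by_channel: dict[str, np.ndarray],
    events,
    tol: float = 0.001,
) -> tuple[float, float]:
    """Recall and precision of detected events against ground truth."""
    det_by_channel: dict[str, list[float]] = {}
    for ev in events:
        det_by_channel.setdefault(ev.channel, []).append(ev.time)
    n_true = sum(t.size for t in truth_by_channel.values())
    n_det = sum(len(v) for v in det_by_channel.values())
    matched = sum(
        match_events(truth_by_channel.get(ch, np.empty(0)), times, tol)
        for ch, times in det_by_channel.items()
    )
    recall = matched / n_true if n_true else 1.0
    precision = matched / n_det if n_det else 1.0
    return recall, precision
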