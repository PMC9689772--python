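"""File formats: recording CSV/HDF5, event CSV, ground-truth and report JSON.

Recording CSV dialect (matching the acquisition software's export style):
header row ``time_s,ch01,...,chNN``; first column the time axis in seconds;
one column of microvolt samples per channel; UTF-8, decimal point, no
thousands separators.  The optional HDF5 container stores ``/samples`` and
``/time`` datasets with ``sampling_rate`` and ``channel_labels`` attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Recording
from .dose import DoseMetrics, PressureWaveform
from .events import DetectedEvent, EventSummary
from .synthetic import GroundTruth

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_recording_hdf5",
    "read_recording_hdf5",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_events_csv",
    "read_events_csv",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_json",
]


def write_recording_csv(recording: Recording, path: str | Path) -> None:
    """Write ``time_s,ch01..chNN`` CSV with >= 8 significant digits."""
    frame = pd.DataFrame(
        {"time_s": recording.time}
        | {lab: recording.samples[i] for i, lab in enumerate(recording.channel_labels)}
    )
    frame.to_csv(path, index=False, float_format="%.10g")


def read_recording_csv(path: str | Path) -> Recording:
    """Read a recording CSV written by :func:`write_recording_csv`.

    The sampling rate is inferred from the time column.  Malformed input
    (missing/unknown header, ragged rows, non-numeric cells, non-monotone
    time) raises with the offending line where it can be localized.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    if frame.columns.size < 2 or frame.columns[0] != "time_s":
        raise ValueError(
            f"{path}: expected header 'time_s,<channel>,...', got "
            f"{list(frame.columns[:3])}..."
        )
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r}, line {line}")
    time = frame["time_s"].to_numpy(dtype=np.float64)
    if time.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3  # +2 header/0-base, +1 second row
        raise ValueError(f"{path}: non-monotone time column at line {line}")
    labels = [str(c) for c in frame.columns[1:]]
    samples = frame[labels].to_numpy(dtype=np.float64).T
    sampling_rate = (time.size - 1) / (time[-1] - time[0])
    return Recording(
        samples=samples,
        sampling_rate=float(sampling_rate),
        channel_labels=labels,
        t0=float(time[0]),
    )


def write_recording_hdf5(recording: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=recording.samples)
        f.create_dataset("time", data=recording.time)
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["channel_labels"] = recording.channel_labels
        f.attrs["t0"] = recording.t0


def read_recording_hdf5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            samples=f["samples"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_labels=[str(s) for s in f.attrs["channel_labels"]],
            t0=float(f.attrs.get("t0", 0.0)),
        )


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "spike_times_by_channel": {
            cls: {ch: times.tolist() for ch, times in by_ch.items()}
            for cls, by_ch in truth.spike_times_by_channel.items()
        },
        "population_amplitudes": {
            ch: amps.tolist() for ch, amps in truth.population_amplitudes.items()
        },
        "oscillation_freq": truth.oscillation_freq,
        "oscillation_amplitude": truth.oscillation_amplitude,
        "coupling": truth.coupling,
        "seed": truth.seed,
        "channel_labels": truth.channel_labels,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        spike_times_by_channel={
            cls: {ch: np.asarray(t, dtype=np.float64) for ch, t in by_ch.items()}
            for cls, by_ch in payload["spike_times_by_channel"].items()
        },
        population_amplitudes={
            ch: np.asarray(a, dtype=np.float64)
            for ch, a in payload["population_amplitudes"].items()
        },
        oscillation_freq=payload["oscillation_freq"],
        oscillation_amplitude=payload["oscillation_amplitude"],
        coupling=payload["coupling"],
        seed=payload["seed"],
        channel_labels=payload["channel_labels"],
    )


def write_events_csv(events: list[DetectedEvent], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "channel": [ev.channel for ev in events],
            "time_s": [ev.time for ev in events],
            "amplitude_uV": [ev.amplitude for ev in events],
            "class": [ev.event_class for ev in events],
        }
    )
    frame.to_csv(path, index=False, float_format="%.10g")


def read_events_csv(path: str | Path) -> list[DetectedEvent]:
    frame = pd.read_csv(path)
    return [
        DetectedEvent(
            channel=str(r.channel),
            time=float(r.time_s),
            amplitude=float(r.amplitude_uV),
            event_class=str(getattr(r, "class")),
        )
        for r in frame.itertuples(index=False)
    ]


def write_waveform_csv(waveform: PressureWaveform, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": waveform.time, "pressure_kPa": waveform.pressure}
    ).to_csv(path, index=False, float_format="%.10g")


def read_waveform_csv(path: str | Path) -> PressureWaveform:
    frame = pd.read_csv(path)
    if list(frame.columns[:2]) != ["time_s", "pressure_kPa"]:
        raise ValueError(
            f"{path}: expected header 'time_s,pressure_kPa', got "
            f"{list(frame.columns[:2])}"
        )
    time = frame["time_s"].to_numpy(dtype=np.float64)
    pressure = frame["pressure_kPa"].to_numpy(dtype=np.float64)
    return PressureWaveform(
        time=time,
        pressure=pressure,
        loading_freq=float("nan"),
        nominal_peak=float(pressure.max()) if pressure.size else 0.0,
        duration=float(time[-1] - time[0]) if time.size > 1 else 0.0,
    )


def _jsonable(obj):
    if isinstance(obj, (EventSummary, DoseMetrics)) or dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    """Serialize summaries / reports (dataclasses, arrays) to JSON."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))
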