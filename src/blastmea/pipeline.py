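"""End-to-end experiment orchestration.

``run_pipeline`` sequences the full analysis for a synthetic (or loaded)
exposure experiment: generate/load recordings -> band-pass condition ->
detect single-unit and population events -> epoch power spectra ->
channel-pair phase synchrony -> exposure dosimetry -> control-normalized
group statistics.  The result bundle is a pure function of (config, seed):
a manifest records the seed and a hash of the configuration so reruns can
be verified bit-for-bit.

Group design mirrors the exposure experiments: a no-blast control plus
loading-frequency groups (low 500 Hz / mid 3000 Hz / high 5000 Hz) at one
or two peak amplitudes (250 / 350 kPa), n organoids per group, with
timepoint (1 h / 24 h) carried as a plain group label.  Synthetic group
differences are injected by per-group overrides of the generator
parameters; by default all groups share the same generator settings (a null
experiment).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np

from .core import ActiveElectrodeMask, default_electrode_map
from .dose import integrate_overpressure
from .events import detect_events, summarize_events
from .filters import apply_filter, standard_specs
from .spectral import compute_psd, normalize_to_control, select_epoch
from .stats import chi_squared_counts, one_way_anova_tukey, summarize_group
from .synchrony import morlet_phase, pair_select, synchrony_index
from .synthetic import SynthConfig, generate_pressure_waveform, generate_recording

__all__ = [
    "GroupSpec",
    "RunConfig",
    "PipelineStageError",
    "default_run_config",
    "run_pipeline",
]

logger = logging.getLogger("blastmea")

LOADING_FREQS = {"low": 500.0, "mid": 3000.0, "high": 5000.0}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``partial`` holds results produced so far."""

    def __init__(self, stage: str, message: str, partial: dict | None = None):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.partial = partial or {}


@dataclass
class GroupSpec:
    """One experimental group.

    ``loading_freq`` / ``peak`` are None for the no-blast control.
    ``synth_overrides`` replaces fields of the base generator config for
    this group (how synthetic exposure effects are injected).
    """

    label: str
    loading_freq: float | None = None
    peak: float | None = None
    timepoint: str = "1h"
    n_organoids: int = 12
    synth_overrides: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    seed: int = 0
    groups: list[GroupSpec] = field(default_factory=list)
    control_label: str = "control"
    base_synth: SynthConfig = field(default_factory=SynthConfig)
    active_channels: list[str] | None = None     # None => all channels active
    epoch_length_spectral: float = 5.0           # s
    epoch_length_synchrony: float = 2.0          # s
    probe_freq: float = 10.0                     # Hz
    synchrony_pair: tuple[str, str] | None = None
    grubbs_alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def default_run_config(
    seed: int = 0,
    n_organoids: int = 12,
    duration: float = 120.0,
    peaks: tuple[float, ...] = (250.0,),
) -> RunConfig:
    """Standard design: no-blast control + low/mid/high at each peak."""
    base = SynthConfig(duration=duration)
    groups = [GroupSpec(label="control", n_organoids=n_organoids)]
    for peak in peaks:
        for name, freq in LOADING_FREQS.items():
            label = f"{name}_{int(peak)}kPa" if len(peaks) > 1 else name
            groups.append(
                GroupSpec(
                    label=label,
                    loading_freq=freq,
                    peak=peak,
                    n_organoids=n_organoids,
                )
            )
    return RunConfig(seed=seed, groups=groups, base_synth=base)


def _organoid_seed(root_seed: int, group_idx: int, organoid_idx: int) -> int:
    ss = np.random.SeedSequence(
        entropy=root_seed, spawn_key=(group_idx, organoid_idx)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _analyze_organoid(
    config: RunConfig, group: GroupSpec, seed: int
) -> dict:
    """Full per-organoid analysis -> scalar metrics."""
    synth = dataclasses.replace(config.base_synth, **group.synth_overrides)
    recording, truth = generate_recording(synth, seed)
    labels = recording.channel_labels
    if config.active_channels is None:
        mask = ActiveElectrodeMask.all_active(labels)
    else:
        mask = ActiveElectrodeMask(
            {lab: lab in config.active_channels for lab in labels}
        )

    specs = standard_specs()
    su = detect_events(
        apply_filter(recording, specs["single_unit"]), mask, "single_unit"
    )
    pop = detect_events(
        apply_filter(recording, specs["population"]), mask, "population"
    )
    summary = summarize_events(su + pop, recording.duration, mask)

    epoch_seed = seed + 1
    peak_powers = []
    for lab in mask.active_labels():
        epoch = select_epoch(
            recording, config.epoch_length_spectral, seed=epoch_seed, channel=lab
        )
        peak_powers.append(compute_psd(recording, epoch).band_peak_power)

    electrode_map = default_electrode_map(recording.n_channels)
    pair = pair_select(electrode_map, mask, override=config.synchrony_pair)
    sync_epoch = select_epoch(
        recording, config.epoch_length_synchrony, seed=epoch_seed + 1
    )
    phases = [
        morlet_phase(recording, ch, sync_epoch, probe_freq=config.probe_freq)
        for ch in pair
    ]
    sync = synchrony_index(*phases)

    return {
        "seed": seed,
        "single_unit_rate_per_min": summary.events_per_minute["single_unit"],
        "single_unit_mean_amplitude_uV": summary.mean_amplitude["single_unit"],
        "population_rate_per_min": summary.events_per_minute["population"],
        "population_mean_amplitude_uV": summary.mean_amplitude["population"],
        "has_population_events": summary.n_events["population"] > 0,
        "band_peak_power_uV2_per_Hz": float(np.mean(peak_powers)),
        "synchrony_index": sync.index,
        "synchrony_pair": list(pair),
        "n_true_single_unit": truth.n_events("single_unit"),
        "n_true_population": truth.n_events("population"),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full experiment and return the result bundle.

    The bundle contains per-organoid metrics, per-group mean +/- SEM tables
    (raw and percent-of-control), exposure dose metrics, omnibus ANOVA /
    chi-squared reports, and a reproducibility manifest.  Stage failures
    raise :class:`PipelineStageError` carrying partial results.
    """
    if not config.groups:
        raise PipelineStageError("configure", "no groups defined")
    t_start = _time.time()
    bundle: dict = {"organoids": {}, "groups": {}, "dose": {}, "tests": {}}

    for gi, group in enumerate(config.groups):
        rows = []
        for oi in range(group.n_organoids):
            seed = _organoid_seed(config.seed, gi, oi)
            t0 = _time.time()
            try:
                rows.append(_analyze_organoid(config, group, seed))
            except Exception as exc:
                raise PipelineStageError(
                    "analyze_organoid",
                    f"group {group.label!r} organoid {oi}: {exc}",
                    partial=bundle,
                ) from exc
            logger.info(
                "group=%s organoid=%d seed=%d elapsed=%.2fs",
                group.label, oi, seed, _time.time() - t0,
            )
        bundle["organoids"][group.label] = rows

        if group.loading_freq is not None and group.peak is not None:
            waveform = generate_pressure_waveform(group.loading_freq, group.peak)
            bundle["dose"][group.label] = integrate_overpressure(waveform)

    metrics = [
        "single_unit_rate_per_min",
        "population_rate_per_min",
        "band_peak_power_uV2_per_Hz",
        "synchrony_index",
    ]
    control_rows = bundle["organoids"].get(config.control_label)
    try:
        for metric in metrics:
            per_group = {
                g.label: np.array(
                    [row[metric] for row in bundle["organoids"][g.label]],
                    dtype=np.float64,
                )
                for g in config.groups
            }
            control = per_group.get(config.control_label)
            table = {}
            for label, values in per_group.items():
                use_control = (
                    control
                    if control is not None and control.mean() > 0
                    else None
                )
                table[label] = summarize_group(
                    label, values, control_values=use_control,
                    grubbs_alpha=config.grubbs_alpha,
                )
            bundle["groups"][metric] = table
            if len(per_group) >= 2 and all(v.size >= 2 for v in per_group.values()):
                bundle["tests"][metric] = one_way_anova_tukey(
                    list(per_group.values()), labels=list(per_group)
                )
    except Exception as exc:
        raise PipelineStageError("group_stats", str(exc), partial=bundle) from exc

    # presence/absence of population events -> chi-squared path
    counts = []
    for g in config.groups:
        rows = bundle["organoids"][g.label]
        with_events = sum(r["has_population_events"] for r in rows)
        counts.append([with_events, len(rows) - with_events])
    contingency = np.array(counts).T  # 2 x n_groups
    if contingency.shape[1] >= 2 and np.all(contingency.sum(axis=0) > 0):
        row_margins = contingency.sum(axis=1)
        if np.all(row_margins > 0):
            bundle["tests"]["population_presence"] = chi_squared_counts(contingency)
        else:
            bundle["tests"]["population_presence"] = None
    bundle["population_presence_table"] = {
        "groups": [g.label for g in config.groups],
        "with_events": contingency[0].tolist(),
        "without_events": contingency[1].tolist(),
    }

    bundle["manifest"] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_groups": len(config.groups),
        "n_organoids": int(sum(g.n_organoids for g in config.groups)),
        "control_label": config.control_label,
        "elapsed_s": round(_time.time() - t_start, 3),
    }
    _ = control_rows
    return bundle
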