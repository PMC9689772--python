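"""Event detection: robust noise estimate, thresholding, oracle equivalence."""

import numpy as np
import pytest

from blastmea import (
    ActiveElectrodeMask,
    DetectedEvent,
    SynthConfig,
    apply_filter,
    detect_events,
    estimate_noise_sd,
    generate_recording,
    standard_specs,
    summarize_events,
)
from blastmea.events import DEAD_TIMES, _detect_channel
from conftest import brute_force_detect, make_recording, recall_precision


def spike_config(**kw) -> SynthConfig:
    base = dict(
        duration=30.0, n_channels=3, noise_sd=4.0, spike_amplitude=-40.0,
        spike_rate=1.0, population_rate=0.0, oscillation_amplitude=0.0,
    )
    base.update(kw)
    return SynthConfig(**base)


class TestNoiseEstimate:
    def test_gaussian_noise_recovered(self, rng):
        trace = rng.normal(0.0, 5.0, size=100_000)
        assert estimate_noise_sd(trace) == pytest.approx(5.0, rel=0.03)

    def test_all_zero_trace_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert estimate_noise_sd(np.zeros(10_000)) == 0.0

    def test_robust_to_embedded_spikes(self, rng):
        # 50 large spikes inflate the sample SD but barely move the
        # median-based estimate
        trace = rng.normal(0.0, 5.0, size=100_000)
        idx = rng.choice(trace.size, size=50, replace=False)
        trace[idx] = -100.0
        assert estimate_noise_sd(trace) == pytest.approx(5.0, rel=0.05)
        # contaminated variance 25 + (50/1e5)*100^2 => SD ~5.47, ~9% inflated
        assert trace.std() > 5.0 * 1.08


class TestDetectChannel:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        trace = rng.normal(0.0, 1.0, size=100_000)
        trace[rng.choice(trace.size, 200, replace=False)] -= 8.0
        threshold, dead = 5.0, 10
        peaks, amps = _detect_channel(trace, threshold, dead)
        oracle_peaks, oracle_amps = brute_force_detect(trace, threshold, dead)
        assert peaks.tolist() == oracle_peaks
        assert amps.tolist() == pytest.approx(oracle_amps)

    def test_monotone_in_threshold_multiple(self, rng):
        trace = rng.normal(0.0, 1.0, size=50_000)
        counts = [
            _detect_channel(trace, k * 1.0, 10)[0].size
            for k in (2.0, 3.0, 4.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDetectEvents:
    def test_pure_noise_has_no_population_events(self):
        config = spike_config(spike_rate=0.0)
        recording, _ = generate_recording(config, seed=11)
        filtered = apply_filter(recording, standard_specs()["population"])
        mask = ActiveElectrodeMask.all_active(recording.channel_labels)
        events = detect_events(filtered, mask, "population")
        assert len(events) == 0

    def test_recall_precision_at_10sd_snr(self):
        # -40 uV spikes over 4 uV noise = 10 SD; detection at k=5
        recording, truth = generate_recording(spike_config(), seed=7)
        filtered = apply_filter(recording, standard_specs()["single_unit"])
        mask = ActiveElectrodeMask.all_active(recording.channel_labels)
        events = detect_events(filtered, mask, "single_unit")
        recall, precision = recall_precision(truth.all_times("single_unit"), events)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_10sd_spikes_invisible_at_k15_but_population_detected(self):
        config = spike_config(
            population_rate=0.2, population_amplitude_range=(-120.0, -120.0)
        )
        recording, truth = generate_recording(config, seed=13)
        filtered = apply_filter(recording, standard_specs()["population"])
        mask = ActiveElectrodeMask.all_active(recording.channel_labels)
        events = detect_events(filtered, mask, "population")
        # every detection matches a -120 uV population event, none a -40 uV spike
        recall, precision = recall_precision(
            truth.all_times("population"), events, tol=0.002
        )
        assert precision >= 0.95
        assert recall >= 0.9
        assert len(events) < truth.n_events("single_unit") / 2

    def test_recall_non_decreasing_in_snr(self):
        recalls = []
        for snr in (4.0, 6.0, 8.0, 10.0):
            config = spike_config(
                noise_sd=4.0, spike_amplitude=-snr * 4.0, n_channels=2
            )
            recording, truth = generate_recording(config, seed=21)
            filtered = apply_filter(recording, standard_specs()["single_unit"])
            mask = ActiveElectrodeMask.all_active(recording.channel_labels)
            events = detect_events(filtered, mask, "single_unit")
            recall, _ = recall_precision(truth.all_times("single_unit"), events)
            recalls.append(recall)
        assert recalls == sorted(recalls)
        assert recalls[-1] >= 0.95

    def test_mismatched_filter_guard(self):
        recording, _ = generate_recording(spike_config(duration=5.0), seed=1)
        filtered = apply_filter(recording, standard_specs()["population"])
        mask = ActiveElectrodeMask.all_active(recording.channel_labels)
        with pytest.raises(ValueError, match="single_unit"):
            detect_events(filtered, mask, "single_unit")

    def test_unfiltered_recording_warns(self):
        recording, _ = generate_recording(spike_config(duration=5.0), seed=1)
        mask = ActiveElectrodeMask.all_active(recording.channel_labels)
        with pytest.warns(UserWarning, match="filter history"):
            detect_events(recording, mask, "single_unit")

    def test_masked_channels_skipped(self):
        recording, _ = generate_recording(spike_config(duration=10.0), seed=5)
        filtered = apply_filter(recording, standard_specs()["single_unit"])
        mask = ActiveElectrodeMask(
            {lab: lab == "ch01" for lab in recording.channel_labels}
        )
        events = detect_events(filtered, mask, "single_unit")
        assert {ev.channel for ev in events} <= {"ch01"}

    def test_dead_time_merges_nearby_excursions(self):
        trace = np.zeros(10_000)
        noise = np.random.default_rng(0).normal(0, 1.0, size=trace.size)
        trace += noise
        trace[5000] = -30.0
        trace[5005] = -40.0  # 0.5 ms later: merged, larger peak kept
        peaks, amps = _detect_channel(
            trace, 5.0, int(DEAD_TIMES["single_unit"] * 10_000)
        )
        assert 5005 in peaks.tolist()
        assert 5000 not in peaks.tolist()


class TestSummarize:
    def make_events(self, n, cls="single_unit", channel="ch01"):
        return [
            DetectedEvent(channel=channel, time=i * 0.5, amplitude=-20.0, event_class=cls)
            for i in range(n)
        ]

    def test_rate_is_events_per_minute(self):
        mask = ActiveElectrodeMask({"ch01": True})
        summary = summarize_events(self.make_events(120), duration=120.0, mask=mask)
        assert summary.events_per_minute["single_unit"] == pytest.approx(60.0)
        assert summary.n_events["single_unit"] == 120

    def test_empty_list_rate_zero_amplitude_absent(self):
        mask = ActiveElectrodeMask({"ch01": True})
        summary = summarize_events([], duration=60.0, mask=mask)
        assert summary.events_per_minute["single_unit"] == 0.0
        assert summary.mean_amplitude["single_unit"] is None

    def test_classes_partition_total(self):
        mask = ActiveElectrodeMask({"ch01": True})
        events = self.make_events(10) + self.make_events(4, cls="population")
        summary = summarize_events(events, duration=60.0, mask=mask)
        assert summary.n_events["single_unit"] + summary.n_events["population"] == 14

    def test_event_on_masked_channel_is_pipeline_bug(self):
        mask = ActiveElectrodeMask({"ch01": True, "ch02": False})
        with pytest.raises(ValueError, match="ch02"):
            summarize_events(
                self.make_events(1, channel="ch02"), duration=60.0, mask=mask
            )
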