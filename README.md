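# blastmea

Analysis pipeline for multi-electrode-array (MEA) recordings from
blast-overpressure experiments on cerebral organoids.

Controlled pressure exposures — raised-cosine loading cycles at 500 / 3000 /
5000 Hz reaching 250 or 350 kPa for 8 ms — are one way to study the primary
(pressure-only) component of blast traumatic brain injury *in vitro*.
Organoids are recorded on 12-electrode MEA wells (10 kHz sampling, 2 min
recordings), and the neurophysiological readouts are: single-unit and
population event rates and amplitudes, sub-10 Hz network-oscillation power,
and phase synchrony between neighboring electrodes. This package implements
that full analysis as a tested, reusable library plus CLI, for
electrophysiologists who have MEA exports (CSV/HDF5) and exposure
parameters, and for anyone who wants to probe the analysis itself on
synthetic data with exact ground truth.

## What it computes

* **Event detection** — per active electrode, negative threshold crossing at
  `k x sigma_noise` with `sigma_noise = median(|x|)/0.6745`: single-unit
  events at `k = 5` on the 100–3500 Hz band, population spikes at `k = 15`
  on the 1–3500 Hz band (second-order zero-phase Butterworth filters).
* **Spectral power** — untapered periodogram of a random 5 s epoch;
  *band peak power* = power at the largest local PSD maximum strictly inside
  (0, 10) Hz; values normalized to the control-group mean; spectrograms
  (1 s Hann, 50% overlap).
* **Phase synchrony** — complex Morlet wavelet (default 10 Hz probe,
  7 cycles) gives per-sample phase `phi(t)`; the synchrony index is the
  phase-locking value `PLV = |<e^{i(phi_a - phi_b)}>|` in [0, 1] for the
  closest pair of active electrodes.
* **Pressure dosimetry** — trapezoidal integrated overpressure (kPa·ms) of
  the non-negative loading cycle, plus the quasi-hydrostatic check: a 30 mm
  water-filled chamber homogenizes in `L/c ≈ 20 µs` (characteristic
  frequency ≈ 50 kHz, ~10× the fastest 5 kHz loading).
* **Group statistics** — mean ± SEM after iterative Grubbs exclusion,
  percent-of-control / percent-difference normalization, Student/Welch
  t-test, one-way ANOVA + Tukey HSD, and Pearson chi-squared for
  presence/absence counts when controls measure zero.
* **Synthetic data** — `generate_recording` produces MEA recordings with
  Gaussian noise, stereotyped biphasic spikes at Poisson times, sparse
  variable-amplitude population spikes, and a sub-10 Hz oscillation with a
  tunable cross-channel phase-coupling knob — together with exact ground
  truth, so detection recall/precision and synchrony recovery can be scored.

## Worked example

```python
from blastmea import (SynthConfig, generate_recording, apply_filter,
    standard_specs, ActiveElectrodeMask, detect_events, summarize_events,
    select_epoch, compute_psd, default_electrode_map, pair_select,
    morlet_phase, synchrony_index, generate_pressure_waveform,
    integrate_overpressure)

config = SynthConfig(duration=60.0, coupling=0.9)
recording, truth = generate_recording(config, seed=7)
mask = ActiveElectrodeMask.all_active(recording.channel_labels)

filtered = apply_filter(recording, standard_specs()["single_unit"])
events = detect_events(filtered, mask, "single_unit")
summary = summarize_events(events, recording.duration, mask)

epoch = select_epoch(recording, 5.0, seed=7)
psd = compute_psd(recording, epoch)

pair = pair_select(default_electrode_map(), mask)
sync_epoch = select_epoch(recording, 2.0, seed=8)
pa, pb = (morlet_phase(recording, ch, sync_epoch, probe_freq=6.0) for ch in pair)

dose = integrate_overpressure(generate_pressure_waveform(5000.0, 250.0))
```

prints (via the obvious `print` statements):

```
single-unit events: 804 (804.0/min, mean amplitude -25.90 uV)
band peak power: 952.9 uV^2/Hz at 6.0 Hz
synchrony index (ch01-ch02): 0.985
integrated overpressure: 1000 kPa*ms (peak 250 kPa, mean 125 kPa)
```

Reading the numbers: 12 channels at the default 1 Hz per-channel spike rate
over 60 s yield ~720 expected spikes (804 observed events pool true spikes
and the sparse population spikes that also cross the 5 SD threshold); the
mean amplitude sits near the configured −25 µV template. The 6 Hz network
oscillation dominates the (0, 10) Hz band, and with coupling 0.9 the two
closest electrodes are nearly phase-locked (PLV 0.985). The 250 kPa / 8 ms
raised-cosine burst integrates to exactly `peak x duration / 2 = 1000`
kPa·ms regardless of loading frequency.

The same stages are exposed as a CLI:

```bash
blastmea --seed 7 --out-dir out simulate --duration 60
blastmea --out-dir out detect out/recording.csv --event-class single_unit
blastmea --out-dir out dose --synthetic 5000,250,0.008
blastmea --seed 7 --out-dir out run --n-organoids 6 --duration 60
```

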