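# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Recording model and conditioning

A `Recording` is a channels × time matrix of extracellular voltage (µV)
with a sampling rate (default 10 kHz, matching the acquisition system the
pipeline targets) and channel labels. Analyses exclude electrodes not in
contact with tissue via an `ActiveElectrodeMask`; the electrode grid is a
3 × 4 layout of 12 electrodes at 700 µm pitch per well.

All filtering uses second-order Butterworth designs applied forward and
backward (`sosfiltfilt`), so the effective magnitude response is |H(f)|²
and the group delay cancels — detected event times are not shifted relative
to the raw signal, which is what makes recall/precision scoring against
ground-truth event times meaningful. Three presets cover the pipeline:
100–3500 Hz (single-unit detection), 1–3500 Hz (population detection), and
a 10 Hz low-pass for the network-oscillation band. A "0 Hz low cut" is
treated as a pure low-pass: a genuine 0 Hz band-pass edge is degenerate.
Edges are reflect-padded (3× the section settling length); the first and
last 50 ms are flagged as untrusted for event detection. Line-noise
filtering is deliberately absent.

## Event detection

Per active channel, the noise SD is estimated robustly as
`median(|x − median(x)|)/0.6745`, which equals the SD for Gaussian noise
but is barely perturbed by embedded spikes (the plain sample SD is inflated
~9% by 50 spikes of −100 µV in a 10 s trace of 5 µV noise; the robust
estimate moves <5%). Events are negative-going excursions beyond
`−k·sigma`: k = 5 for single-unit events, k = 15 for population spikes.
Each excursion is timestamped at its negative-peak sample with that peak's
signed amplitude; excursions closer than a dead time (1 ms single-unit,
10 ms population — chosen from the respective template widths) are merged,
keeping the larger |amplitude|. Detection is negative-polarity only because
all reported event amplitudes in this preparation are negative.

Thresholds are per-channel (noise varies across electrodes); rates are
pooled across active channels into one events/min value per recording, as
a per-organoid summary. Detection on traces is verified against an
independent brute-force scan (mark samples below threshold, group runs,
take minima, merge within dead time) and against generator ground truth:
at 10 SD spike SNR and k = 5, recall and precision exceed 0.95 with ±1 ms
matching tolerance, while the same spikes are invisible at k = 15.

## Spectral analysis

Power spectra are untapered one-sided periodograms of a demeaned epoch
(default 5 s, drawn uniformly at random from the recording under a seed).
No taper is applied to the epoch itself, so Parseval holds exactly
(`sum(PSD)·df` = epoch variance); the spectrogram view uses a 1 s Hann
window at 50% overlap to resolve the sub-10 Hz band at ~1 Hz resolution.
The *band peak power* is the power at the most powerful local maximum of
the PSD strictly inside (0, 10) Hz — DC excluded — using a minimum peak
prominence of 5% of the in-band maximum to avoid declaring noise ripples
as peaks; when no local maximum qualifies, the in-band maximum is used and
flagged. Per-organoid values average the band peak power over active
channels. Group values divide by the mean of the matching control group,
so normalized controls average exactly 1.

## Phase synchrony

Instantaneous phase comes from convolving the raw (unfiltered) epoch with
a complex Morlet wavelet at the probe frequency (default 10 Hz, the top of
the oscillation band; 7 cycles, i.e. Gaussian SD `7/(2π·10) ≈ 0.11 s`, a
standard time–frequency compromise). The synchrony index is the
phase-locking value `PLV = |mean(e^{i·Δphi})|`, which is 1 iff the phase
difference is constant (a constant offset still counts as perfect locking)
and O(1/√n) for unrelated phases. Samples within 3 wavelet SDs of each
epoch edge are discarded before averaging to remove convolution edge bias.
The analyzed pair is the two active electrodes at minimum grid distance
(ties broken by channel order), or an explicitly configured pair.

Two epoch conventions circulate for this analysis — 2 s raw-signal epochs,
and 5 s epochs low-pass filtered below 10 Hz before phase extraction. The
pipeline defaults to 2 s on the raw signal and keeps the 10 Hz low-pass
preset available as a separate, explicit path; both are configurable and
neither is asserted to be canonical.

## Pressure dosimetry

Exposures are idealized raised-cosine bursts
`p(t) = (peak/2)(1 − cos 2π f t)` over 8 ms: strictly non-negative
(no ultrasound-style negative phase), complete cycles, time average
`peak/2` independent of loading frequency — so exposures at 500, 3000 and
5000 Hz with equal peak deliver the same mean pressure. The integrated
overpressure is the trapezoidal time integral, reported in kPa·ms (a unit
choice logged in output; `integral = mean pressure × duration` by
construction). On whole cycles the trapezoid rule is spectrally accurate;
its generic second-order convergence is demonstrated on a quarter-cycle
segment where the endpoint slope is nonzero.

The quasi-hydrostatic argument: pressure changes traverse the 30 mm
chamber at the speed of sound in water (1480 m/s), homogenizing in
`L/c ≈ 20 µs`, a characteristic frequency of ≈ 49.3 kHz. The check passes
when this frequency, rounded to one significant figure (50 kHz), is at
least 10× the loading frequency; the exact ratio (9.87 at 5 kHz) is always
reported alongside the rounded verdict.

## Group statistics

Groups are labeled by exposure frequency (control/low/mid/high), peak
amplitude (250/350 kPa) and timepoint (1 h/24 h, carried as a plain label —
no temporal modeling). Summaries are mean ± SEM (`sd/√n` over retained
values) after iterative two-sided Grubbs exclusion at α = 0.05 (one removal
per iteration, t-distribution critical value, no-op for n < 3 or zero
variance). Normalization is percent-of-control (100 × value / control
mean) when the control mean is positive; otherwise percent difference from
baseline, and when the baseline itself is zero the values are flagged to
the chi-squared route: organoids are dichotomized by presence/absence of
population events into a 2 × k count table and tested with Pearson's
chi-squared (no continuity correction, df = (r−1)(k−1); a 2 × 8 layout
gives df = 7). Omnibus comparisons use one-way ANOVA with Tukey HSD
(studentized range); two-group comparisons use Student's t by default with
Welch available by flag. ANOVA type-I error is verified at 0.05 ± 0.01
under the null by simulation.

## Synthetic data generator

`generate_recording(config, seed)` is a pure function emulating the
statistical structure of organoid MEA data:

* **Noise**: iid zero-mean Gaussian, default SD 2.5 µV. The hardware
  acquisition band-pass is *not* re-applied, so the sample SD of
  event-free segments equals the configured value exactly; apply the
  1–3500 Hz preset to emulate the acquisition band when needed.
* **Single-unit spikes**: a stereotyped biphasic template (sharp negative
  lobe, 25% positive rebound, 1 ms width — conventions, since real spike
  waveform parameters are not published) scaled to −25 µV (10 SD over the
  default noise), at homogeneous Poisson times (default 1 event/s per
  channel) thinned to ≥ 2 ms separation so every ground-truth event maps
  to one unambiguous threshold excursion.
* **Population spikes**: a wider (5 ms) template with per-event amplitude
  drawn uniformly from 1.5–3× the single-unit amplitude, sparse (default
  0.1 event/s per channel).
* **Network oscillation**: a shared sinusoid (default 20 µV at 6 Hz) with
  per-channel phase `2π f t + (1 − coupling)·J_i(t)`, where `J_i` is a
  mean-reverting (Ornstein–Uhlenbeck) phase walk with stationary SD
  2.2 rad and correlation time 0.3 s. Mean reversion is essential: an
  unbounded random walk drives the pair PLV to the null for *any*
  coupling < 1 once the walk wanders beyond ~2π within the epoch, leaving
  no usable intermediate regime, whereas the OU model gives
  `PLV ≈ exp(−((1−c)·2.2)²)` asymptotically — a smooth, monotone knob.
  The (SD, τ) pair was fixed once so that the coupling grid
  {0, 0.25, 0.5, 0.75, 1} spans the index range under the default
  oscillation and noise amplitudes (measured means ≈ 0.10 / 0.29 / 0.60 /
  0.89 / 1.0 on 30 s epochs).

Ground truth records every injected event time (at the template's negative
peak), drawn population amplitudes and the oscillation parameters;
identical `(config, seed)` yields bit-identical recordings.

What the generator does **not** emulate: electrode drift and artifacts,
non-Gaussian or correlated noise, spike waveform variability and unit
overlap, amplitude attenuation with electrode–tissue distance, bursting
structure and non-stationarity, and any biophysics of the pressure–tissue
interaction. Passing tests therefore demonstrate that the *analysis* is
correct and calibrated on data with known structure — not that real
recordings satisfy these statistical assumptions, and not any biological
effect size.

## Orchestration and reproducibility

`run_pipeline` analyzes a group design (control plus exposure groups, n
organoids each): per organoid it generates a recording from a
deterministic per-organoid seed (derived from the root seed via
`SeedSequence(root, spawn_key=(group, organoid))`), detects both event
classes, averages band peak power across active channels, computes the
pair synchrony index, and then builds group tables (raw and
percent-of-control), dose metrics per exposure, omnibus ANOVA/Tukey per
metric, and the population-presence chi-squared table. The bundle carries
a manifest with the seed and a SHA-256 hash of the full configuration; all
numeric outputs are a pure function of (config, seed). Synthetic group
differences are injected by per-group overrides of generator parameters;
the default design is a null experiment.

## Problem sizes in the test suite

The suite exercises deliberately scaled problem sizes chosen to make the
statistical assertions sharp while keeping the default run quick: detection
oracle checks use 100 traces of 10⁵ samples; synchrony calibration uses
30 s two-channel recordings (5 seeds per coupling level) and 200-draw null
ensembles at n = 20 000; ANOVA calibration uses 10⁴ simulated experiments;
the end-to-end reproducibility check runs 7 groups × 6 organoids × 60 s
recordings twice. `scripts/acceptance.py` recomputes the same quantities
at comparable sizes from a user-supplied seed.

## Known limitations

* The peak-prominence rule (5% of in-band max) and the dead times are
  conventions; vendor analysis software may timestamp at threshold
  crossing rather than peak, and may aggregate channels differently
  (pooled rates are used here).
* The synchrony index is computed on a single epoch per recording;
  averaging over sub-windows would reduce variance but is not done.
* Percent-difference normalization with near-zero baselines is unstable by
  construction; the chi-squared path exists precisely for that regime.
* Idealized raised-cosine exposures do not represent the multi-frequency,
  decaying pressure transients of real blast; they are discrete samples of
  a frequency–amplitude space.
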