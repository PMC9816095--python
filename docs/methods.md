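# Methods

This note documents the models and procedures implemented in `ecosyn`, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic benchmark does and does not establish about real recordings.

## Experiment model

A recording is a single-channel ECoG voltage trace (µV) on an experiment
clock anchored at the scopolamine injection (t = 0). The protocol timeline
defaults to pilocarpine at 1800 s and 3600 s, diazepam at 7200 s, and a
static magnet (or sham replica) on the skull over [0, 3600] s. Recordings
may begin before t = 0; the hour before scopolamine is the baseline.
Analyses use three phase windows — baseline = [scopolamine − 3600,
scopolamine), prediazepam = [pilocarpine₂, diazepam), postdiazepam =
[diazepam, diazepam + 3600) — clipped to the recorded span and flagged
partial when clipped, plus 60-s epochs cut every 30 min for time courses.
Phase membership of an epoch is decided by its start time with half-open,
start-inclusive intervals, so an epoch never straddles two phases. Epochs
that would run past the end of the recording are dropped.

All event onsets (ground truth and detections) are in seconds from the start
of the recording they refer to, which keeps them non-negative even when the
recording starts before t = 0; `Recording.t0` converts to the experiment
clock.

## Signal conditioning

Acquisition-rate traces (20 kHz in the modeled setup) are brought to the
1 kHz analysis rate by zero-phase low-pass filtering (8th-order Butterworth,
cutoff 0.4 × target rate) followed by integer decimation; non-integer ratios
are rejected rather than resampled, keeping the operation exactly invertible
in tests. All band-pass filtering is 4th-order Butterworth applied
forward–backward (`sosfiltfilt`), so filtered events keep their latencies;
the effective amplitude response is the squared single-pass response, which
the tests use as the oracle for pass-band attenuation.

## Spike detection

The criterion is a discharge lasting ≥ 0.3 s with amplitude ≥ 2× baseline.
Neither "amplitude" nor "baseline" has a unique operationalisation, so:
amplitude is the Hilbert-envelope magnitude (polarity-free and well defined
for oscillatory discharges), and baseline is the median envelope of a
pre-injection epoch (robust to occasional baseline transients). Contiguous
supra-threshold envelope runs separated by less than 50 ms are merged before
the duration test, so one discharge is not split at its internal zero
crossings; 50 ms is shorter than the half-period of any discharge component
the generator produces and longer than envelope ripple. Detections scale-
invariantly track the signal: multiplying signal and baseline by the same
constant leaves them unchanged.

## Ripple detection

The criterion is ≥ 4 consecutive peaks above mean + 3 SD of the 80–200 Hz
band-passed signal. The threshold statistics are computed over the analysis
window being scanned (a per-phase window in the pipeline), so they track
amplitude differences between phases; within a window the generator keeps
the background variance stationary (see below). Peaks are counted on the
signed filtered signal — one peak per oscillation cycle. Counting rectified
peaks (both polarities) was evaluated and rejected: for a Gaussian-like
background the envelope only needs to stay above threshold for two carrier
periods to produce four rectified peaks, and the resulting chance trains
arrive at a rate comparable to the true ripple rate, making the stated
precision target unreachable; with signed peaks a chance train requires four
full periods above threshold and is rare. "Consecutive" means an inter-peak
gap of at most two 80 Hz periods (25 ms): one period because signed peaks of
the slowest in-band carrier are 12.5 ms apart, plus one period so that a
single peak lost to destructive interference with the background does not
split a train. The event's mean frequency is the reciprocal of the mean
inter-peak interval, excluding intervals ≥ 1.5× the train median (those are
single-peak dropouts; including them biases frequency low by ~10 Hz).
Raising the SD multiplier or the minimum peak count never increases the
detection count on the signals the generator produces; this is asserted on
simulated recordings rather than proven, since a sufficiently long train
can in principle split into two qualifying trains when an interior peak is
removed.

## RMS and band power

RMS is √(mean x²). Percent reduction is 100 × (1 − RMS/RMS_ref) with the
baseline window as the default reference; negative values mean an increase
(the prediazepam phase typically shows one). Band power uses a Welch PSD
with 4-s Hann segments and 50 % overlap — 0.25 Hz resolution, enough to
resolve the delta band — integrated over half-open bands δ [0, 4), θ [4, 8),
α [8, 12), β [12, 30) Hz, so a 4 Hz component counts once, toward theta.
Band powers are rectangle-rule sums of the one-sided density, which makes
them additive and Parseval-consistent: for a 0–30 Hz band-limited signal the
four bands sum to the signal variance (within Welch bias). The mean is
removed per segment, so the delta band effectively holds 15 rather than 16
quarter-Hz bins; the white-noise partition test accounts for this.

## Synthetic ECoG generator

The generator produces the statistical structure the analysis assumes, with
exact ground truth:

* **Background**: a 1 Hz alternation between up (+100 µV) and down
  (−100 µV) states — a square wave smoothed with a 40 ms Gaussian kernel —
  plus 1/f-amplitude noise with 20 µV SD. These defaults give a baseline
  median-envelope amplitude of ~120 µV, a plausible anesthesia ECoG scale;
  cycle boundaries are computed from the exact phase so the noise-free
  waveform is strictly periodic.
* **Spikes**: an inhomogeneous Poisson process, 0.2 events/min at baseline,
  ramping exponentially (τ = 300 s) toward 20 events/min after the first
  pilocarpine dose and decaying after diazepam (τ = 300 s) toward 8
  events/min (sham) or 3.2 events/min (magnet). The magnet also scales the
  pilocarpine-driven rate by 0.5. No quantitative rates are published for
  this protocol (the source figures are normalized), so these are free
  parameters chosen to make the prediazepam trace discharge-dominated and
  the baseline nearly silent. Each spike is a 3-cycle sinusoid under a
  Tukey (α = 0.25) taper, duration ~ U(0.4, 0.8) s, peak amplitude 3× the
  measured baseline envelope amplitude: the tapered envelope keeps the
  Hilbert envelope above the 2× criterion for most of the nominal duration,
  which a sharper biphasic transient does not, and its spectral content
  stays far below the ripple band.
* **Ripples**: Poisson bursts at 20/h (baseline), 60/h (pilocarpine) and
  10/h (post-diazepam) — identical in both conditions, the magnet has no
  programmed ripple effect. A burst is a cosine-tapered (Tukey α = 0.4)
  oscillation of n ~ U{6..12} cycles at f ~ U(85, 150) Hz, peak amplitude
  5 SD of the band-filtered baseline background. The flat-topped envelope
  with support exactly n/f makes the detection geometry sharp: a 3-cycle
  burst cannot contain four same-polarity peaks, while ≥ 6-cycle bursts at
  5 SD keep at least four peaks above a 3 SD threshold. Carriers stay below
  150 Hz because a burst at the 200 Hz band edge is attenuated to half by
  any realizable zero-phase band-pass (and under-sampled at 1 kHz), which
  would make edge events undetectable at the stated amplitude; observed
  ripple frequencies in this model cluster near 90 Hz in any case.
* **Diazepam suppression**: after the injection the background amplitude
  scales to 0.7 (sham) or 0.5 (magnet) of its pre-injection value — the
  amplitude half of the programmed synergy, reflecting the visible
  suppression of oscillatory activity that motivates the dose. The ramp is
  a 10-s cosine completing exactly at the injection time, so each per-phase
  analysis window sees variance-stationary background; a transition inside
  the post window would locally defeat the per-window 3 SD threshold.
  Event amplitudes are anchored to the pre-injection background and are not
  suppressed.
* **Placement**: same-kind events never overlap and keep a clearance gap
  (0.1 s spikes, 0.05 s ripples); conflicting arrivals are re-drawn within
  ±30 s by thinning, preserving both the event count and the local
  intensity, so ground truth is unambiguous for precision/recall scoring
  and window counts stay Poisson-faithful.
* **Cohorts**: n sham + n magnet subjects; each subject's rates carry a
  log-normal multiplicative factor with σ = 0.2 on the log scale, giving
  the mixed ANOVA a realistic between-subject variance component. All
  randomness flows from one seed through a seed sequence; identical
  (parameters, seed) reproduce recordings and event logs exactly, and the
  events-only fast path produces the same events as full synthesis.

`scaled_params` compresses the protocol (timeline, ramps, t0) by a factor
while keeping per-minute and per-hour intensities, which is how the tests
and the acceptance script run the full pipeline at 1/6 duration and 1 kHz.

### What the generator does not emulate

Electrode/movement artifacts, line noise, anesthesia-depth drift, seizure
electrographic evolution (the discharge process is Poisson, not clustered),
spike morphology variability beyond duration, fast ripples (> 200 Hz), and
any pharmacokinetic realism. Passing tests therefore establish that the
pipeline implements its stated criteria and statistics correctly and
recovers effects of the programmed structure and size — not that the
detectors are robust to artifact-laden in-vivo data.

## Statistics

The mixed repeated-measures ANOVA is the classic split-plot decomposition:
CONDITION is between-subject (each animal receives only one treatment), TIME
within-subject, with subjects-within-condition as the error stratum for the
between effect and the subject × time residual for the within effects.
Implemented directly from cell means (balanced or unbalanced groups,
complete within-subject cases required; subjects with missing cells are
excluded listwise with a warning). The implementation is verified against a
projection-based least-squares oracle (sequential RSS reductions over
explicit indicator designs) to 10⁻⁸ relative error and against pingouin's
`mixed_anova` F statistics.

Greenhouse–Geisser ε is computed from the pooled within-group covariance of
the subject × time matrix (group means removed, so between-condition
differences do not masquerade as non-sphericity), double-centered, with
ε = tr(S̃)² / ((k−1) ΣS̃²), clipped to [1/(k−1), 1]; under compound symmetry
ε ≈ 1. Both uncorrected and GG-corrected p-values are always reported; the
working p-value applies the correction when ε < 0.75 — a conventional
trigger, made explicit because "corrected if needed" is not a rule.

Tukey HSD uses the studentized-range distribution with the error stratum
matched to the comparison family: subjects-within-condition for condition
means, the within residual for time means, and the two strata pooled for
condition × time cell means (the standard choice for between-at-within
simple effects, e.g. magnet vs sham within the postdiazepam phase). The
Tukey–Kramer form handles unequal group sizes. α = 0.05 throughout.

### Calibration

Type-I error and power of the CONDITION × TIME interaction test are measured
by replicate simulation on the generator's ground-truth event process
(events-only path; the waveform and detector stages are validated separately
and would add hours of compute without informing the inferential layer), at
the compressed protocol with 10-min phase windows and n = 6 per group.
Under the null (magnet effect switched off entirely) the interaction rejects
at α = 0.05 in ≈ 4.6 % of 1000 replicates — inside the binomial band, very
slightly conservative because the GG correction engages for the
heteroscedastic rate data. Under the default programmed magnet effect
(post-diazepam rate ratio 0.4 plus the 0.5× prediazepam scaling) power
exceeds 99 % at 500 replicates; with the prediazepam effect suppressed and
only the post-diazepam ratio, power at this reduced problem size is ≈ 75 %,
because the large prediazepam rates inflate the pooled within error.

## Serialization

Signals travel as 16-bit EDF with the physical range fixed at ±5000 µV —
comfortably above the largest simulated discharge and giving a deterministic
0.153 µV quantization step that round-trip tests assert exactly. Samples
outside the range are rejected, never clipped. Subject condition and the
injection timeline go in a YAML sidecar next to the EDF (EDF header fields
cannot carry them); a missing sidecar falls back to the default protocol
with a logged warning. Reading uses MNE and never resamples or rescales.
Event tables are UTF-8 CSV with a `kind,onset,duration,prop_*` header;
malformed rows raise errors naming the line number. Pipeline runs write a
resolved copy of their config plus a run record (package version, config
hash, seed); identical config and seed reproduce all tabular outputs
byte-identically.

## Known limitations

* The spike criterion's "baseline" requires a pre-injection segment; very
  short baselines fall back to whatever baseline window exists and are
  flagged, but recordings with no baseline at all cannot be analyzed.
* The ripple detector's per-window threshold assumes within-window variance
  stationarity; abrupt amplitude shifts inside a window produce false
  trains on the high-variance side (this drove the generator's design of
  the suppression ramp, and would need a locally adaptive threshold on real
  data with rapid state changes).
* Monotonicity of ripple counts in the threshold parameters is asserted
  empirically, not guaranteed combinatorially.
* The ANOVA requires complete within-subject cases; there is no
  mixed-effects (REML) fallback for unbalanced missingness.
* Only integer downsampling ratios are supported.
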