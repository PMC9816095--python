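# ecosyn

Quantification pipeline for electrocorticogram (ECoG) recordings from the
lithium–pilocarpine model of status epilepticus, built for experiments that
combine a pharmacological intervention (low-dose diazepam) with transcranial
static magnetic stimulation (tSMS, "magnet" vs "sham" groups). The package
detects epileptiform spikes and high-frequency ripples, tracks RMS amplitude
and band-limited spectral power across the injection protocol, and tests
group × phase effects with a mixed repeated-measures ANOVA. A synthetic ECoG
generator with full ground truth makes every stage testable without animal
recordings, and lets the statistical pipeline be calibrated by simulation.

It is intended for electrophysiologists analyzing single-channel rodent
ECoG under a timed drug protocol, and for methodologists who want a
ground-truth-driven testbed for event detectors and repeated-measures
statistics.

## The measurements

The experiment clock is anchored at the scopolamine injection (t = 0);
pilocarpine doses follow at 30 and 60 min and diazepam at 120 min. Analyses
run on the 1 kHz downsampled trace in three one-hour phase windows —
baseline (before scopolamine), prediazepam (second pilocarpine dose →
diazepam) and postdiazepam — plus 60-s epochs every 30 min for time courses.

* **Epileptiform spike**: a discharge whose Hilbert-envelope amplitude
  exceeds 2× the baseline amplitude (median envelope of a pre-injection
  epoch) for at least 0.3 s. Reported as spikes/min, optionally normalized
  per subject to the first post-pilocarpine timepoint.
* **Ripple (HFO)**: after band-pass filtering to 80–200 Hz, an oscillation
  with ≥ 4 consecutive peaks above mean + 3 SD of the filtered analysis
  window. Reported as ripples/hour plus the mean intra-burst frequency.
* **RMS**: √(mean x²) per epoch or window, with percent reduction relative
  to baseline.
* **Band power**: Welch PSD (4-s Hann segments, 50 % overlap) integrated
  over δ [0, 4), θ [4, 8), α [8, 12) and β [12, 30) Hz.
* **Statistics**: two-way mixed ANOVA with CONDITION (sham, magnet) between
  subjects and TIME (baseline, prediazepam, postdiazepam) within subjects;
  Greenhouse–Geisser ε always reported and applied to within-effect degrees
  of freedom when ε < 0.75; Tukey HSD (studentized range) post hocs on the
  appropriate error stratum.

The synthetic generator emulates anesthesia up/down-state background with
1/f noise, spike and ripple event processes with protocol-locked Poisson
intensities (spike rates rise after pilocarpine and fall after diazepam,
more under the magnet; ripple rates are condition-independent), and the
diazepam suppression of background amplitude. Every injected event is
logged, so detector precision/recall are measurable exactly.

## Worked example

`examples/02_detect_events.py` simulates one recording on a 6×-compressed
protocol and scores both detectors against the generator's ground truth:

```
baseline amplitude: 127.2 uV
spikes: 383 detected / 388 injected -> precision 1.000, recall 0.987
ripples: 16 detected / 16 injected in analysis windows -> precision 1.000, recall 1.000
mean ripple frequency: 121.1 Hz (generator draws carriers from (85.0, 150.0) Hz)
```

The baseline amplitude is the median Hilbert envelope of a pre-injection
epoch (the "2×" reference of the spike criterion); precision/recall compare
detected onsets with the injected events. `examples/04_cohort_statistics.py`
runs a 6 vs 6 cohort end to end; its ANOVA table shows the programmed
pattern — e.g. mean spikes/min per condition × phase:

```
time       baseline  prediazepam  postdiazepam
condition
magnet         0.20         9.40          3.88
sham           0.18        18.28          7.88
```

with a significant CONDITION × TIME interaction for spike rate and RMS
reduction, and no condition effect for ripples.

The same flow is available from the shell:

```bash
ecosyn demo --out demo_run --seed 1        # simulated cohort, full analysis
ecosyn simulate --n-per-group 6 --seed 1 --out cohort/   # EDF + truth CSVs
ecosyn detect-spikes --in cohort/sham01.edf --out spikes.csv
```

## Layout

| module | contents |
| --- | --- |
| `ecosyn.core` | `Recording`, `Timeline`, `Phase`, `EventRecord` |
| `ecosyn.io` | EDF read/write (+ YAML timeline sidecar), event CSVs |
| `ecosyn.simulate` | `SimParams`, synthetic recordings/cohorts with ground truth |
| `ecosyn.preprocess` | downsampling, zero-phase band-pass, epoching, phase windows |
| `ecosyn.detect` | spike and ripple detectors, rates, precision/recall scoring |
| `ecosyn.metrics` | RMS, RMS reduction, Welch band powers per phase |
| `ecosyn.stats` | mixed rm-ANOVA + GG ε, Tukey HSD, cohort-wide `synergy_analysis` |
| `ecosyn.pipeline` | config schema, per-recording analysis, full `run_pipeline` |
| `ecosyn.cli` | thin `ecosyn` command (simulate/preprocess/detect/metrics/stats/run/demo) |

See `docs/methods.md` for the model, parameter defaults and their rationale,
numerical choices, and known limitations.
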