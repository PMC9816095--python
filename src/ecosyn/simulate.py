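"""Synthetic ECoG generator with ground truth.

The generator emulates the phenomenology of a lithium–pilocarpine experiment
recorded under anesthesia:

* a background of slow (~1 Hz) up/down-state alternation plus 1/f noise;
* epileptiform spikes — high-amplitude oscillatory transients lasting several
  hundred milliseconds — arriving as an inhomogeneous Poisson process whose
  rate is low at baseline, ramps up after the first pilocarpine dose, and
  decays after diazepam toward a condition-specific floor (the magnet group
  receives a lower prediazepam rate and a lower post-diazepam floor, the
  programmed "synergy" the statistics are meant to recover);
* ripples — brief 80–200 Hz cosine-tapered oscillation bursts — whose rate
  rises with pilocarpine and falls with diazepam *identically in both
  conditions* (the magnet has no programmed effect on ripples).

Every injected event is logged with its true onset, duration and parameters,
so detector precision and recall can be scored against ground truth.  Event
onsets are seconds from the start of the recording.

Amplitudes are calibrated against the generated background itself: spike peak
amplitude is ``amp_ratio`` times the median Hilbert-envelope amplitude of the
baseline background, and ripple peak amplitude is ``amp_sd_multiple`` times
the standard deviation of the 80–200 Hz-filtered background, so injected
events satisfy the detection criteria by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage, signal

from .core import Condition, EventRecord, Recording, Timeline, ValidationError

__all__ = [
    "BackgroundParams",
    "SpikeParams",
    "RippleParams",
    "SimParams",
    "GroundTruth",
    "simulate_recording",
    "simulate_ground_truth",
    "simulate_cohort",
    "scaled_params",
    "phase_event_rates",
    "spike_waveform",
    "ripple_waveform",
]


@dataclass(frozen=True)
class BackgroundParams:
    """Anesthesia background: smoothed up/down alternation plus pink noise."""

    slow_osc_freq: float = 1.0  # Hz
    up_state_amp: float = 100.0  # µV
    down_state_amp: float = 100.0  # µV
    pink_noise_sd: float = 20.0  # µV
    smooth_ms: float = 40.0  # Gaussian smoothing of the square alternation
    # Diazepam visibly suppresses the spontaneous oscillatory background (at
    # high doses to the point of isoelectric ECoG); the asymptotic amplitude
    # scale after injection, smaller under the magnet — the amplitude half of
    # the programmed synergy.  The ramp is fast relative to the hour-long
    # analysis window and completes by the injection time, so every per-phase
    # window sees variance-stationary background.
    diazepam_suppression_sham: float = 0.7
    diazepam_suppression_magnet: float = 0.5
    suppression_ramp_s: float = 10.0


@dataclass(frozen=True)
class SpikeParams:
    """Epileptiform-spike process. Rates are events/min."""

    baseline_rate: float = 0.2
    pilocarpine_rate: float = 20.0
    postdiazepam_rate_sham: float = 8.0
    postdiazepam_rate_magnet: float = 3.2
    amp_ratio: float = 3.0  # peak envelope / baseline envelope amplitude
    duration_range: Tuple[float, float] = (0.4, 0.8)  # s, min >= 0.3
    onset_ramp_tau: float = 300.0  # s, exponential approach after pilocarpine
    diazepam_decay_tau: float = 300.0  # s, exponential decay after diazepam
    magnet_prediazepam_scale: float = 0.5  # magnet scales the pilocarpine rate
    carrier_cycles: int = 3  # oscillation cycles inside one discharge


@dataclass(frozen=True)
class RippleParams:
    """Ripple (80–200 Hz burst) process. Rates are events/h, both conditions."""

    baseline_rate: float = 20.0
    pilocarpine_rate: float = 60.0
    postdiazepam_rate: float = 10.0
    # Carrier frequencies concentrate in the lower half of the 80-200 Hz
    # analysis band, as in-vivo ripples in this model do (~85-95 Hz means);
    # events at the band edge would be attenuated below threshold by any
    # realizable band-pass filter and are not representative.
    freq_range: Tuple[float, float] = (85.0, 150.0)  # Hz
    n_cycles_range: Tuple[int, int] = (6, 12)  # min >= 4
    amp_sd_multiple: float = 5.0  # peak amp in SDs of the filtered background
    onset_ramp_tau: float = 300.0
    diazepam_decay_tau: float = 300.0


@dataclass(frozen=True)
class SimParams:
    """Full parameter set for one simulated experiment."""

    fs: float = 20000.0
    background: BackgroundParams = field(default_factory=BackgroundParams)
    spikes: SpikeParams = field(default_factory=SpikeParams)
    ripples: RippleParams = field(default_factory=RippleParams)
    timeline: Timeline = field(default_factory=Timeline)
    t0: float = -3600.0  # recording starts one hour before scopolamine
    jitter_sd: float = 0.2  # per-subject log-normal rate jitter (cohorts)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        sp, rp = self.spikes, self.ripples
        for name, rate in [
            ("spike baseline", sp.baseline_rate),
            ("spike pilocarpine", sp.pilocarpine_rate),
            ("spike postdiazepam sham", sp.postdiazepam_rate_sham),
            ("spike postdiazepam magnet", sp.postdiazepam_rate_magnet),
            ("ripple baseline", rp.baseline_rate),
            ("ripple pilocarpine", rp.pilocarpine_rate),
            ("ripple postdiazepam", rp.postdiazepam_rate),
        ]:
            if rate < 0:
                raise ValidationError(f"{name} rate must be >= 0, got {rate}")
        if sp.amp_ratio < 2.0:
            raise ValidationError("spike amp_ratio must be >= 2 (detection criterion)")
        if sp.duration_range[0] < 0.3:
            raise ValidationError("spike durations must be >= 0.3 s (detection criterion)")
        if rp.n_cycles_range[0] < 4:
            raise ValidationError("ripple n_cycles must be >= 4 (detection criterion)")
        if not (80.0 <= rp.freq_range[0] <= rp.freq_range[1] <= 200.0):
            raise ValidationError("ripple frequencies must lie within [80, 200] Hz")
        if rp.amp_sd_multiple < 3.0:
            raise ValidationError("ripple amp_sd_multiple must be >= 3 (detection criterion)")


@dataclass
class GroundTruth:
    """True injected events for one recording (onsets relative to rec start)."""

    spike_events: List[EventRecord]
    ripple_events: List[EventRecord]
    params: SimParams
    condition: Condition = Condition.SHAM
    subject_id: str = "sim"
    duration: float = 0.0  # simulated span (s) the events were drawn over
    baseline_env_amp: Optional[float] = None  # µV, median baseline envelope
    ripple_band_sd: Optional[float] = None  # µV, SD of 80–200 Hz background


def scaled_params(params: SimParams, factor: float) -> SimParams:
    """Compress/stretch the protocol: timeline, taus and t0 scaled by factor.

    Event rates are left untouched, so a compressed run keeps per-minute and
    per-hour intensities while shortening every phase.
    """
    return replace(
        params,
        timeline=params.timeline.scaled(factor),
        t0=params.t0 * factor,
        spikes=replace(
            params.spikes,
            onset_ramp_tau=params.spikes.onset_ramp_tau * factor,
            diazepam_decay_tau=params.spikes.diazepam_decay_tau * factor,
        ),
        ripples=replace(
            params.ripples,
            onset_ramp_tau=params.ripples.onset_ramp_tau * factor,
            diazepam_decay_tau=params.ripples.diazepam_decay_tau * factor,
        ),
    )


# ---------------------------------------------------------------------------
# Rate trajectories


def spike_rate_at(t: np.ndarray, params: SimParams, condition: Condition) -> np.ndarray:
    """Spike intensity (events/min) at experiment-clock times ``t``."""
    sp = params.spikes
    tl = params.timeline
    t = np.asarray(t, dtype=float)
    scale = sp.magnet_prediazepam_scale if condition is Condition.MAGNET else 1.0
    target = sp.pilocarpine_rate * scale
    post = (
        sp.postdiazepam_rate_magnet
        if condition is Condition.MAGNET
        else sp.postdiazepam_rate_sham
    )
    r = np.full_like(t, sp.baseline_rate)
    ramp = t >= tl.pilocarpine1_t
    r[ramp] = target - (target - sp.baseline_rate) * np.exp(
        -(t[ramp] - tl.pilocarpine1_t) / sp.onset_ramp_tau
    )
    r_at_diaz = target - (target - sp.baseline_rate) * math.exp(
        -(tl.diazepam_t - tl.pilocarpine1_t) / sp.onset_ramp_tau
    )
    decay = t >= tl.diazepam_t
    r[decay] = post + (r_at_diaz - post) * np.exp(
        -(t[decay] - tl.diazepam_t) / sp.diazepam_decay_tau
    )
    return r


def ripple_rate_at(t: np.ndarray, params: SimParams) -> np.ndarray:
    """Ripple intensity (events/h) at experiment-clock times ``t``.

    Condition-independent: the magnet is modelled as having no ripple effect.
    """
    rp = params.ripples
    tl = params.timeline
    t = np.asarray(t, dtype=float)
    r = np.full_like(t, rp.baseline_rate)
    ramp = t >= tl.pilocarpine1_t
    r[ramp] = rp.pilocarpine_rate - (rp.pilocarpine_rate - rp.baseline_rate) * np.exp(
        -(t[ramp] - tl.pilocarpine1_t) / rp.onset_ramp_tau
    )
    r_at_diaz = rp.pilocarpine_rate - (rp.pilocarpine_rate - rp.baseline_rate) * math.exp(
        -(tl.diazepam_t - tl.pilocarpine1_t) / rp.onset_ramp_tau
    )
    decay = t >= tl.diazepam_t
    r[decay] = rp.postdiazepam_rate + (r_at_diaz - rp.postdiazepam_rate) * np.exp(
        -(t[decay] - tl.diazepam_t) / rp.diazepam_decay_tau
    )
    return r


# ---------------------------------------------------------------------------
# Event sampling


def _thinned_poisson_times(
    rate_fn, t_start: float, t_end: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample an inhomogeneous Poisson process by thinning (rates per second)."""
    grid = np.linspace(t_start, t_end, 512)
    lam_max = float(np.max(rate_fn(grid))) * 1.05
    if lam_max <= 0:
        return np.array([])
    n_cand = rng.poisson(lam_max * (t_end - t_start))
    cand = np.sort(rng.uniform(t_start, t_end, size=n_cand))
    keep = rng.uniform(0, 1, size=n_cand) < rate_fn(cand) / lam_max
    return cand[keep]


def _redraw_time(rate_fn, t_start, t_end, lam_max, rng, near=None, radius=30.0) -> float:
    """Thinning re-draw; restricted to a neighbourhood of ``near`` so that
    resolving an overlap does not move intensity between analysis windows."""
    lo, hi = t_start, t_end
    if near is not None:
        lo, hi = max(t_start, near - radius), min(t_end, near + radius)
    for _ in range(200):
        t = rng.uniform(lo, hi)
        if rng.uniform() < rate_fn(np.array([t]))[0] / lam_max:
            return t
    return rng.uniform(lo, hi)


def _place_events(
    times: np.ndarray,
    durations: np.ndarray,
    rate_fn,
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
    min_gap: float = 0.1,
) -> List[Tuple[float, int]]:
    """Re-draw event times that land within ``min_gap`` of an earlier event.

    Same-kind events never overlap and keep a clearance gap, so ground truth
    stays unambiguous for precision/recall scoring, while the event count is
    preserved and empirical rates track the programmed intensities.  Returns
    (time, original index) pairs sorted by time, so per-event parameters drawn
    alongside ``times`` stay attached to their event.
    """
    import bisect

    grid = np.linspace(t_start, t_end, 512)
    lam_max = float(np.max(rate_fn(grid))) * 1.05
    starts: List[float] = []  # sorted
    placed: List[Tuple[float, int]] = []  # aligned with starts

    def conflict(t: float, d: float) -> bool:
        # placed events are mutually disjoint (with clearance), so only the
        # nearest neighbours by start time can conflict with a candidate
        pos = bisect.bisect_left(starts, t)
        if pos > 0:
            pt, pi = placed[pos - 1]
            if pt + durations[pi] + min_gap > t:
                return True
        if pos < len(placed):
            pt, _ = placed[pos]
            if t + d + min_gap > pt:
                return True
        return False

    for i, (t, d) in enumerate(zip(times, durations)):
        t = float(t)
        t_orig = t
        tries = 0
        while conflict(t, d) and tries < 50:
            t = _redraw_time(rate_fn, t_start, t_end, lam_max, rng, near=t_orig)
            tries += 1
        if not conflict(t, d):
            pos = bisect.bisect_left(starts, t)
            starts.insert(pos, t)
            placed.insert(pos, (t, i))
    return placed


def simulate_ground_truth(
    params: SimParams,
    condition: Condition,
    duration: float,
    seed: Optional[int] = None,
) -> GroundTruth:
    """Sample event times and parameters only (no waveform synthesis).

    This is the fast path used for statistical calibration studies, where
    thousands of replicate cohorts are needed and only the ground-truth event
    counts matter.  The same seed produces the same events as
    :func:`simulate_recording`.
    """
    condition = Condition(condition)
    seed = params.seed if seed is None else seed
    tl = params.timeline
    t_start, t_end = params.t0, params.t0 + duration
    if t_end < tl.diazepam_t:
        raise ValidationError(
            f"duration {duration} s ends at t={t_end} s, before diazepam at "
            f"t={tl.diazepam_t} s; recording must cover the timeline"
        )
    ss = np.random.SeedSequence(seed)
    ev_ss, _ = ss.spawn(2)
    rng = np.random.default_rng(ev_ss)

    sp, rp = params.spikes, params.ripples
    spike_rate_s = lambda t: spike_rate_at(t, params, condition) / 60.0
    ripple_rate_s = lambda t: ripple_rate_at(t, params) / 3600.0

    spike_times = _thinned_poisson_times(spike_rate_s, t_start, t_end, rng)
    spike_durs = rng.uniform(*sp.duration_range, size=spike_times.size)
    spikes = _place_events(
        spike_times, spike_durs, spike_rate_s, t_start, t_end, rng, min_gap=0.1
    )

    ripple_times = _thinned_poisson_times(ripple_rate_s, t_start, t_end, rng)
    ripple_freqs = rng.uniform(*rp.freq_range, size=ripple_times.size)
    ripple_cycles = rng.integers(
        rp.n_cycles_range[0], rp.n_cycles_range[1] + 1, size=ripple_times.size
    )
    ripple_durs = ripple_cycles / ripple_freqs
    ripples = _place_events(
        ripple_times, ripple_durs, ripple_rate_s, t_start, t_end, rng, min_gap=0.05
    )

    spike_events = [
        EventRecord(
            "spike",
            onset=t - t_start,
            duration=float(spike_durs[i]),
            properties={"amp_ratio": sp.amp_ratio},
        )
        for (t, i) in spikes
        if t + spike_durs[i] <= t_end
    ]
    ripple_events = [
        EventRecord(
            "ripple",
            onset=t - t_start,
            duration=float(ripple_durs[i]),
            properties={
                "freq": float(ripple_freqs[i]),
                "n_cycles": float(ripple_cycles[i]),
                "amp_sd": rp.amp_sd_multiple,
            },
        )
        for (t, i) in ripples
        if t + ripple_durs[i] <= t_end
    ]
    return GroundTruth(spike_events, ripple_events, params, condition, duration=duration)


# ---------------------------------------------------------------------------
# Waveform synthesis


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, zero mean, standard deviation ``sd``."""
    if sd == 0 or n < 2:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    x = np.fft.irfft(spec, n)
    x_sd = x.std()
    return x * (sd / x_sd) if x_sd > 0 else x


def _background(params: SimParams, n: int, rng: np.random.Generator) -> np.ndarray:
    bg = params.background
    t = np.arange(n) / params.fs
    phase = np.mod(t * bg.slow_osc_freq, 1.0)  # exact cycle boundaries
    square = np.where(phase < 0.5, bg.up_state_amp, -bg.down_state_amp).astype(float)
    sigma = bg.smooth_ms * 1e-3 * params.fs
    if sigma > 0:
        square = ndimage.gaussian_filter1d(square, sigma, mode="nearest")
    return square + _pink_noise(n, bg.pink_noise_sd, rng)


def spike_waveform(d: float, peak: float, fs: float, cycles: int) -> np.ndarray:
    """Oscillatory discharge: ``cycles``-cycle sinusoid under a Tukey taper."""
    n = max(int(round(d * fs)), 8)
    t = np.arange(n) / fs
    carrier = np.sin(2 * np.pi * cycles / d * t)
    return peak * signal.windows.tukey(n, alpha=0.25) * carrier


def ripple_waveform(freq: float, n_cycles: int, amp: float, fs: float) -> np.ndarray:
    """Cosine-tapered (Tukey) oscillation burst of exactly ``n_cycles / freq``.

    The flat-topped envelope (60 % flat, cosine tapers to zero at the edges)
    keeps most carrier peaks near full amplitude, so a 5-SD burst of >= 6
    cycles robustly clears a 3-SD / 4-peak criterion, while the bounded
    support means a 3-cycle burst physically cannot contain four
    same-polarity peaks.
    """
    d = n_cycles / freq
    n = max(int(round(d * fs)), 8)
    t = np.arange(n) / fs - d / 2
    envelope = signal.windows.tukey(n, alpha=0.4)
    return amp * envelope * np.cos(2 * np.pi * freq * t)


def simulate_recording(
    params: SimParams,
    condition: Condition,
    duration: float,
    seed: Optional[int] = None,
) -> Tuple[Recording, GroundTruth]:
    """Synthesize one recording plus its ground-truth event log.

    Identical (params, condition, duration, seed) yield identical output.
    """
    condition = Condition(condition)
    seed = params.seed if seed is None else seed
    truth = simulate_ground_truth(params, condition, duration, seed)
    ss = np.random.SeedSequence(seed)
    _, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(noise_ss)

    fs = params.fs
    n = int(round(duration * fs))
    x = _background(params, n, rng)

    # Amplitude references measured on the (unsuppressed) background, over up
    # to the first minute of the recording — pre-diazepam statistics are
    # stationary, and event amplitudes are anchored to the baseline state.
    ref = x[: min(n, int(60 * fs))].copy()
    baseline_env = float(np.median(np.abs(signal.hilbert(ref))))
    if fs >= 500.0:
        sos = signal.butter(4, [80.0, 200.0], btype="bandpass", fs=fs, output="sos")
        band_sd = float(np.std(signal.sosfiltfilt(sos, ref)))
    else:
        band_sd = 0.0
    truth.baseline_env_amp = baseline_env
    truth.ripple_band_sd = band_sd

    # diazepam suppresses the background amplitude toward a condition-specific
    # floor (events are added afterwards and keep their absolute amplitudes)
    bg = params.background
    s_inf = (
        bg.diazepam_suppression_magnet
        if condition is Condition.MAGNET
        else bg.diazepam_suppression_sham
    )
    i_diaz = int(round((params.timeline.diazepam_t - params.t0) * fs))
    if s_inf != 1.0 and i_diaz < n:
        ramp_n = min(int(round(bg.suppression_ramp_s * fs)), i_diaz)
        if ramp_n > 0:  # cosine ramp ending exactly at the injection time
            u = np.arange(ramp_n) / ramp_n
            x[i_diaz - ramp_n : i_diaz] *= 1.0 + (s_inf - 1.0) * 0.5 * (
                1 - np.cos(np.pi * u)
            )
        x[i_diaz:] *= s_inf

    for ev in truth.spike_events:
        peak = ev.properties["amp_ratio"] * baseline_env
        w = spike_waveform(ev.duration, peak, fs, params.spikes.carrier_cycles)
        i0 = int(round(ev.onset * fs))
        seg = slice(i0, min(i0 + w.size, n))
        x[seg] += w[: seg.stop - seg.start]
        ev.properties["peak_amp"] = float(peak)

    if band_sd > 0:
        for ev in truth.ripple_events:
            amp = ev.properties["amp_sd"] * band_sd
            w = ripple_waveform(
                ev.properties["freq"], int(ev.properties["n_cycles"]), amp, fs
            )
            i0 = max(0, int(round(ev.onset * fs)))
            seg = slice(i0, min(i0 + w.size, n))
            x[seg] += w[: seg.stop - seg.start]
            ev.properties["peak_amp"] = float(amp)

    rec = Recording(
        subject_id="sim",
        condition=condition,
        samples=x,
        fs=fs,
        t0=params.t0,
        timeline=params.timeline,
    )
    return rec, truth


def phase_event_rates(
    truth: GroundTruth, window_s: float = 3600.0
) -> dict:
    """Ground-truth spike rates (events/min) per analysis phase.

    Counts logged spike events inside the three per-phase windows (baseline
    ends at scopolamine, prediazepam spans pilocarpine2 → diazepam,
    postdiazepam starts at diazepam), clipped to the recorded span.  The fast
    companion of the detector pipeline for calibration studies.
    """
    tl = truth.params.timeline
    t0 = truth.params.t0
    t_end = t0 + truth.duration
    windows = {
        "baseline": (max(tl.scopolamine_t - window_s, t0), tl.scopolamine_t),
        "prediazepam": (tl.pilocarpine2_t, tl.diazepam_t),
        "postdiazepam": (tl.diazepam_t, min(tl.diazepam_t + window_s, t_end)),
    }
    out = {}
    for name, (lo, hi) in windows.items():
        if hi <= lo:  # window not covered by the simulated span
            continue
        n = sum(1 for e in truth.spike_events if lo <= t0 + e.onset < hi)
        out[name] = n * 60.0 / (hi - lo)
    return out


def simulate_cohort(
    n_per_group: int,
    params: SimParams,
    seed: Optional[int] = None,
    duration: Optional[float] = None,
    events_only: bool = False,
) -> List[Tuple[Optional[Recording], GroundTruth]]:
    """Simulate a two-group cohort (``n_per_group`` sham + magnet subjects).

    Between-subject variability is a log-normal multiplicative factor (sd
    ``params.jitter_sd`` on the log scale) applied to every event rate of that
    subject.  Per-subject seeds derive from ``seed`` via a seed sequence, so a
    cohort is reproducible as a whole.  With ``events_only`` the waveforms are
    skipped (Recording is None) — the fast path for calibration studies.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    seed = params.seed if seed is None else seed
    if duration is None:
        duration = params.timeline.diazepam_t + 3600.0 - params.t0
    ss = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for gi, condition in enumerate((Condition.SHAM, Condition.MAGNET)):
        for si in range(n_per_group):
            factor = float(
                np.exp(jitter_rng.normal(0.0, params.jitter_sd))
            ) if params.jitter_sd > 0 else 1.0
            sp = params.spikes
            rp = params.ripples
            subj_params = replace(
                params,
                spikes=replace(
                    sp,
                    baseline_rate=sp.baseline_rate * factor,
                    pilocarpine_rate=sp.pilocarpine_rate * factor,
                    postdiazepam_rate_sham=sp.postdiazepam_rate_sham * factor,
                    postdiazepam_rate_magnet=sp.postdiazepam_rate_magnet * factor,
                ),
                ripples=replace(
                    rp,
                    baseline_rate=rp.baseline_rate * factor,
                    pilocarpine_rate=rp.pilocarpine_rate * factor,
                    postdiazepam_rate=rp.postdiazepam_rate * factor,
                ),
            )
            subj_seed = int(jitter_rng.integers(0, 2**31 - 1))
            subject_id = f"{condition.value}{si + 1:02d}"
            if events_only:
                truth = simulate_ground_truth(subj_params, condition, duration, subj_seed)
                truth.subject_id = subject_id
                out.append((None, truth))
            else:
                rec, truth = simulate_recording(subj_params, condition, duration, subj_seed)
                rec.subject_id = subject_id
                truth.subject_id = subject_id
                out.append((rec, truth))
    return out
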