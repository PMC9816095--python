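"""Event detectors: epileptiform spikes and 80–200 Hz ripples.

Spike criterion: a discharge lasting at least ``min_duration`` (0.3 s) whose
amplitude is at least ``ratio`` (2×) the baseline amplitude.  "Amplitude" is
the Hilbert-envelope magnitude and "baseline" the median envelope of a
pre-injection epoch — the criterion itself leaves both operationalisations
open, and the envelope makes the 2× ratio well defined for oscillatory
backgrounds and insensitive to polarity.

Ripple criterion: after band-pass filtering to 80–200 Hz, an oscillation with
4 or more consecutive peaks whose amplitude exceeds mean + 3 SD of the
filtered signal.  Peaks are counted on the rectified filtered trace (both
polarities), "consecutive" means inter-peak gaps no longer than the 80 Hz
period (12.5 ms), and the threshold statistics are computed over the analysis
window being scanned so they track slow non-stationarity across phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .core import EventRecord, Recording, ValidationError
from .preprocess import Epoch, bandpass_array

__all__ = [
    "BaselineStats",
    "SpikeEvent",
    "RippleEvent",
    "estimate_baseline",
    "detect_spikes",
    "spike_rate",
    "normalize_rates",
    "detect_ripples",
    "ripple_rate",
    "mean_ripple_frequency",
    "match_events",
    "precision_recall",
]


@dataclass(frozen=True)
class BaselineStats:
    """Reference amplitude of the pre-injection background."""

    baseline_amp: float  # µV, median Hilbert envelope
    source_epoch: Optional[Epoch] = None

    def __post_init__(self) -> None:
        if not (self.baseline_amp > 0):
            raise ValidationError("baseline amplitude must be positive")


@dataclass(frozen=True)
class SpikeEvent:
    """One epileptiform discharge (onset in seconds from segment start)."""

    onset: float
    duration: float
    peak_amp: float  # µV, max envelope during the event
    amp_ratio: float  # peak envelope / baseline amplitude

    def to_record(self) -> EventRecord:
        return EventRecord(
            "spike",
            self.onset,
            self.duration,
            {"peak_amp": self.peak_amp, "amp_ratio": self.amp_ratio},
        )


@dataclass(frozen=True)
class RippleEvent:
    """One high-frequency oscillation burst."""

    onset: float
    offset: float
    n_peaks: int
    mean_freq: float  # Hz
    max_amp_sd: float  # peak amplitude in SD units of the filtered signal

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def to_record(self) -> EventRecord:
        return EventRecord(
            "ripple",
            self.onset,
            self.duration,
            {
                "n_peaks": float(self.n_peaks),
                "mean_freq": self.mean_freq,
                "max_amp_sd": self.max_amp_sd,
            },
        )


def _envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(signal.hilbert(x))


def estimate_baseline(epoch: Epoch) -> BaselineStats:
    """Median Hilbert-envelope amplitude of a baseline epoch."""
    x = np.asarray(epoch.samples, dtype=float)
    if np.allclose(x, 0.0):
        raise ValidationError("baseline epoch is identically zero; amplitude undefined")
    amp = float(np.median(_envelope(x)))
    return BaselineStats(baseline_amp=amp, source_epoch=epoch)


def detect_spikes(
    samples,
    base: BaselineStats,
    min_duration: float = 0.3,
    ratio: float = 2.0,
    merge_gap: float = 0.05,
    fs: float = 1000.0,
) -> List[SpikeEvent]:
    """Detect epileptiform discharges in an Epoch, Recording or 1 kHz array.

    Contiguous runs where the Hilbert envelope exceeds ``ratio`` ×
    baseline amplitude become candidate segments; segments separated by less
    than ``merge_gap`` (50 ms, so one discharge is not split at its internal
    zero crossings) are merged before the ≥ ``min_duration`` test.  Onsets are
    seconds from the start of the supplied segment.
    """
    if isinstance(samples, Epoch):
        fs, samples = samples.fs, samples.samples
    elif isinstance(samples, Recording):
        fs, samples = samples.fs, samples.samples
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        return []
    env = _envelope(x)
    threshold = ratio * base.baseline_amp
    above = env > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(x.size)
    # merge segments separated by < merge_gap
    gap = int(round(merge_gap * fs))
    merged: List[Tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        dur = (e - s) / fs
        if dur >= min_duration:
            peak = float(env[s:e].max())
            events.append(
                SpikeEvent(
                    onset=s / fs,
                    duration=dur,
                    peak_amp=peak,
                    amp_ratio=peak / base.baseline_amp,
                )
            )
    return events


def spike_rate(events: Sequence, epoch_len: float) -> float:
    """Events per minute over a segment of ``epoch_len`` seconds."""
    if epoch_len <= 0:
        raise ValidationError("epoch_len must be positive")
    return len(events) * 60.0 / epoch_len


def normalize_rates(
    rates: Dict[float, float], reference_time: float
) -> Optional[Dict[float, float]]:
    """Normalize a subject's rate series to its rate at ``reference_time``.

    ``rates`` maps time points (minutes from diazepam, or any consistent key)
    to events/min.  The reference is the subject's rate at the first time
    point ≥ ``reference_time``; subjects with a zero reference rate cannot be
    normalized and yield None (flagged, excluded from normalized summaries).
    """
    times = sorted(rates)
    ref_times = [t for t in times if t >= reference_time]
    if not ref_times:
        return None
    ref = rates[ref_times[0]]
    if ref <= 0:
        return None
    return {t: rates[t] / ref for t in times}


def detect_ripples(
    samples,
    band: Tuple[float, float] = (80.0, 200.0),
    min_peaks: int = 4,
    sd_mult: float = 3.0,
    fs: float = 1000.0,
) -> List[RippleEvent]:
    """Detect ripples in a segment at 1 kHz (or any fs > 2×band[1]).

    The segment is band-pass filtered and oscillation peaks exceeding
    mean + ``sd_mult`` × SD of the filtered signal are grouped into trains:
    "consecutive" means an inter-peak gap no longer than one 80 Hz period
    (12.5 ms).  Trains with at least ``min_peaks`` peaks become events.  Peaks
    are counted on the signed filtered signal — one per oscillation cycle —
    so the event's mean frequency is the reciprocal mean inter-peak interval
    (intervals ≥ 1.5× the train median are treated as single-peak dropouts and
    excluded), and chance trains in Gaussian background — whose envelope would
    have to stay above threshold for four full carrier periods — are rare.
    """
    if isinstance(samples, Epoch):
        fs, samples = samples.fs, samples.samples
    elif isinstance(samples, Recording):
        fs, samples = samples.fs, samples.samples
    x = np.asarray(samples, dtype=float)
    if x.size < fs:
        raise ValidationError("segment must be at least 1 s long")
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValidationError(f"band {band} outside (0, fs/2) at fs={fs}")
    if min_peaks < 1 or sd_mult <= 0:
        raise ValidationError("min_peaks must be >= 1 and sd_mult > 0")
    filt = bandpass_array(x, band[0], band[1], fs)
    sd = float(np.std(filt))
    if sd == 0:
        return []
    mean = float(np.mean(filt))
    threshold = mean + sd_mult * sd
    peaks, _ = signal.find_peaks(filt, height=threshold)
    if peaks.size == 0:
        return []
    # Two 80 Hz periods: one carrier period (signed peaks are one per cycle)
    # plus one period of slack, so a single peak lost to destructive
    # interference with the background does not split a train.
    max_gap = int(np.ceil(2 * 0.0125 * fs))
    breaks = np.flatnonzero(np.diff(peaks) > max_gap)
    groups = np.split(peaks, breaks + 1)
    events = []
    for g in groups:
        if g.size < min_peaks:
            continue
        intervals = np.diff(g) / fs
        med = float(np.median(intervals))
        kept = intervals[intervals <= 1.5 * med] if med > 0 else intervals
        mean_freq = 1.0 / float(np.mean(kept)) if kept.size and np.mean(kept) > 0 else float("nan")
        events.append(
            RippleEvent(
                onset=g[0] / fs,
                offset=g[-1] / fs,
                n_peaks=int(g.size),
                mean_freq=float(mean_freq),
                max_amp_sd=float((filt[g].max() - mean) / sd),
            )
        )
    return events


def ripple_rate(events: Sequence, window_duration: float) -> float:
    """Events per hour over a window of ``window_duration`` seconds."""
    if window_duration <= 0:
        raise ValidationError("window duration must be positive")
    return len(events) * 3600.0 / window_duration


def mean_ripple_frequency(events: Sequence[RippleEvent]) -> Optional[float]:
    """Average mean_freq over events; None when the window holds no events."""
    if not events:
        return None
    return float(np.mean([e.mean_freq for e in events]))


# ---------------------------------------------------------------------------
# Scoring against ground truth


def match_events(
    detected: Sequence[Tuple[float, float]],
    truth: Sequence[Tuple[float, float]],
    tol: float = 0.25,
) -> List[Tuple[int, int]]:
    """Greedy one-to-one matching of (onset, duration) intervals.

    A detection matches a true event when their intervals overlap, or their
    midpoints are within ``tol`` seconds.  Each true event is matched at most
    once, in onset order.
    """
    matches: List[Tuple[int, int]] = []
    used = set()
    for i, (d_on, d_dur) in enumerate(detected):
        d_mid = d_on + d_dur / 2
        best, best_dist = None, float("inf")
        for j, (t_on, t_dur) in enumerate(truth):
            if j in used:
                continue
            overlap = min(d_on + d_dur, t_on + t_dur) - max(d_on, t_on)
            dist = abs(d_mid - (t_on + t_dur / 2))
            if overlap > 0 or dist <= tol:
                if dist < best_dist:
                    best, best_dist = j, dist
        if best is not None:
            matches.append((i, best))
            used.add(best)
    return matches


def precision_recall(
    detected: Sequence[Tuple[float, float]],
    truth: Sequence[Tuple[float, float]],
    tol: float = 0.25,
) -> Tuple[float, float]:
    """Precision and recall of detections against ground truth intervals."""
    if not detected and not truth:
        return 1.0, 1.0
    matches = match_events(detected, truth, tol=tol)
    precision = len(matches) / len(detected) if detected else 1.0
    recall = len(matches) / len(truth) if truth else 1.0
    return precision, recall
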