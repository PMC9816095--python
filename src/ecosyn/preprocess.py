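"""Signal conditioning and epoching.

The analysis operates at 1 kHz: the acquired 20 kHz trace is anti-alias
filtered and decimated, 60-s epochs are cut every 30 min, and each epoch is
labelled with its protocol phase (baseline / prediazepam / postdiazepam) and
its offset from the diazepam injection.  All filtering is zero-phase
(forward–backward Butterworth), so event latencies are never shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
from scipy import signal

from .core import Condition, Phase, Recording, ValidationError

__all__ = [
    "Epoch",
    "PhaseWindow",
    "downsample",
    "bandpass",
    "extract_epochs",
    "phase_windows",
]

logger = logging.getLogger(__name__)


@dataclass
class Epoch:
    """A fixed-length analysis segment at 1 kHz."""

    subject_id: str
    condition: Condition
    start: float  # experiment clock, s
    duration: float
    phase: Phase
    offset_from_diazepam: float  # minutes, negative before injection
    samples: np.ndarray
    fs: float = 1000.0


@dataclass(frozen=True)
class PhaseWindow:
    """A per-phase analysis window on the experiment clock."""

    phase: Phase
    start: float
    stop: float
    partial: bool = False  # recording does not cover the nominal window

    @property
    def duration(self) -> float:
        return self.stop - self.start


def downsample(rec: Recording, target_fs: float = 1000.0) -> Recording:
    """Anti-alias low-pass then decimate to ``target_fs``.

    Only integer decimation ratios are supported; the low-pass is a zero-phase
    Butterworth with cutoff 0.4 × target_fs, so DC and the analysis bands pass
    untouched.
    """
    if target_fs <= 0:
        raise ValidationError("target_fs must be positive")
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValidationError(
            f"fs={rec.fs} is not an integer multiple of target_fs={target_fs}"
        )
    q = int(round(ratio))
    if q == 1:
        return rec
    sos = signal.butter(8, 0.4 * target_fs, btype="lowpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return rec.with_samples(filtered[::q], fs=target_fs)


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    if not (0 < low < high < rec.fs / 2):
        raise ValidationError(
            f"band edges must satisfy 0 < low < high < fs/2, got "
            f"({low}, {high}) at fs={rec.fs}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples))


def bandpass_array(x: np.ndarray, low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Array-level counterpart of :func:`bandpass` for window-wise filtering."""
    if not (0 < low < high < fs / 2):
        raise ValidationError(
            f"band edges must satisfy 0 < low < high < fs/2, got ({low}, {high}) at fs={fs}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def extract_epochs(
    rec: Recording, epoch_len: float = 60.0, interval_min: float = 30.0
) -> List[Epoch]:
    """Cut one ``epoch_len``-second epoch every ``interval_min`` minutes.

    Epochs start at t0 + k·interval; epochs running past the end of the
    recording are dropped.  Phase assignment uses the epoch *start* time
    (half-open phase intervals), so no epoch carries two phases even when it
    straddles an injection.
    """
    if epoch_len <= 0 or interval_min <= 0:
        raise ValidationError("epoch_len and interval must be positive")
    step = interval_min * 60.0
    epochs: List[Epoch] = []
    if rec.duration < epoch_len:
        logger.warning(
            "recording of %.1f s is shorter than one %.1f-s epoch", rec.duration, epoch_len
        )
        return epochs
    n_per_epoch = int(round(epoch_len * rec.fs))
    k = 0
    while True:
        start = rec.t0 + k * step
        i0 = int(round(k * step * rec.fs))
        if i0 + n_per_epoch > rec.samples.size:
            break
        epochs.append(
            Epoch(
                subject_id=rec.subject_id,
                condition=rec.condition,
                start=start,
                duration=epoch_len,
                phase=rec.timeline.phase_of(start),
                offset_from_diazepam=(start - rec.timeline.diazepam_t) / 60.0,
                samples=rec.samples[i0 : i0 + n_per_epoch],
                fs=rec.fs,
            )
        )
        k += 1
    return epochs


def phase_windows(rec: Recording, window_s: float = 3600.0) -> Dict[Phase, PhaseWindow]:
    """The three per-phase analysis windows (default one hour each).

    baseline ends at the scopolamine injection, prediazepam runs from the
    second pilocarpine dose to diazepam, postdiazepam starts at diazepam.
    Windows the recording only partly covers are clipped and flagged partial.
    """
    tl = rec.timeline
    nominal = {
        Phase.BASELINE: (tl.scopolamine_t - window_s, tl.scopolamine_t),
        Phase.PREDIAZEPAM: (tl.pilocarpine2_t, tl.diazepam_t),
        Phase.POSTDIAZEPAM: (tl.diazepam_t, tl.diazepam_t + window_s),
    }
    out: Dict[Phase, PhaseWindow] = {}
    for phase, (lo, hi) in nominal.items():
        clo, chi = max(lo, rec.t0), min(hi, rec.t_end)
        if chi <= clo:
            logger.warning("recording does not cover the %s window", phase.value)
            continue
        out[phase] = PhaseWindow(
            phase=phase, start=clo, stop=chi, partial=(clo > lo or chi < hi)
        )
    return out
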