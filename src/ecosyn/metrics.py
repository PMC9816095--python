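"""Amplitude and spectral metrics: RMS per epoch, band power per phase.

Band power uses a Welch PSD with 4-s Hann segments and 50 % overlap
(0.25 Hz resolution, enough to resolve the 0–4 Hz delta band) integrated
over half-open frequency bands, so a component at exactly 4 Hz counts toward
theta, never twice.  Summed over all bins the one-sided density recovers the
signal variance (Parseval), so the four band powers of a 0–30 Hz band-limited
signal add up to its variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import signal

from .core import Condition, Phase, Recording, ValidationError
from .preprocess import PhaseWindow, phase_windows

__all__ = [
    "BANDS",
    "EpochMetrics",
    "BandPower",
    "rms",
    "rms_reduction",
    "band_power",
    "phase_band_power",
]

#: Analysis bands (Hz), half-open [lo, hi).
BANDS: Dict[str, tuple] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}


@dataclass
class EpochMetrics:
    """Per-epoch summary row (one epoch of one subject)."""

    subject_id: str
    condition: Condition
    phase: Phase
    offset_from_diazepam: float  # minutes
    spike_rate: float  # events/min
    rms: float  # µV
    rms_pct_reduction: Optional[float] = None  # % vs baseline epoch


@dataclass
class BandPower:
    """Band-limited power (µV²) of one phase window of one subject."""

    subject_id: str
    condition: Condition
    phase: Phase
    power: Dict[str, float] = field(default_factory=dict)
    partial: bool = False  # window only partly covered by the recording


def rms(samples: np.ndarray) -> float:
    """Root mean square: sqrt of the arithmetic mean of squared samples."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValidationError("rms of an empty sample array is undefined")
    return float(np.sqrt(np.mean(x**2)))


def rms_reduction(epoch_rms: float, reference_rms: float) -> float:
    """Percent reduction of RMS relative to a reference (negative = increase)."""
    if not (reference_rms > 0):
        raise ValidationError("reference RMS must be positive")
    return 100.0 * (1.0 - epoch_rms / reference_rms)


def band_power(
    samples: np.ndarray,
    fs: float = 1000.0,
    bands: Dict[str, tuple] = BANDS,
    nperseg_s: float = 4.0,
) -> Dict[str, float]:
    """Welch band powers (µV²) over half-open bands [lo, hi).

    Requires at least two Welch segments' worth of signal (8 s at the default
    4-s segment length).
    """
    x = np.asarray(samples, dtype=float)
    nperseg = int(round(nperseg_s * fs))
    if x.size < 2 * nperseg:
        raise ValidationError(
            f"window of {x.size / fs:.1f} s too short for Welch PSD with "
            f"{nperseg_s:.0f}-s segments (need >= {2 * nperseg_s:.0f} s)"
        )
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", scaling="density",
    )
    df = freqs[1] - freqs[0]
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        out[name] = float(np.sum(psd[sel]) * df)
    return out


def phase_band_power(
    rec: Recording,
    window_s: float = 3600.0,
    windows: Optional[Dict[Phase, PhaseWindow]] = None,
) -> List[BandPower]:
    """Band powers per phase window (one BandPower per covered phase).

    Windows the recording does not cover at all are reported missing (absent
    from the output) rather than fabricated; partially covered windows are
    computed on the covered part and flagged.
    """
    if windows is None:
        windows = phase_windows(rec, window_s=window_s)
    out = []
    for phase in Phase:
        win = windows.get(phase)
        if win is None:
            continue
        seg = rec.slice(win.start, win.stop)
        out.append(
            BandPower(
                subject_id=rec.subject_id,
                condition=rec.condition,
                phase=phase,
                power=band_power(seg, fs=rec.fs),
                partial=win.partial,
            )
        )
    return out
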