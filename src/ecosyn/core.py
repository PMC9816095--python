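"""Core domain types shared by every stage of the pipeline.

The experiment clock follows the drug-administration protocol: t = 0 is the
scopolamine injection, the two pilocarpine doses follow 30 min apart, and
diazepam is given 60 min after the second pilocarpine dose.  A static magnet
(or its sham replica) sits on the skull for the first hour.  Recordings may
start before t = 0 (the pre-scopolamine baseline), so ``Recording.t0`` can be
negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "Condition",
    "Phase",
    "Timeline",
    "Recording",
    "EventRecord",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class Condition(str, enum.Enum):
    """Experimental group: real magnet or non-magnetic sham replica."""

    SHAM = "sham"
    MAGNET = "magnet"


class Phase(str, enum.Enum):
    """Analysis phase relative to the injection timeline.

    ``BASELINE`` is the window before scopolamine, ``PREDIAZEPAM`` the window
    between the second pilocarpine dose and diazepam, and ``POSTDIAZEPAM``
    everything from the diazepam injection on.
    """

    BASELINE = "baseline"
    PREDIAZEPAM = "prediazepam"
    POSTDIAZEPAM = "postdiazepam"


@dataclass(frozen=True)
class Timeline:
    """Injection / magnet schedule on the experiment clock (seconds).

    Defaults encode the standard protocol: scopolamine at t = 0, pilocarpine
    at 30 and 60 min, diazepam at 120 min, magnet (or sham replica) on from
    scopolamine until the second pilocarpine dose.
    """

    scopolamine_t: float = 0.0
    pilocarpine1_t: float = 1800.0
    pilocarpine2_t: float = 3600.0
    diazepam_t: float = 7200.0
    magnet_on: Tuple[float, float] = (0.0, 3600.0)

    def __post_init__(self) -> None:
        if not (
            self.scopolamine_t < self.pilocarpine1_t < self.pilocarpine2_t < self.diazepam_t
        ):
            raise ValidationError(
                "timeline must satisfy scopolamine < pilocarpine1 < pilocarpine2 < diazepam, "
                f"got {self.scopolamine_t}, {self.pilocarpine1_t}, "
                f"{self.pilocarpine2_t}, {self.diazepam_t}"
            )
        if self.magnet_on[0] > self.magnet_on[1]:
            raise ValidationError("magnet_on interval must have start <= end")

    def scaled(self, factor: float) -> "Timeline":
        """Return a compressed/stretched copy (all times multiplied by factor).

        Useful for reduced-duration simulations that keep the protocol shape.
        """
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return Timeline(
            scopolamine_t=self.scopolamine_t * factor,
            pilocarpine1_t=self.pilocarpine1_t * factor,
            pilocarpine2_t=self.pilocarpine2_t * factor,
            diazepam_t=self.diazepam_t * factor,
            magnet_on=(self.magnet_on[0] * factor, self.magnet_on[1] * factor),
        )

    def phase_of(self, t: float) -> Phase:
        """Phase of a time point (half-open intervals, start-inclusive).

        Times in [scopolamine, pilocarpine2) — the induction period — are
        grouped with the baseline for lack of a phase of their own; the three
        analysis phases proper are selected through window helpers.
        """
        if t >= self.diazepam_t:
            return Phase.POSTDIAZEPAM
        if t >= self.pilocarpine2_t:
            return Phase.PREDIAZEPAM
        return Phase.BASELINE


@dataclass
class Recording:
    """A uniformly sampled single-channel ECoG voltage trace (µV)."""

    subject_id: str
    condition: Condition
    samples: np.ndarray
    fs: float
    t0: float = 0.0
    timeline: Timeline = field(default_factory=Timeline)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must all be finite")
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if isinstance(self.condition, str):
            self.condition = Condition(self.condition)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        """End of the recording on the experiment clock."""
        return self.t0 + self.duration

    def time_axis(self) -> np.ndarray:
        """Sample times on the experiment clock (s)."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice(self, start: float, stop: float) -> np.ndarray:
        """Samples in the half-open experiment-clock window [start, stop)."""
        i0 = max(0, int(round((start - self.t0) * self.fs)))
        i1 = min(self.samples.size, int(round((stop - self.t0) * self.fs)))
        return self.samples[i0:i1]

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "Recording":
        return replace(self, samples=samples, fs=self.fs if fs is None else fs)


@dataclass(frozen=True)
class EventRecord:
    """A detected or ground-truth transient event.

    ``properties`` carries event-kind-specific numbers (peak amplitude,
    carrier frequency, peak count, ...), serialized to ``prop_*`` CSV columns.
    """

    kind: str  # "spike" or "ripple"
    onset: float
    duration: float
    properties: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("spike", "ripple"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.onset < 0:
            raise ValidationError(f"event onset must be >= 0, got {self.onset}")
        if not (self.duration > 0):
            raise ValidationError(f"event duration must be > 0, got {self.duration}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


def events_of_kind(events: List[EventRecord], kind: str) -> List[EventRecord]:
    """Filter an event list by kind, preserving order."""
    return [e for e in events if e.kind == kind]
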