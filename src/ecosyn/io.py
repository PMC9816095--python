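"""Readers and writers: EDF recordings, event CSV tables, timeline sidecars.

Signals travel as EDF (16-bit, physical range fixed at ±5000 µV so the
quantization step is deterministic); the subject's condition and injection
timeline travel in a YAML sidecar next to the EDF, because EDF header fields
are too limited to carry them.  Event tables (detections or ground truth) are
plain CSV with a ``kind,onset,duration,prop_*`` header; onsets are seconds
from the start of the recording they refer to.

Reading uses MNE; writing is a small EDF serializer of our own (one channel,
16-bit little-endian, the standard 256-byte header blocks).  The reader never
resamples or rescales beyond the EDF digital-to-physical mapping.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from pathlib import Path
from typing import List, Sequence

import numpy as np
import yaml

from .core import Condition, EventRecord, Recording, Timeline, ValidationError

__all__ = [
    "FormatError",
    "ParseError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "PHYS_RANGE_UV",
]

logger = logging.getLogger(__name__)

PHYS_RANGE_UV = 5000.0  # fixed EDF physical range: ±5000 µV
_DIG_MIN, _DIG_MAX = -32768, 32767


class FormatError(ValueError):
    """Raised when a file cannot be read as the expected format."""


class ParseError(ValueError):
    """Raised when a tabular file has a malformed row."""


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def write_recording(rec: Recording, path) -> None:
    """Write a Recording as single-channel EDF plus a YAML sidecar.

    The physical range is fixed at ±5000 µV; samples outside it are rejected
    rather than clipped so a round trip can never silently distort amplitudes.
    """
    path = Path(path)
    amax = float(np.max(np.abs(rec.samples)))
    if amax > PHYS_RANGE_UV:
        raise ValidationError(
            f"sample amplitude {amax:.1f} µV exceeds the EDF physical range "
            f"±{PHYS_RANGE_UV:.0f} µV"
        )
    n = rec.samples.size
    fs = rec.fs
    # 1-s records when the sample count divides evenly, otherwise one record
    # holding the whole signal (EDF allows non-integer record durations).
    if fs == int(fs) and n % int(fs) == 0:
        spr = int(fs)
        n_records = n // spr
        record_dur = "1"
    else:
        spr = n
        n_records = 1
        record_dur = f"{n / fs:.6g}"
        if len(record_dur) > 8:
            raise ValidationError("recording length not representable in an EDF record")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"{rec.subject_id} {rec.condition.value}", 80),
            _pad("ecosyn ECoG", 80),
            _pad("01.01.01", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * 2), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(record_dur, 8),
            _pad("1", 4),
            # signal header block (one channel)
            _pad("ECoG", 16),
            _pad("screw electrode", 80),
            _pad("uV", 8),
            _pad(f"{-PHYS_RANGE_UV:.0f}", 8),
            _pad(f"{PHYS_RANGE_UV:.0f}", 8),
            _pad(str(_DIG_MIN), 8),
            _pad(str(_DIG_MAX), 8),
            _pad("HP:1Hz LP:500Hz", 80),
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    scale = 2 * PHYS_RANGE_UV / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.samples + PHYS_RANGE_UV) / scale).astype(np.int64) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
    _write_sidecar(path, rec)


def _sidecar_path(edf_path: Path) -> Path:
    return edf_path.with_suffix(".yaml")


def _write_sidecar(edf_path: Path, rec: Recording) -> None:
    tl = rec.timeline
    doc = {
        "subject_id": rec.subject_id,
        "condition": rec.condition.value,
        "t0": float(rec.t0),
        "timeline": {
            "scopolamine_t": float(tl.scopolamine_t),
            "pilocarpine1_t": float(tl.pilocarpine1_t),
            "pilocarpine2_t": float(tl.pilocarpine2_t),
            "diazepam_t": float(tl.diazepam_t),
            "magnet_on": [float(tl.magnet_on[0]), float(tl.magnet_on[1])],
        },
    }
    with open(_sidecar_path(edf_path), "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_recording(path) -> Recording:
    """Read an EDF/EDF+ recording (first channel) and its YAML sidecar.

    Without a sidecar the timeline falls back to the standard protocol
    defaults (with a logged warning) and subject/condition are recovered from
    the EDF patient field where possible.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad files
        raise FormatError(f"could not read {path} as EDF: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise ValidationError(f"{path} contains no signal channels")
    data = raw.get_data(picks=[0])[0] * 1e6  # MNE returns volts; we store µV
    fs = float(raw.info["sfreq"])

    subject_id = "unknown"
    condition = Condition.SHAM
    t0 = 0.0
    timeline = Timeline()
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            doc = yaml.safe_load(fh) or {}
        subject_id = str(doc.get("subject_id", subject_id))
        condition = Condition(doc.get("condition", condition.value))
        t0 = float(doc.get("t0", 0.0))
        tl = doc.get("timeline") or {}
        timeline = Timeline(
            scopolamine_t=float(tl.get("scopolamine_t", 0.0)),
            pilocarpine1_t=float(tl.get("pilocarpine1_t", 1800.0)),
            pilocarpine2_t=float(tl.get("pilocarpine2_t", 3600.0)),
            diazepam_t=float(tl.get("diazepam_t", 7200.0)),
            magnet_on=tuple(tl.get("magnet_on", (0.0, 3600.0))),
        )
    else:
        logger.warning(
            "%s has no timeline sidecar; falling back to protocol defaults", path
        )
        with open(path, "rb") as fh:  # local-patient header field, bytes 8..88
            fh.seek(8)
            patient = fh.read(80).decode("ascii", errors="replace").strip()
        parts = patient.split()
        if parts:
            subject_id = parts[0]
        if len(parts) > 1 and parts[1] in (c.value for c in Condition):
            condition = Condition(parts[1])
    return Recording(
        subject_id=subject_id,
        condition=condition,
        samples=data,
        fs=fs,
        t0=t0,
        timeline=timeline,
    )


# ---------------------------------------------------------------------------
# Event CSV


def write_events(events: Sequence[EventRecord], path) -> None:
    """Write events as CSV (``kind,onset,duration,prop_*``), UTF-8, header row."""
    prop_keys = sorted({k for e in events for k in e.properties})
    header = ["kind", "onset", "duration"] + [f"prop_{k}" for k in prop_keys]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for e in events:
            row = [e.kind, repr(float(e.onset)), repr(float(e.duration))]
            row += [
                repr(float(e.properties[k])) if k in e.properties else ""
                for k in prop_keys
            ]
            writer.writerow(row)


def read_events(path) -> List[EventRecord]:
    """Read an event CSV written by :func:`write_events`.

    Malformed rows raise :class:`ParseError` naming the 1-based line number.
    """
    events: List[EventRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header row")
        required = ["kind", "onset", "duration"]
        if header[: len(required)] != required:
            raise ParseError(
                f"{path}: line 1: expected header starting with {required}, got {header[:3]}"
            )
        prop_keys = [c[len("prop_"):] for c in header[3:]]
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            try:
                onset = float(row[1])
                duration = float(row[2])
                props = {
                    k: float(v) for k, v in zip(prop_keys, row[3:]) if v != ""
                }
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if onset < 0:
                raise ParseError(f"{path}: line {lineno}: negative onset {onset}")
            if not duration > 0 or not math.isfinite(duration):
                raise ParseError(f"{path}: line {lineno}: bad duration {duration}")
            try:
                events.append(EventRecord(row[0], onset, duration, props))
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return events
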