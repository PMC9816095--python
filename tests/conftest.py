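"""Shared fixtures: compressed-protocol simulations and detector scores.

Heavy simulations are session-scoped so detector evaluation over many seeds
is paid for once.  All randomness is seeded; the suite is deterministic.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from ecosyn.core import Condition, Phase
from ecosyn.detect import detect_ripples, detect_spikes, estimate_baseline, match_events
from ecosyn.preprocess import Epoch
from ecosyn.simulate import SimParams, scaled_params, simulate_recording

# Protocol compressed 6x: scopolamine at t=0, pilocarpine at 300/600 s,
# diazepam at 1200 s, 600-s per-phase windows, 1 kHz synthesis.
SCALE = 1.0 / 6.0
SHORT_DURATION = 2400.0
N_EVAL_SEEDS = 20


@pytest.fixture(scope="session")
def short_params() -> SimParams:
    return scaled_params(SimParams(fs=1000.0), SCALE)


@pytest.fixture(scope="session")
def sim_pair(short_params):
    """One compressed-protocol sham recording plus its ground truth."""
    return simulate_recording(short_params, Condition.SHAM, SHORT_DURATION, seed=7)


def baseline_epoch(rec):
    return Epoch(
        rec.subject_id, rec.condition, rec.t0, 60.0, Phase.BASELINE,
        (rec.t0 - rec.timeline.diazepam_t) / 60.0, rec.samples[:60000], rec.fs,
    )


@pytest.fixture(scope="session")
def detector_scores(short_params):
    """Pooled detection counts against ground truth over many seeds.

    Spikes are detected over the whole recording; ripples per phase window,
    matching the pipeline's per-window threshold semantics, so ripple recall
    is evaluated against the true events that lie inside those windows.
    Returns per-detector dicts with pooled true/false positives and false
    negatives plus per-seed precision/recall.
    """
    from ecosyn.preprocess import phase_windows

    out = {
        "spike": {"tp": 0, "fp": 0, "fn": 0, "precision": [], "recall": []},
        "ripple": {"tp": 0, "fp": 0, "fn": 0, "precision": [], "recall": []},
    }
    freq_errors = []
    window_s = 600.0
    for seed in range(N_EVAL_SEEDS):
        rec, truth = simulate_recording(
            short_params, Condition.SHAM, SHORT_DURATION, seed=seed
        )
        base = estimate_baseline(baseline_epoch(rec))
        windows = phase_windows(rec, window_s=window_s).values()

        def in_windows(onset):
            t = rec.t0 + onset
            return any(w.start <= t < w.stop for w in windows)

        ripple_events = []
        det_ripples = []
        for w in windows:
            seg = rec.slice(w.start, w.stop)
            off = w.start - rec.t0
            for e in detect_ripples(seg):
                ripple_events.append(e)
                det_ripples.append((e.onset + off, e.duration))
        detections = {
            "spike": [(e.onset, e.duration) for e in detect_spikes(rec, base)],
            "ripple": det_ripples,
        }
        truths = {
            "spike": [(e.onset, e.duration) for e in truth.spike_events],
            "ripple": [
                (e.onset, e.duration)
                for e in truth.ripple_events
                if in_windows(e.onset)
            ],
        }
        tols = {"spike": 0.3, "ripple": 0.1}
        for kind in ("spike", "ripple"):
            m = match_events(detections[kind], truths[kind], tol=tols[kind])
            tp = len(m)
            fp = len(detections[kind]) - tp
            fn = len(truths[kind]) - tp
            out[kind]["tp"] += tp
            out[kind]["fp"] += fp
            out[kind]["fn"] += fn
            out[kind]["precision"].append(tp / max(tp + fp, 1))
            out[kind]["recall"].append(tp / max(tp + fn, 1))
        truth_ripples_in = [e for e in truth.ripple_events if in_windows(e.onset)]
        m = match_events(
            detections["ripple"],
            [(e.onset, e.duration) for e in truth_ripples_in],
            tol=0.1,
        )
        for i, j in m:
            freq_errors.append(
                ripple_events[i].mean_freq - truth_ripples_in[j].properties["freq"]
            )
    for kind in ("spike", "ripple"):
        d = out[kind]
        d["pooled_precision"] = d["tp"] / (d["tp"] + d["fp"])
        d["pooled_recall"] = d["tp"] / (d["tp"] + d["fn"])
    out["ripple_freq_errors"] = np.asarray(freq_errors)
    return out


@pytest.fixture(scope="session")
def null_spike_params(short_params) -> SimParams:
    """Magnet effect switched off entirely (statistical null)."""
    sp = replace(
        short_params.spikes,
        postdiazepam_rate_magnet=short_params.spikes.postdiazepam_rate_sham,
        magnet_prediazepam_scale=1.0,
    )
    return replace(short_params, spikes=sp)
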