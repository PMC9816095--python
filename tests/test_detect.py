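import numpy as np
import pytest

from ecosyn.core import Condition, Phase, ValidationError
from ecosyn.detect import (
    BaselineStats,
    detect_ripples,
    detect_spikes,
    estimate_baseline,
    match_events,
    mean_ripple_frequency,
    normalize_rates,
    precision_recall,
    ripple_rate,
    spike_rate,
)
from ecosyn.preprocess import Epoch, bandpass_array
from ecosyn.simulate import ripple_waveform, spike_waveform, _pink_noise


def make_epoch(x, fs=1000.0, phase=Phase.BASELINE):
    return Epoch("s", Condition.SHAM, 0.0, len(x) / fs, phase, -120.0, np.asarray(x), fs)


class TestEstimateBaseline:
    def test_sinusoid_envelope_equals_amplitude(self):
        t = np.arange(0, 60, 1e-3)
        stats = estimate_baseline(make_epoch(np.sin(2 * np.pi * 5 * t)))
        assert stats.baseline_amp == pytest.approx(1.0, rel=0.05)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 50, 60_000)
        a = estimate_baseline(make_epoch(x)).baseline_amp
        b = estimate_baseline(make_epoch(2.5 * x)).baseline_amp
        assert b == pytest.approx(2.5 * a, rel=1e-9)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValidationError):
            estimate_baseline(make_epoch(np.zeros(60_000)))


@pytest.fixture
def noisy_background():
    rng = np.random.default_rng(42)
    t = np.arange(0, 120, 1e-3)
    return 100 * np.sin(2 * np.pi * 1.0 * t) + 10 * rng.standard_normal(t.size)


class TestDetectSpikes:
    def test_baseline_signal_alone_yields_no_events(self, noisy_background):
        base = estimate_baseline(make_epoch(noisy_background[:60_000]))
        assert detect_spikes(noisy_background[:60_000], base) == []

    @pytest.mark.parametrize(
        "duration,ratio,expected",
        [
            (0.5, 3.0, 1),   # satisfies both criteria
            (0.1, 3.0, 0),   # too short
            (0.5, 1.5, 0),   # too small
        ],
    )
    def test_criterion_fidelity_on_injected_transient(
        self, noisy_background, duration, ratio, expected
    ):
        base = estimate_baseline(make_epoch(noisy_background[:60_000]))
        x = noisy_background[:60_000].copy()
        w = spike_waveform(duration, ratio * base.baseline_amp, 1000.0, 3)
        x[30_000 : 30_000 + w.size] += w
        events = detect_spikes(x, base)
        assert len(events) == expected
        if expected:
            ev = events[0]
            assert ev.duration >= 0.3
            assert ev.amp_ratio >= 2.0
            assert abs(ev.onset + ev.duration / 2 - (30.0 + duration / 2)) < 0.3

    def test_scale_invariance(self, noisy_background):
        base = estimate_baseline(make_epoch(noisy_background[:60_000]))
        x = noisy_background[:60_000].copy()
        w = spike_waveform(0.5, 3.0 * base.baseline_amp, 1000.0, 3)
        x[30_000 : 30_000 + w.size] += w
        ref = detect_spikes(x, base)
        scaled_base = BaselineStats(base.baseline_amp * 7.0)
        scaled = detect_spikes(x * 7.0, scaled_base)
        assert [(e.onset, e.duration) for e in scaled] == [
            (e.onset, e.duration) for e in ref
        ]

    def test_nearby_segments_merge_into_one_discharge(self):
        # a discharge briefly dipping below threshold is not split in two
        x = np.zeros(10_000)
        base = BaselineStats(1.0)
        t = np.arange(400) / 1000.0
        burst = 5.0 * np.sin(2 * np.pi * 10 * t)
        x[3000:3400] = burst
        x[3430:3830] = burst  # 30 ms gap < 50 ms merge gap
        events = detect_spikes(x, base)
        assert len(events) == 1
        assert events[0].duration >= 0.7


class TestRateHelpers:
    def test_spike_rate_per_minute(self):
        assert spike_rate(range(12), 60.0) == 12.0
        assert spike_rate([], 60.0) == 0.0
        with pytest.raises(ValidationError):
            spike_rate([], 0.0)

    def test_normalize_rates_to_reference_timepoint(self):
        rates = {-60.0: 10.0, 0.0: 10.0, 30.0: 5.0}
        norm = normalize_rates(rates, reference_time=0.0)
        assert norm == {-60.0: 1.0, 0.0: 1.0, 30.0: 0.5}

    def test_zero_reference_flags_subject(self):
        assert normalize_rates({0.0: 0.0, 30.0: 5.0}, 0.0) is None

    def test_ripple_rate_and_mean_frequency(self):
        assert ripple_rate(range(10), 3600.0) == 10.0
        events = [
            type("E", (), {"mean_freq": 90.0})(),
            type("E", (), {"mean_freq": 100.0})(),
        ]
        assert mean_ripple_frequency(events) == 95.0
        assert mean_ripple_frequency([]) is None


class TestDetectRipples:
    @pytest.fixture
    def pink(self):
        rng = np.random.default_rng(7)
        return _pink_noise(120_000, 20.0, rng)

    def band_sd(self, x):
        return bandpass_array(x, 80.0, 200.0, 1000.0).std()

    def test_injected_burst_detected_with_frequency(self, pink):
        sd = self.band_sd(pink)
        x = pink.copy()
        w = ripple_waveform(100.0, 6, 5 * sd, 1000.0)
        x[60_000 : 60_000 + w.size] += w
        events = [e for e in detect_ripples(x) if abs(e.onset - 60.0) < 0.2]
        assert len(events) == 1
        ev = events[0]
        assert ev.n_peaks >= 4
        assert ev.mean_freq == pytest.approx(100.0, abs=10.0)
        assert ev.max_amp_sd > 3.0

    def test_three_cycle_burst_rejected(self, pink):
        sd = self.band_sd(pink)
        x = pink.copy()
        w = ripple_waveform(100.0, 3, 5 * sd, 1000.0)
        x[60_000 : 60_000 + w.size] += w
        assert [e for e in detect_ripples(x) if abs(e.onset - 60.0) < 0.2] == []

    def test_outputs_satisfy_type_invariants(self, sim_pair):
        rec, _ = sim_pair
        for ev in detect_ripples(rec):
            assert ev.n_peaks >= 4
            assert ev.max_amp_sd > 3.0
            assert ev.offset > ev.onset

    def test_monotone_in_threshold_and_min_peaks(self, sim_pair):
        rec, _ = sim_pair
        x = rec.samples[: 600_000]
        counts_sd = [len(detect_ripples(x, sd_mult=s)) for s in (3.0, 3.5, 4.0, 5.0)]
        assert counts_sd == sorted(counts_sd, reverse=True)
        counts_pk = [len(detect_ripples(x, min_peaks=k)) for k in (4, 5, 6, 8)]
        assert counts_pk == sorted(counts_pk, reverse=True)

    def test_validation(self):
        with pytest.raises(ValidationError):
            detect_ripples(np.zeros(500), fs=1000.0)  # < 1 s
        with pytest.raises(ValidationError):
            detect_ripples(np.zeros(2000), band=(80.0, 600.0), fs=1000.0)


class TestMatching:
    def test_greedy_one_to_one(self):
        det = [(1.0, 0.5), (1.1, 0.5), (5.0, 0.5)]
        truth = [(1.0, 0.5), (9.0, 0.5)]
        matches = match_events(det, truth)
        assert matches == [(0, 0)]
        p, r = precision_recall(det, truth)
        assert (p, r) == (1 / 3, 1 / 2)

    def test_empty_sets(self):
        assert precision_recall([], []) == (1.0, 1.0)
        assert precision_recall([(1.0, 0.1)], []) == (0.0, 1.0)
        assert precision_recall([], [(1.0, 0.1)]) == (1.0, 0.0)
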