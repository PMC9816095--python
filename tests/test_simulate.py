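import numpy as np
import pytest
from dataclasses import replace

from ecosyn.core import Condition, ValidationError
from ecosyn.preprocess import bandpass_array
from ecosyn.simulate import (
    RippleParams,
    SimParams,
    SpikeParams,
    phase_event_rates,
    ripple_rate_at,
    simulate_cohort,
    simulate_ground_truth,
    simulate_recording,
    spike_rate_at,
)
from tests.conftest import SHORT_DURATION


def _zero_rate_params(base: SimParams) -> SimParams:
    return replace(
        base,
        spikes=replace(
            base.spikes,
            baseline_rate=0.0, pilocarpine_rate=0.0,
            postdiazepam_rate_sham=0.0, postdiazepam_rate_magnet=0.0,
        ),
        ripples=replace(
            base.ripples,
            baseline_rate=0.0, pilocarpine_rate=0.0, postdiazepam_rate=0.0,
        ),
    )


class TestValidation:
    def test_detectability_constraints_enforced(self):
        with pytest.raises(ValidationError):
            SimParams(spikes=SpikeParams(amp_ratio=1.5))
        with pytest.raises(ValidationError):
            SimParams(spikes=SpikeParams(duration_range=(0.1, 0.5)))
        with pytest.raises(ValidationError):
            SimParams(ripples=RippleParams(n_cycles_range=(3, 8)))
        with pytest.raises(ValidationError):
            SimParams(ripples=RippleParams(amp_sd_multiple=2.0))
        with pytest.raises(ValidationError):
            SimParams(ripples=RippleParams(freq_range=(50.0, 150.0)))

    def test_duration_must_cover_timeline(self, short_params):
        with pytest.raises(ValidationError):
            simulate_ground_truth(short_params, Condition.SHAM, 500.0, seed=0)

    def test_cohort_size_validated(self, short_params):
        with pytest.raises(ValidationError):
            simulate_cohort(0, short_params, seed=0)


class TestDeterminism:
    def test_identical_seed_gives_identical_ground_truth(self, short_params):
        a = simulate_ground_truth(short_params, Condition.SHAM, SHORT_DURATION, seed=3)
        b = simulate_ground_truth(short_params, Condition.SHAM, SHORT_DURATION, seed=3)
        assert a.spike_events == b.spike_events
        assert a.ripple_events == b.ripple_events

    def test_ground_truth_and_recording_share_events(self, short_params):
        gt = simulate_ground_truth(short_params, Condition.SHAM, SHORT_DURATION, seed=3)
        rec, truth = simulate_recording(short_params, Condition.SHAM, SHORT_DURATION, seed=3)
        assert [(e.onset, e.duration) for e in gt.spike_events] == [
            (e.onset, e.duration) for e in truth.spike_events
        ]

    def test_cohort_reproducible(self, short_params):
        a = simulate_cohort(2, short_params, seed=5, duration=SHORT_DURATION, events_only=True)
        b = simulate_cohort(2, short_params, seed=5, duration=SHORT_DURATION, events_only=True)
        for (_, ta), (_, tb) in zip(a, b):
            assert ta.spike_events == tb.spike_events
            assert ta.ripple_events == tb.ripple_events


class TestBackground:
    def test_zero_rates_give_pure_background(self, short_params):
        params = _zero_rate_params(short_params)
        rec, truth = simulate_recording(params, Condition.SHAM, SHORT_DURATION, seed=1)
        assert truth.spike_events == [] and truth.ripple_events == []
        # background stays well under the spike detection threshold
        assert np.max(np.abs(rec.samples)) < 2.5 * truth.baseline_env_amp

    def test_noiseless_symmetric_background_is_periodic(self, short_params):
        params = _zero_rate_params(short_params)
        params = replace(params, background=replace(params.background, pink_noise_sd=0.0))
        rec, _ = simulate_recording(params, Condition.SHAM, SHORT_DURATION, seed=1)
        period = int(rec.fs / params.background.slow_osc_freq)
        x = rec.samples[period : 10 * period]
        np.testing.assert_allclose(x, rec.samples[2 * period : 11 * period], atol=1e-9)
        rec2, _ = simulate_recording(params, Condition.SHAM, SHORT_DURATION, seed=99)
        np.testing.assert_array_equal(rec.samples, rec2.samples)  # noise-free


class TestRates:
    def test_rate_trajectory_shape(self, short_params):
        tl = short_params.timeline
        sp = short_params.spikes
        t = np.array([tl.scopolamine_t - 300.0, tl.pilocarpine2_t, tl.diazepam_t + 3000.0])
        sham = spike_rate_at(t, short_params, Condition.SHAM)
        magnet = spike_rate_at(t, short_params, Condition.MAGNET)
        assert sham[0] == pytest.approx(sp.baseline_rate)
        assert sham[1] == pytest.approx(sp.pilocarpine_rate, rel=0.01)
        assert sham[2] == pytest.approx(sp.postdiazepam_rate_sham, rel=0.05)
        assert magnet[1] == pytest.approx(
            sp.pilocarpine_rate * sp.magnet_prediazepam_scale, rel=0.01
        )
        assert magnet[2] == pytest.approx(sp.postdiazepam_rate_magnet, rel=0.05)
        # ripples are condition-independent by construction
        np.testing.assert_array_equal(
            ripple_rate_at(t, short_params), ripple_rate_at(t, short_params)
        )

    def test_prediazepam_spike_count_matches_poisson_oracle(self):
        """Event counts in the prediazepam hour follow the programmed rate."""
        params = SimParams(fs=1000.0)
        truth = simulate_ground_truth(params, Condition.SHAM, 14400.0, seed=1)
        tl = params.timeline
        count = sum(
            1
            for e in truth.spike_events
            if tl.pilocarpine2_t <= params.t0 + e.onset < tl.diazepam_t
        )
        expected = params.spikes.pilocarpine_rate * 60.0
        assert abs(count - expected) <= 4 * np.sqrt(expected)

    def test_empirical_rates_track_programmed_rates(self, short_params):
        """Mean prediazepam counts over seeds within 3 SE of the intensity."""
        counts = []
        tl = short_params.timeline
        for seed in range(30):
            truth = simulate_ground_truth(
                short_params, Condition.SHAM, SHORT_DURATION, seed=100 + seed
            )
            counts.append(
                sum(
                    1
                    for e in truth.spike_events
                    if tl.pilocarpine2_t <= short_params.t0 + e.onset < tl.diazepam_t
                )
            )
        expected = short_params.spikes.pilocarpine_rate * (
            (tl.diazepam_t - tl.pilocarpine2_t) / 60.0
        )
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_phase_event_rates_window_clipping(self, short_params):
        truth = simulate_ground_truth(short_params, Condition.SHAM, SHORT_DURATION, seed=2)
        rates = phase_event_rates(truth, window_s=600.0)
        assert set(rates) == {"baseline", "prediazepam", "postdiazepam"}
        # a span ending at diazepam leaves no postdiazepam window
        short = simulate_ground_truth(short_params, Condition.SHAM, 1800.0, seed=2)
        assert "postdiazepam" not in phase_event_rates(short, window_s=600.0)


class TestCohort:
    def test_cohort_structure(self, short_params):
        cohort = simulate_cohort(
            6, short_params, seed=1, duration=SHORT_DURATION, events_only=True
        )
        assert len(cohort) == 12
        conditions = [t.condition for _, t in cohort]
        assert conditions.count(Condition.SHAM) == 6
        assert conditions.count(Condition.MAGNET) == 6
        assert len({t.subject_id for _, t in cohort}) == 12

    def test_zero_jitter_gives_identical_expected_rates(self, short_params):
        params = replace(short_params, jitter_sd=0.0)
        cohort = simulate_cohort(
            1, params, seed=1, duration=SHORT_DURATION, events_only=True
        )
        for _, truth in cohort:
            assert truth.params.spikes.pilocarpine_rate == params.spikes.pilocarpine_rate


class TestInjectedDetectability:
    def test_every_injected_ripple_has_four_peaks_above_threshold(self, sim_pair):
        """The generator's ripples satisfy the detection criterion by design."""
        rec, truth = sim_pair
        filt = bandpass_array(rec.samples, 80.0, 200.0, rec.fs)
        thr = filt.mean() + 3.0 * filt.std()
        from scipy.signal import find_peaks

        ok = 0
        for ev in truth.ripple_events:
            i0 = int((ev.onset - 0.5 * ev.duration) * rec.fs)
            i1 = int((ev.onset + 1.5 * ev.duration) * rec.fs)
            peaks, _ = find_peaks(filt[max(i0, 0) : i1], height=thr)
            if peaks.size >= 4:
                ok += 1
        assert ok / len(truth.ripple_events) >= 0.9

    def test_spike_gap_keeps_ground_truth_unambiguous(self, sim_pair):
        _, truth = sim_pair
        ev = sorted(truth.spike_events, key=lambda e: e.onset)
        gaps = [b.onset - (a.onset + a.duration) for a, b in zip(ev, ev[1:])]
        assert min(gaps) > 0.0
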