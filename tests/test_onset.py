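"""Envelope extraction and the dual-threshold amplitude-onset rule."""

import numpy as np
import pytest

from eggms.onset import (
    Envelope,
    OnsetConfig,
    OnsetResult,
    compare_events,
    compute_envelope,
    detect_onsets,
    onset_metrics,
)
from eggms.preprocess import bandpass_filter
from eggms.synthetic import ButtonEvents, EpisodeSpec, SimConfig, generate_session


def _env(values, fs=2.0, t0=0.0):
    return Envelope(values=np.asarray(values, float), window_samples=300, fs=fs, t0=t0)


class TestComputeEnvelope:
    def test_constant_signal_envelope_is_abs(self):
        env = compute_envelope(np.full(1200, -7.0), fs=2.0)
        np.testing.assert_allclose(env.values, 7.0)

    def test_sinusoid_envelope_near_rectified_median(self):
        """Median of |sin| over full cycles is sin(pi/4) ~ 0.707 A."""
        t = np.arange(1800) / 2.0
        a = 200.0
        env = compute_envelope(a * np.sin(2 * np.pi * 0.05 * t), fs=2.0)
        core = env.values[300:-300]
        assert np.all(core >= 0.5 * a) and np.all(core <= a)
        assert np.median(core) == pytest.approx(a * np.sin(np.pi / 4), rel=0.05)
        # stationary: little drift across the signal
        assert np.ptp(core) < 0.1 * a

    def test_amplitude_step_transition_confined_to_one_window(self):
        t = np.arange(2400) / 2.0
        a = np.where(t < 600, 100.0, 200.0)
        x = a * np.sin(2 * np.pi * 0.05 * t)
        env = compute_envelope(x, fs=2.0, config=OnsetConfig())
        w = 300  # samples
        step = 1200
        lo = np.median(env.values[300:step - w])
        hi = np.median(env.values[step + w:-300])
        assert hi == pytest.approx(2 * lo, rel=0.05)
        # before the window reaches the step the envelope stays at the low level
        assert np.all(env.values[300:step - w] < 1.2 * lo)
        assert np.all(env.values[step + w:-300] > 0.8 * hi)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter than envelope window"):
            compute_envelope(np.ones(100), fs=2.0)

    def test_window_samples_from_duration_and_rate(self):
        assert OnsetConfig().window_samples(2.0) == 300


class TestDetectOnsets:
    """Truth table of the dual-threshold rule on hand-built envelopes."""

    def _run(self, sample_value, base_mean=100.0, trial_mean=None):
        trial_values = np.full(900, trial_mean)
        trial_values[400:420] = sample_value
        # rescale so the trial envelope mean stays at trial_mean
        trial_values += trial_mean - trial_values.mean()
        base = _env(np.full(900, base_mean))
        return detect_onsets(_env(trial_values), base)

    def test_sample_exceeding_both_thresholds_is_flagged(self):
        res = self._run(250.0, base_mean=100.0, trial_mean=120.0)
        assert res.duration_s > 0  # 250 > 200 and 250 > 192

    def test_sample_below_baseline_threshold_not_flagged(self):
        res = self._run(190.0, base_mean=100.0, trial_mean=120.0)
        assert res.duration_s == 0  # 190 < 2.0 x 100

    def test_sample_below_trial_threshold_not_flagged(self):
        res = self._run(205.0, base_mean=100.0, trial_mean=130.0)
        assert res.duration_s == 0  # 205 > 200 but 205 < 1.6 x 130

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline envelope is empty"):
            detect_onsets(_env(np.full(900, 1.0)), _env(np.array([])))

    def test_episodes_are_maximal_runs_and_duration_consistent(self):
        values = np.full(900, 10.0)
        values[100:200] = 500.0
        values[400:500] = 500.0
        res = detect_onsets(_env(values), _env(np.full(900, 10.0)))
        assert len(res.episodes) == 2
        assert res.episodes[0] == (50.0, 100.0)
        assert res.duration_s == pytest.approx(sum(e - s for s, e in res.episodes))
        assert res.duration_s == res.mask.sum() / 2.0

    def test_raising_thresholds_never_increases_duration(self):
        rng = np.random.default_rng(4)
        trial = _env(np.abs(rng.normal(120, 60, size=1800)))
        base = _env(np.abs(rng.normal(80, 20, size=1800)))
        durations = []
        for bf, tf in [(1.5, 1.2), (2.0, 1.2), (2.5, 1.2), (1.5, 1.6), (1.5, 2.0)]:
            cfg = OnsetConfig(baseline_factor=bf, trial_factor=tf)
            durations.append(detect_onsets(trial, base, cfg).duration_s)
        assert durations[0] >= durations[1] >= durations[2]
        assert durations[0] >= durations[3] >= durations[4]

    def test_stationary_sessions_yield_zero_duration(self):
        """Null behavior: no episodes -> no flagged time in >=95% of runs."""
        zeros = 0
        for seed in range(100):
            cfg = SimConfig(seed=seed, noise_sd_uv=20.0)
            bundle = generate_session(cfg)
            filt = bandpass_filter(bundle.egg)
            seg = bundle.segments
            x = filt.samples[0]
            base = compute_envelope(x[filt.sample_slice(*seg.trial1)], 2.0)
            trial = compute_envelope(x[filt.sample_slice(*seg.trial2)], 2.0)
            res = detect_onsets(trial, base)
            zeros += res.duration_s == 0
        assert zeros >= 95


class TestOnsetMetrics:
    def _result(self, n_flagged, n=1800):
        mask = np.zeros(n, dtype=bool)
        mask[:n_flagged] = True
        return OnsetResult(mask=mask, episodes=((0.0, n_flagged / 2.0),) if n_flagged else (),
                           duration_s=n_flagged / 2.0, fs=2.0)

    def test_flagged_samples_to_seconds(self):
        dur, _ = onset_metrics(self._result(120), np.ones(1800), baseline_rms=1.0)
        assert dur == 60.0

    def test_relative_rms_increase(self):
        sig = np.zeros(1800)
        sig[:120] = 300.0
        dur, rel = onset_metrics(self._result(120), sig, baseline_rms=150.0)
        assert rel == pytest.approx(100.0)

    def test_empty_mask_reports_absent_increase(self):
        dur, rel = onset_metrics(self._result(0), np.ones(1800), baseline_rms=150.0)
        assert dur == 0.0
        assert rel is None

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline_rms"):
            onset_metrics(self._result(10), np.ones(1800), baseline_rms=0.0)


class TestCompareEvents:
    def _result_with_episodes(self, episodes):
        return OnsetResult(mask=np.zeros(10, bool), episodes=tuple(episodes),
                           duration_s=0.0, fs=2.0)

    def test_lead_is_episode_start_minus_preceding_press(self):
        res = self._result_with_episodes([(160.0, 200.0)])
        cmp = compare_events(res, ButtonEvents((100.0,)))
        assert cmp.leads_s == (60.0,)
        assert cmp.mean_lead_s == 60.0

    def test_no_presses_gives_empty_summary(self):
        res = self._result_with_episodes([(160.0, 200.0)])
        cmp = compare_events(res, ButtonEvents(()))
        assert cmp.leads_s == ()
        assert cmp.mean_lead_s is None

    def test_presses_counted_per_segment(self):
        res = self._result_with_episodes([])
        cmp = compare_events(res, ButtonEvents((10.0, 20.0, 150.0)),
                             segments={"a": (0.0, 100.0), "b": (100.0, 200.0)})
        assert cmp.presses_per_segment == {"a": 2, "b": 1}

    def test_generator_lead_recovered_over_seeds(self):
        """With one press per episode, mean lead to the true window ~ 60 s."""
        ep = EpisodeSpec(start_s=1440.0, end_s=1740.0, amp_gain=2.5,
                         press_rate_per_min=0.01)
        leads = []
        for seed in range(100):
            bundle = generate_session(SimConfig(seed=seed, episodes=(ep,)))
            res = self._result_with_episodes([(ep.start_s, ep.end_s)])
            cmp = compare_events(res, bundle.buttons)
            leads.extend(cmp.leads_s)
        assert np.mean(leads) == pytest.approx(60.0, abs=10.0)
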