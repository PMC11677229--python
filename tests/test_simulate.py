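"""Generator contracts: trial statistics, trace construction, ground truth."""
import numpy as np
import pytest

import tuftpipe as tp
from tuftpipe.datamodel import ConfigError

from conftest import kernel_trace


def tiny_cfg(**kw):
    base = dict(n_tufts=1, n_sessions=1, n_trials=30, seed=0)
    base.update(kw)
    return tp.SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("p_cs_plus", 1.5), ("p_cs_plus", -0.1), ("noise_sd", -1.0),
        ("iti_range_s", (12.0, 8.0)), ("frames_per_second", 0.0),
        ("kernel_rise_s", 0.5), ("arm", "other"),
        ("spont_rate_per_min", float("nan")),
    ])
    def test_bad_values_rejected(self, field, value):
        with pytest.raises(ConfigError):
            tiny_cfg(**{field: value}).validate()

    def test_default_config_valid(self):
        tp.SimConfig().validate()


class TestTrialStructure:
    def test_cs_plus_fraction_near_half(self):
        # 180 trials at p=0.5; mean fraction over 50 seeded cohorts
        fracs = []
        for seed in range(50):
            cfg = tiny_cfg(n_trials=180, seed=seed)
            sessions, _ = tp.simulate_cohort(cfg)
            stim = sessions[0].trials.stimulus
            fracs.append(np.mean(stim == "CS+"))
        assert abs(np.mean(fracs) - 0.5) < 0.04

    def test_itis_within_bounds(self):
        sessions, _ = tp.simulate_cohort(tiny_cfg(n_trials=100, seed=3))
        gaps = np.diff(sessions[0].trials.onset_time)
        assert gaps.min() >= 8.0 and gaps.max() <= 12.0

    def test_evoked_draws_match_trial_count(self):
        cfg = tiny_cfg(n_tufts=3, n_trials=50, seed=5)
        sessions, gt = tp.simulate_cohort(cfg)
        for succ in gt.evoked_success[0]:
            assert succ.size == sessions[0].trials.n_trials


class TestTraceConstruction:
    def test_all_sources_off_gives_zero_traces(self):
        cfg = tiny_cfg(noise_sd=0.0, spont_rate_per_min=0.0, frac_unresponsive=1.0)
        sessions, _ = tp.simulate_cohort(cfg)
        for t in sessions[0].tufts:
            assert np.all(t.dff == 0.0)

    def test_trace_matches_kernel_superposition_oracle(self):
        # noise-free trace equals an independently summed kernel train
        cfg = tiny_cfg(noise_sd=0.0, spont_rate_per_min=0.0, frac_unresponsive=0.0,
                       event_amplitude_sd=0.0, n_trials=20, seed=8)
        sessions, gt = tp.simulate_cohort(cfg)
        s = sessions[0]
        ev = s.trials.onset_time[gt.evoked_success[0][0]]
        oracle = kernel_trace(ev, np.full(ev.size, 0.28), s.tufts[0].n_frames)
        assert np.allclose(s.tufts[0].dff, oracle, atol=1e-9)

    def test_amplitude_equals_kernel_window_mean(self):
        # success prob 1, amplitude 0.28, no noise: per-trial amplitude equals
        # the discrete mean of the unit-peak kernel over the 1.5 s window
        cfg = tiny_cfg(noise_sd=0.0, spont_rate_per_min=0.0, frac_unresponsive=0.0,
                       event_amplitude_sd=0.0, p_pref_range=(1.0, 1.0),
                       si_sd_pre=1e-12, n_trials=20, seed=2)
        sessions, _ = tp.simulate_cohort(cfg)
        s = sessions[0]
        rs = tp.trial_amplitudes(s.tufts[0], s.trials)
        fs = 30.0

        def window_mean(onset):
            f0 = int(np.floor(onset * fs))
            frames = np.arange(f0, f0 + 45) / fs
            return 0.28 * np.where(frames >= onset,
                                   tp.calcium_kernel(frames - onset), 0.0).mean()

        # first trial has no preceding events at all: oracle exact to 1e-9
        stim0 = s.trials.stimulus[0]
        assert abs(rs.amplitudes[stim0][0]
                   - window_mean(s.trials.onset_time[0])) < 1e-9
        # later trials carry <=1e-8 ΔF/F kernel tails from earlier trials
        for stim in ("CS+", "CS-"):
            expected = [window_mean(o) for o in s.trials.onsets(stim)]
            assert np.allclose(rs.amplitudes[stim], expected, atol=1e-6)

    def test_reproducibility_bit_identical(self):
        cfg = tiny_cfg(n_tufts=2, n_sessions=2, seed=17)
        s1, g1 = tp.simulate_cohort(cfg)
        s2, g2 = tp.simulate_cohort(tiny_cfg(n_tufts=2, n_sessions=2, seed=17))
        for a, b in zip(s1, s2):
            assert np.array_equal(a.tufts[0].dff, b.tufts[0].dff)
            assert np.array_equal(a.licks, b.licks)
            assert np.array_equal(a.whisker_angle, b.whisker_angle)
        assert np.array_equal(g1.si, g2.si)


class TestGroundTruthStructure:
    def test_true_si_reproduced_by_success_probabilities(self):
        _, gt = tp.simulate_cohort(tiny_cfg(n_tufts=50, frac_unresponsive=0.0,
                                            seed=4, n_trials=2))
        p = gt.p_success[0]
        si = (p[:, 0] - p[:, 1]) / (p[:, 0] + p[:, 1])
        assert np.allclose(si, gt.si[0], atol=1e-12)
        assert np.all(np.abs(gt.si) <= 1.0)

    def test_conditioned_final_abs_si_dominates_exposure(self):
        kw = dict(n_tufts=400, n_sessions=3, n_trials=2, seed=2)
        _, g_cond = tp.simulate_cohort(tp.SimConfig(arm="conditioned", **kw))
        _, g_exp = tp.simulate_cohort(tp.SimConfig(arm="exposure", **kw))
        assert np.abs(g_cond.si[-1]).mean() > np.abs(g_exp.si[-1]).mean() + 0.1

    def test_exposure_si_constant_across_sessions(self):
        _, gt = tp.simulate_cohort(tp.SimConfig(arm="exposure", n_tufts=30,
                                                n_sessions=4, n_trials=2, seed=6))
        assert np.all(gt.si == gt.si[0])

    def test_session_labels(self):
        assert tp.session_labels(5, "conditioned") == [
            "pre", "conditioning_1", "conditioning_2", "last_rewarded", "post"]
        assert tp.session_labels(2, "exposure") == ["exposure_day_1", "exposure_day_2"]


class TestBehaviorGenerator:
    def test_deterministic_policies(self):
        trials = _trials_for_behavior()
        cfg = tp.SimConfig(arm="exposure")  # no within-session extinction
        rng = np.random.default_rng(0)
        licks = tp.simulate_behavior(cfg, trials,
                                     {"p_lick_csp": 1.0, "p_lick_csm": 0.0,
                                      "rewarded": False}, rng)
        beh = tp.session_behavior_summary(trials, licks)
        assert beh.discrimination == 1.0
        licks0 = tp.simulate_behavior(cfg, trials,
                                      {"p_lick_csp": 0.0, "p_lick_csm": 0.0,
                                       "rewarded": False}, np.random.default_rng(0))
        beh0 = tp.session_behavior_summary(trials, licks0)
        assert beh0.p_lick_csp == 0.0 and beh0.p_lick_csm == 0.0

    def test_intermediate_policy_ci_coverage(self):
        # Clopper-Pearson CIs cover the true probabilities in >= 93% of runs
        trials = _trials_for_behavior(n=180)
        cfg = tp.SimConfig(arm="exposure")
        cover_p = cover_m = 0
        n_runs = 1000
        for seed in range(n_runs):
            licks = tp.simulate_behavior(
                cfg, trials, {"p_lick_csp": 0.8, "p_lick_csm": 0.3,
                              "rewarded": False}, np.random.default_rng(seed))
            out = tp.score_trials(trials, licks)
            k_p = int((out == "hit").sum())
            k_m = int((out == "FA").sum())
            n_p = int((trials.stimulus == "CS+").sum())
            n_m = int((trials.stimulus == "CS-").sum())
            _, lo, hi = tp.performance_ci(k_p, n_p)
            cover_p += lo <= 0.8 <= hi
            _, lo, hi = tp.performance_ci(k_m, n_m)
            cover_m += lo <= 0.3 <= hi
        assert cover_p / n_runs >= 0.93
        assert cover_m / n_runs >= 0.93


def _trials_for_behavior(n=40):
    rng = np.random.default_rng(1)
    stim = np.where(rng.random(n) < 0.5, "CS+", "CS-").astype(object)
    return tp.TrialTable(onset_time=5.0 + 10.0 * np.arange(n), stimulus=stim,
                         rewarded=np.zeros(n, dtype=bool))


class TestWhiskingGenerator:
    def test_no_bouts_gives_flat_angle(self):
        cfg = tp.SimConfig(whisk_bout_rate=0.0, whisk_evoked=False,
                           whisk_noise_sd=0.0)
        trials = _trials_for_behavior(5)
        angle, bouts = tp.simulate_whisking(cfg, trials, 60.0,
                                            np.random.default_rng(0))
        assert bouts.shape == (0, 2)
        assert np.ptp(angle) == 0.0

    def test_evoked_bouts_within_200ms_of_stimuli(self):
        cfg = tp.SimConfig(whisk_bout_rate=0.0, whisk_noise_sd=0.0)
        trials = _trials_for_behavior(10)
        _, bouts = tp.simulate_whisking(cfg, trials, 120.0,
                                        np.random.default_rng(0))
        assert bouts.shape[0] == 10
        lat = bouts[:, 0] - trials.onset_time
        assert np.all((lat >= 0.0) & (lat <= 0.2))

    def test_single_bout_peak_to_peak_amplitude(self):
        # 1 s bout of carrier amplitude A -> extracted amplitude ~ 2A inside
        cfg = tp.SimConfig(whisk_bout_rate=0.0, whisk_evoked=False,
                           whisk_noise_sd=0.0)
        fs = 125.0
        t = np.arange(int(30 * fs)) / fs
        env = np.zeros(t.size)
        env[int(10 * fs):int(11 * fs)] = 1.0
        A = 7.0
        angle = 90 + A * env * np.sin(2 * np.pi * 10 * t)
        ws = tp.whisking_amplitude(angle, fs=fs)
        mid = ws.amplitude[int(10.4 * fs):int(10.6 * fs)]
        assert np.all(np.abs(mid - 2 * A) < 0.1 * A)
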