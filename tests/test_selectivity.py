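"""Selectivity index, d-prime, tuft classification and population summaries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tuftpipe as tp

from conftest import kernel_trace, make_trials

pos = st.floats(0.0, 2.0, allow_nan=False)


class TestComputeSI:
    @pytest.mark.parametrize("fp,fm,expected", [
        (0.2, 0.0, 1.0),      # exclusively CS+ responsive
        (0.0, 0.2, -1.0),     # exclusively CS- responsive
        (0.1, 0.1, 0.0),
        (0.3, 0.1, 0.5),
    ])
    def test_values(self, fp, fm, expected):
        assert tp.compute_si(fp, fm) == pytest.approx(expected)

    def test_both_nonpositive_undefined(self):
        assert np.isnan(tp.compute_si(-0.05, 0.0))
        assert np.isnan(tp.compute_si(0.0, -1.0))

    def test_negative_input_clipped(self):
        assert tp.compute_si(0.2, -0.3) == 1.0

    @given(pos, pos)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_and_range(self, a, b):
        si = tp.compute_si(a, b)
        if np.isnan(si):
            assert np.isnan(tp.compute_si(b, a))
        else:
            assert si == pytest.approx(-tp.compute_si(b, a))
            assert -1.0 <= si <= 1.0


class TestComputeDprime:
    def test_equal_means_zero(self):
        assert tp.compute_dprime(0.2, 0.2, 0.05, 0.01) == 0.0

    def test_direct_arithmetic(self):
        assert tp.compute_dprime(0.3, 0.1, 0.02, 0.02) == pytest.approx(
            0.2 / np.sqrt(0.02))

    def test_zero_variance_unequal_means_infinite(self):
        assert np.isinf(tp.compute_dprime(0.3, 0.1, 0.0, 0.0))
        assert tp.compute_dprime(0.1, 0.1, 0.0, 0.0) == 0.0

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(-0.3, 0.3),
           st.floats(0.5, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shift_invariance_and_scale(self, v1, v2, shift, c):
        d0 = tp.compute_dprime(0.4, 0.1, v1, v2)
        assert tp.compute_dprime(0.4 + shift, 0.1 + shift, v1, v2) == pytest.approx(d0)
        # multiplying both SDs by c scales d' by 1/c (means fixed)
        assert tp.compute_dprime(0.4, 0.1, v1 * c * c, v2 * c * c) == pytest.approx(d0 / c)

    def test_matches_analytic_dprime_at_2000_trials(self):
        # sampled d' vs the closed-form d' of the generating distributions
        cfg = tp.SimConfig(n_tufts=1, n_sessions=1, n_trials=2000, seed=7,
                           frac_unresponsive=0.0, spont_rate_per_min=0.0,
                           si_sd_pre=0.5)
        sessions, gt = tp.simulate_cohort(cfg)
        s = sessions[0]
        rs = tp.trial_amplitudes(s.tufts[0], s.trials)
        d_est = tp.compute_dprime(rs.mean_amp["CS+"], rs.mean_amp["CS-"],
                                  rs.var_amp["CS+"], rs.var_amp["CS-"])
        g = tp.calcium_kernel(np.arange(45) / 30.0).mean()
        mu_a, sd_a = 0.28 * g, cfg.event_amplitude_sd * g
        var_w = cfg.noise_sd ** 2 * (1 / 45 + 1 / 30)
        p_p, p_m = gt.p_success[0, 0]

        def moments(p):
            return p * mu_a, p * sd_a ** 2 + p * (1 - p) * mu_a ** 2 + var_w

        (m1, v1), (m2, v2) = moments(p_p), moments(p_m)
        d_true = abs(m1 - m2) / np.sqrt((v1 + v2) / 2)
        assert d_est == pytest.approx(d_true, abs=0.15)


class TestResponsivenessClassification:
    def test_flat_noise_unresponsive(self):
        trials = make_trials(n=40, seed=2)
        rng = np.random.default_rng(0)
        trace = tp.TuftTrace("n", rng.normal(0, 0.05, 14000), 30.0)
        assert tp.classify_responsiveness(trace, trials)["responsiveness"] == "unresponsive"

    def test_significant_but_tiny_response_gated(self):
        # real response of 0.03 dF/F: significant rank-sum but below the
        # 0.04 amplitude criterion -> unresponsive
        trials = make_trials(n=60, seed=3)
        dff = kernel_trace(trials.onset_time,
                           np.full(trials.n_trials, 0.03 / 0.3492), 20000)
        res = tp.classify_responsiveness(tp.TuftTrace("t", dff, 30.0), trials)
        assert min(res["p"].values()) < 0.05
        assert res["responsiveness"] == "unresponsive"

    def test_strong_response_power(self):
        # amplitude 0.28, success probability 0.8: responsive in >=99% seeds
        hits = 0
        for seed in range(30):
            cfg = tp.SimConfig(n_tufts=1, n_sessions=1, n_trials=180,
                               seed=500 + seed, frac_unresponsive=0.0,
                               si_sd_pre=1e-9, p_pref_range=(0.8, 0.8))
            sessions, _ = tp.simulate_cohort(cfg)
            res = tp.classify_responsiveness(sessions[0].tufts[0], sessions[0].trials)
            hits += res["responsiveness"] == "responsive"
        assert hits == 30

    def test_too_few_trials_unclassifiable(self):
        trials = make_trials(n=12, seed=1)  # < 10 per stimulus
        trace = tp.TuftTrace("f", np.zeros(5000), 30.0)
        assert tp.classify_responsiveness(trace, trials)["responsiveness"] == "unclassifiable"


class TestSelectivityClassification:
    def test_single_stimulus_responder_forced_si(self):
        cls, highly, _ = tp.classify_selectivity(True, False,
                                                 np.ones(20), np.zeros(20))
        assert cls == "selective" and highly
        # sign follows the responsive stimulus in the full record path
        trials = make_trials(n=80, seed=5)
        plus = trials.onsets("CS+")
        dff = kernel_trace(plus, np.full(plus.size, 0.28), 35000)
        rec = tp.make_selectivity_record(tp.TuftTrace("p", dff, 30.0), trials)
        assert rec.highly_selective and rec.si == 1.0
        minus = trials.onsets("CS-")
        dff = kernel_trace(minus, np.full(minus.size, 0.28), 35000)
        rec = tp.make_selectivity_record(tp.TuftTrace("m", dff, 30.0), trials)
        assert rec.highly_selective and rec.si == -1.0

    def test_identical_distributions_unselective(self):
        cls, highly, p = tp.classify_selectivity(
            True, True, np.full(30, 0.2), np.full(30, 0.2))
        assert cls == "unselective" and not highly

    def test_dual_responsive_amplitude_difference_power(self):
        # F+=0.3 vs F-=0.15, per-trial SD 0.1, 90 trials each
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            cls, _, _ = tp.classify_selectivity(
                True, True, rng.normal(0.3, 0.1, 90), rng.normal(0.15, 0.1, 90))
            wins += cls == "selective"
        assert wins / 40 >= 0.95


class TestPopulationSummary:
    def test_all_zero_si(self):
        recs = [_rec(f"t{i}", 0.0) for i in range(25)]
        s = tp.population_selectivity_summary(recs)
        assert s["median_abs_si"] == 0.0 and not s["warning"]

    def test_uniform_sample_closer_to_uniform_than_normal(self):
        wins = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            recs = [_rec(f"t{i}", v) for i, v in enumerate(rng.uniform(-1, 1, 400))]
            s = tp.population_selectivity_summary(recs)
            wins += s["ks_uniform"] < s["ks_normal"]
        assert wins / 200 >= 0.95

    def test_forced_si_counted_once(self):
        recs = [_rec("a", 1.0, highly=True), _rec("b", 0.5)]
        s = tp.population_selectivity_summary(recs, min_tufts=1)
        assert s["n"] == 2 and s["hist"].sum() == 2

    def test_conditioned_cohort_median_abs_si_increases(self):
        cfg = tp.SimConfig(n_tufts=80, n_sessions=3, n_trials=120, seed=21)
        sessions, _ = tp.simulate_cohort(cfg)
        med = []
        for s in sessions[::2]:  # pre and post
            recs = tp.analyze_session(s)
            med.append(tp.population_selectivity_summary(recs)["median_abs_si"])
        assert med[1] > med[0]


def _rec(tid, si, highly=False):
    return tp.SelectivityRecord(
        tuft_id=tid, si=si, abs_si=abs(si), dprime=1.0,
        responsiveness="responsive", selectivity_class="selective",
        highly_selective=highly, responsive_plus=True, responsive_minus=not highly,
        p_resp={}, p_amp_diff=0.01, mean_amp={}, si_defined=True)


class TestSelectivityVsPerformance:
    def test_comonotonic_positive(self):
        r, _ = tp.selectivity_vs_performance([0.2, 0.3, 0.5, 0.6], [0.1, 0.4, 0.6, 0.9])
        assert r > 0

    def test_constant_input_undefined(self):
        r, p = tp.selectivity_vs_performance([0.4, 0.4, 0.4], [0.1, 0.5, 0.9])
        assert np.isnan(r) and np.isnan(p)

    def test_coupled_learning_and_selectivity_drift(self):
        # conditioned cohorts: per-session median |SI| tracks discrimination
        # over pre + rewarded sessions. The unrewarded post session is
        # excluded on purpose: behavior extinguishes there while selectivity
        # persists, so it carries no learning-performance coupling.
        rs = []
        for seed in range(10):
            cfg = tp.SimConfig(n_tufts=40, n_sessions=5, n_trials=120,
                               seed=700 + seed, frac_unresponsive=0.4)
            sessions, _ = tp.simulate_cohort(cfg)
            med, disc = [], []
            for s in sessions[:4]:
                recs = tp.analyze_session(s)
                med.append(tp.population_selectivity_summary(recs)["median_abs_si"])
                disc.append(tp.session_behavior_summary(s.trials, s.licks).discrimination)
            r, _ = tp.selectivity_vs_performance(med, disc)
            rs.append(r)
        assert np.mean(rs) > 0.5
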