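import numpy as np
import pytest

import tuftpipe as tp


@pytest.fixture(scope="session")
def small_cohort():
    """3-session conditioned cohort, 12 tufts, shared across read-only tests."""
    cfg = tp.SimConfig(n_tufts=12, n_sessions=3, n_trials=80, seed=11,
                       frac_unresponsive=0.5)
    sessions, gt = tp.simulate_cohort(cfg)
    return cfg, sessions, gt


def make_trials(n=40, iti=10.0, start=5.0, p_plus=0.5, seed=0):
    rng = np.random.default_rng(seed)
    onsets = start + iti * np.arange(n)
    stim = np.where(rng.random(n) < p_plus, "CS+", "CS-").astype(object)
    return tp.TrialTable(onset_time=onsets, stimulus=stim,
                         rewarded=np.zeros(n, dtype=bool))


def kernel_trace(onsets, amps, n_frames, fs=30.0, rise=0.05, decay=0.4):
    """Independent superposition oracle: explicit per-event kernel sums."""
    t = np.arange(n_frames) / fs
    dff = np.zeros(n_frames)
    for o, a in zip(onsets, amps):
        m = t >= o
        dff[m] += a * tp.calcium_kernel(t[m] - o, rise, decay)
    return dff
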