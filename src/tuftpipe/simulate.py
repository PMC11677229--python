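"""Synthetic multi-session cohorts with known ground truth.

The generator emulates the structure of a head-fixed whisker-direction
discrimination experiment: ~180 air-puff trials per 30-min session at 8–12 s
inter-trial intervals with 50% CS+ probability, GCaMP6f-like calcium
transients (unit-peak double-exponential kernel, successes near 28% ΔF/F),
spontaneous tuft-wide events at a few per minute, bout-structured whisking
at 125 Hz, and lick behavior that follows a saturating learning curve on
CS+ trials while CS− licking decays.

Selectivity is imposed at the level of evoked success probabilities: for a
tuft with true selectivity index ``si`` the preferred stimulus succeeds with
probability ``p_pref`` and the other with ``p_pref·(1−|si|)/(1+|si|)``, so
the SI formula on mean amplitudes reproduces ``si`` exactly in expectation.
In the conditioned arm the per-tuft SI drifts linearly from a truncated
Normal draw (pre) to a uniform[−1,1] draw (post); in the repeated-exposure
arm it stays at its initial draw. Ground truth for every source of
variability is returned alongside the sessions.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows

from .datamodel import ConfigError, SessionData, TrialTable, TuftTrace

ARMS = ("conditioned", "exposure")


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort (one arm)."""

    n_tufts: int = 60
    n_sessions: int = 5
    arm: str = "conditioned"
    seed: int = 0
    # acquisition
    frames_per_second: float = 30.0
    whisker_fps: float = 125.0
    # trial structure
    n_trials: int = 180
    iti_range_s: tuple[float, float] = (8.0, 12.0)
    p_cs_plus: float = 0.5
    session_start_s: float = 5.0
    session_tail_s: float = 10.0
    # calcium dynamics
    event_amplitude_mean: float = 0.28
    event_amplitude_sd: float = 0.05
    spont_rate_per_min: float = 3.0
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.4
    noise_sd: float = 0.05
    # selectivity structure
    si_sd_pre: float = 0.35
    frac_unresponsive: float = 0.75
    p_gain_response: float = 0.4            # conditioned arm
    p_gain_response_exposure: float = 0.15  # keeps exposure-arm signal stationary
    p_lose_response: float = 0.15
    p_pref_range: tuple[float, float] = (0.6, 0.9)
    # optional movement coupling of the calcium signal (ΔF/F per unit)
    whisk_coupling: float = 0.0
    lick_coupling: float = 0.0
    # behavior
    lick_learning_rate: float = 1.2
    lick_p0: float = 0.05
    lick_p_max: float = 0.95
    lick_fa0: float = 0.4
    extinction_tau_trials: float = 30.0
    response_window_s: float = 0.5
    reward_delay_s: float = 0.5
    # whisking
    whisk_bout_rate: float = 6.0
    whisk_carrier_hz: float = 10.0
    whisk_bout_amp_range: tuple[float, float] = (5.0, 15.0)
    whisk_bout_dur_range: tuple[float, float] = (0.5, 2.0)
    whisk_evoked_dur_s: float = 1.5
    whisk_evoked: bool = True  # False decouples whisking from the stimuli
    whisk_setpoint_deg: float = 95.0
    whisk_noise_sd: float = 0.3

    def validate(self) -> None:
        def _pos(name):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be finite and > 0, got {v}")

        def _prob(name):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")

        if self.arm not in ARMS:
            raise ConfigError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.n_tufts < 1 or self.n_sessions < 1 or self.n_trials < 1:
            raise ConfigError("n_tufts, n_sessions and n_trials must be >= 1")
        for name in ("frames_per_second", "whisker_fps", "kernel_rise_s",
                     "kernel_decay_s", "whisk_carrier_hz", "si_sd_pre",
                     "extinction_tau_trials", "lick_learning_rate"):
            _pos(name)
        for name in ("p_cs_plus", "frac_unresponsive", "p_gain_response",
                     "p_gain_response_exposure", "p_lose_response",
                     "lick_p0", "lick_p_max", "lick_fa0"):
            _prob(name)
        for name in ("noise_sd", "spont_rate_per_min", "event_amplitude_sd",
                     "whisk_coupling", "lick_coupling", "whisk_bout_rate",
                     "whisk_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.event_amplitude_mean):
            raise ConfigError("event_amplitude_mean must be finite")
        lo, hi = self.iti_range_s
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ConfigError("iti_range_s must satisfy 0 < lo < hi")
        plo, phi = self.p_pref_range
        if not (0 < plo <= phi <= 1):
            raise ConfigError("p_pref_range must satisfy 0 < lo <= hi <= 1")
        if not self.kernel_rise_s < self.kernel_decay_s:
            raise ConfigError("kernel_rise_s must be < kernel_decay_s")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator drew, for downstream recovery checks."""

    config: SimConfig
    session_labels: list[str]
    si: np.ndarray                 # (n_sessions, n_tufts) true selectivity
    responsive: np.ndarray         # (n_sessions, n_tufts) bool
    p_success: np.ndarray          # (n_sessions, n_tufts, 2) for (CS+, CS−)
    evoked_amplitude_mean: float
    evoked_success: list           # [session][tuft] -> bool array over that tuft's trials
    spont_event_times: list        # [session][tuft] -> event time array (s)
    whisk_bouts: list              # [session] -> (n, 2) array of bout intervals (s)
    lick_policy: list              # [session] -> dict(p_lick_csp, p_lick_csm, rewarded)

    def si_by_label(self, label: str) -> np.ndarray:
        return self.si[self.session_labels.index(label)]


def session_labels(n_sessions: int, arm: str) -> list[str]:
    """Labels mirroring the experimental timeline of each arm."""
    if arm == "exposure":
        return [f"exposure_day_{k + 1}" for k in range(n_sessions)]
    if n_sessions == 1:
        return ["pre"]
    if n_sessions == 2:
        return ["pre", "post"]
    mid = [f"conditioning_{k + 1}" for k in range(n_sessions - 3)]
    return ["pre", *mid, "last_rewarded", "post"]


def calcium_kernel(t, rise_s: float = 0.05, decay_s: float = 0.4) -> np.ndarray:
    """Unit-peak double-exponential calcium impulse response.

    ``k(t) = (exp(−t/decay) − exp(−t/rise)) / peak`` for ``t ≥ 0``; the peak
    normalization makes the event-amplitude parameter the peak ΔF/F of a
    single transient.
    """
    if not 0 < rise_s < decay_s:
        raise ConfigError("require 0 < rise_s < decay_s")
    t = np.asarray(t, dtype=float)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    out = np.where(t >= 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    return out / peak


def _render_trace(n_frames: int, fs: float, event_times: np.ndarray,
                  event_amps: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Superpose kernel-shaped transients on a zero baseline (linear, no saturation)."""
    dff = np.zeros(n_frames)
    # truncate each transient where exp(−t/decay) drops below ~1e-16
    n_kernel = int(np.ceil(decay_s * 37.0 * fs)) + 1
    frame_t = np.arange(n_kernel) / fs
    for te, amp in zip(event_times, event_amps):
        i0 = int(np.ceil(te * fs - 1e-9))
        if i0 >= n_frames:
            continue
        seg = min(n_kernel, n_frames - i0)
        dt = np.arange(i0, i0 + seg) / fs - te
        dff[i0:i0 + seg] += amp * calcium_kernel(dt, rise_s, decay_s)
    return dff


def simulate_trials(config: SimConfig, rng: np.random.Generator,
                    rewarded_session: bool) -> TrialTable:
    itis = rng.uniform(*config.iti_range_s, size=config.n_trials)
    onsets = config.session_start_s + np.cumsum(itis) - itis[0]
    stim = np.where(rng.random(config.n_trials) < config.p_cs_plus, "CS+", "CS-")
    rewarded = (stim == "CS+") & rewarded_session
    return TrialTable(onset_time=onsets, stimulus=stim.astype(object), rewarded=rewarded)


def lick_policy(config: SimConfig, session_index: int, label: str) -> dict:
    """Session-level lick probabilities: saturating CS+ learning, decaying CS−."""
    p0, pmax, r = config.lick_p0, config.lick_p_max, config.lick_learning_rate
    if config.arm == "exposure" or label == "pre":
        return {"p_lick_csp": p0, "p_lick_csm": p0, "rewarded": False}
    k = session_index  # 0 = pre
    p_plus = p0 + (pmax - p0) * (1.0 - np.exp(-r * k))
    p_minus = p0 + config.lick_fa0 * np.exp(-r * (k - 1))
    return {"p_lick_csp": float(p_plus), "p_lick_csm": float(min(p_minus, 1.0)),
            "rewarded": label != "post"}


def simulate_behavior(config: SimConfig, trials: TrialTable, policy: dict,
                      rng: np.random.Generator) -> np.ndarray:
    """Lick event times for one session under a session-level lick policy.

    Anticipatory licks land inside the response window (0.08–0.5 s after
    onset); rewarded trials add a consumption bout after reward delivery.
    In the unrewarded post session the CS+ lick probability extinguishes
    exponentially over CS+ trials.
    """
    licks: list[float] = []
    extinguishing = (config.arm == "conditioned" and not policy["rewarded"]
                     and policy["p_lick_csp"] > 2 * config.lick_p0)
    i_csp = 0
    for onset, stim, rewarded in zip(trials.onset_time, trials.stimulus, trials.rewarded):
        p = policy["p_lick_csp"] if stim == "CS+" else policy["p_lick_csm"]
        if stim == "CS+" and extinguishing:
            p = p * np.exp(-i_csp / config.extinction_tau_trials)
            i_csp += 1
        if rng.random() < p:
            n = rng.integers(2, 5)
            licks.extend(onset + np.sort(rng.uniform(0.08, config.response_window_s, n)))
        if rewarded:
            n = rng.integers(5, 9)
            t0 = onset + config.reward_delay_s
            licks.extend(t0 + np.sort(rng.uniform(0.1, 1.5, n)))
    return np.sort(np.asarray(licks, dtype=float))


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return np.zeros((0, 2))
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)


def simulate_whisking(config: SimConfig, trials: TrialTable, duration_s: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Median whisker angle at 125 Hz plus ground-truth bout intervals.

    The angle is a setpoint plus bout-gated carrier oscillation (default
    10 Hz, inside the 4–30 Hz whisking band) with tapered envelopes, plus
    small Gaussian jitter. Each stimulus evokes a bout starting within
    200 ms of onset; spontaneous bouts arrive as a Poisson process.
    """
    fs = config.whisker_fps
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    envelope = np.zeros(n)
    bouts = []

    def add_bout(start: float, dur: float, amp: float) -> None:
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 - i0 < 2:
            return
        taper = windows.tukey(i1 - i0, alpha=min(1.0, 0.2 / max(dur, 1e-6)))
        envelope[i0:i1] = np.maximum(envelope[i0:i1], amp * taper)
        bouts.append([i0 / fs, i1 / fs])

    n_spont = rng.poisson(config.whisk_bout_rate * duration_s / 60.0)
    for _ in range(n_spont):
        add_bout(rng.uniform(0, duration_s),
                 rng.uniform(*config.whisk_bout_dur_range),
                 rng.uniform(*config.whisk_bout_amp_range))
    if config.whisk_evoked:
        for onset in trials.onset_time:
            add_bout(onset + rng.uniform(0.05, 0.15), config.whisk_evoked_dur_s,
                     rng.uniform(*config.whisk_bout_amp_range))

    angle = (config.whisk_setpoint_deg
             + envelope * np.sin(2 * np.pi * config.whisk_carrier_hz * t)
             + rng.normal(0.0, config.whisk_noise_sd, n))
    return angle, _merge_intervals(np.asarray(bouts).reshape(-1, 2))


def _si_trajectory(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """True per-tuft SI per session: Normal→uniform drift when conditioned."""
    n_s, n_t = config.n_sessions, config.n_tufts
    si_pre = np.clip(rng.normal(0.0, config.si_sd_pre, n_t), -1.0, 1.0)
    if config.arm != "conditioned":
        return np.tile(si_pre, (n_s, 1))
    si_post = rng.uniform(-1.0, 1.0, n_t)
    if n_s == 1:
        return si_pre[None, :]
    w = np.linspace(0.0, 1.0, n_s)[:, None]
    return (1.0 - w) * si_pre[None, :] + w * si_post[None, :]


def _responsiveness_trajectory(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Bool (n_sessions, n_tufts): who has evoked responses in each session."""
    n_s, n_t = config.n_sessions, config.n_tufts
    resp0 = rng.random(n_t) >= config.frac_unresponsive
    resp = np.tile(resp0, (n_s, 1))
    if n_s == 1:
        return resp
    p_gain = (config.p_gain_response if config.arm == "conditioned"
              else config.p_gain_response_exposure)
    gain = (~resp0) & (rng.random(n_t) < p_gain)
    lose = resp0 & (rng.random(n_t) < config.p_lose_response)
    for j in np.flatnonzero(gain):
        resp[rng.integers(1, n_s):, j] = True
    for j in np.flatnonzero(lose):
        resp[rng.integers(1, n_s):, j] = False
    return resp


def simulate_cohort(config: SimConfig) -> tuple[list[SessionData], GroundTruth]:
    """Generate one arm of a cohort: sessions plus full ground truth.

    Identical ``SimConfig`` (including ``seed``) gives bit-identical output;
    per-session and per-tuft random substreams are derived deterministically
    from the master seed.
    """
    config.validate()
    labels = session_labels(config.n_sessions, config.arm)
    master = np.random.SeedSequence(config.seed)
    session_seeds = master.spawn(config.n_sessions)

    struct_rng = np.random.default_rng(master.spawn(1)[0])
    si = _si_trajectory(config, struct_rng)
    responsive = _responsiveness_trajectory(config, struct_rng)
    p_pref = struct_rng.uniform(*config.p_pref_range, config.n_tufts)

    # success probabilities per stimulus from true SI: preferred stimulus at
    # p_pref, the other scaled so (p+ − p−)/(p+ + p−) equals the true SI
    p_success = np.zeros((config.n_sessions, config.n_tufts, 2))
    for s in range(config.n_sessions):
        a = np.abs(si[s])
        p_hi = p_pref
        p_lo = p_pref * (1.0 - a) / (1.0 + a)
        plus_pref = si[s] >= 0
        p_success[s, :, 0] = np.where(plus_pref, p_hi, p_lo)
        p_success[s, :, 1] = np.where(plus_pref, p_lo, p_hi)
        p_success[s, ~responsive[s], :] = 0.0

    fs = config.frames_per_second
    sessions: list[SessionData] = []
    evoked_success_all, spont_all, whisk_all, policy_all = [], [], [], []

    for s, label in enumerate(labels):
        seeds = session_seeds[s].spawn(3 + config.n_tufts)
        rng_tr, rng_beh, rng_wh = (np.random.default_rng(x) for x in seeds[:3])
        policy = lick_policy(config, s, label)
        trials = simulate_trials(config, rng_tr, rewarded_session=policy["rewarded"])
        duration = trials.onset_time[-1] + config.session_tail_s
        n_frames = int(round(duration * fs))
        duration = n_frames / fs

        angle, bouts = simulate_whisking(config, trials, duration, rng_wh)
        licks = simulate_behavior(config, trials, policy, rng_beh)
        licks = licks[licks <= duration]

        whisk_drive = None
        if config.whisk_coupling > 0:
            # amplitude envelope resampled onto the frame grid
            wt = np.arange(angle.size) / config.whisker_fps
            env = np.zeros(angle.size)
            for b0, b1 in bouts:
                j0, j1 = int(b0 * config.whisker_fps), int(b1 * config.whisker_fps)
                env[j0:j1] = 1.0
            whisk_drive = np.interp(np.arange(n_frames) / fs, wt, env)
        lick_drive = None
        if config.lick_coupling > 0:
            lick_drive = np.zeros(n_frames)
            idx = np.floor(licks * fs).astype(int)
            lick_drive[idx[idx < n_frames]] = 1.0

        tufts, ev_succ, spont = [], [], []
        is_plus = trials.stimulus == "CS+"
        for j in range(config.n_tufts):
            rng_t = np.random.default_rng(seeds[3 + j])
            p_trial = np.where(is_plus, p_success[s, j, 0], p_success[s, j, 1])
            success = rng_t.random(trials.n_trials) < p_trial
            n_spont = rng_t.poisson(config.spont_rate_per_min * duration / 60.0)
            spont_times = np.sort(rng_t.uniform(0.0, duration, n_spont))
            ev_times = np.concatenate([trials.onset_time[success], spont_times])
            amps = rng_t.normal(config.event_amplitude_mean,
                                config.event_amplitude_sd, ev_times.size)
            amps = np.clip(amps, 0.0, None)
            order = np.argsort(ev_times)
            dff = _render_trace(n_frames, fs, ev_times[order], amps[order],
                                config.kernel_rise_s, config.kernel_decay_s)
            if config.noise_sd > 0:
                dff = dff + rng_t.normal(0.0, config.noise_sd, n_frames)
            if whisk_drive is not None:
                dff = dff + config.whisk_coupling * whisk_drive
            if lick_drive is not None:
                dff = dff + config.lick_coupling * lick_drive
            tufts.append(TuftTrace(tuft_id=f"tuft_{j:04d}", dff=dff, fs=fs))
            ev_succ.append(success)
            spont.append(spont_times)

        sessions.append(SessionData(session_label=label, tufts=tufts, trials=trials,
                                    licks=licks, whisker_angle=angle,
                                    whisker_fps=config.whisker_fps))
        evoked_success_all.append(ev_succ)
        spont_all.append(spont)
        whisk_all.append(bouts)
        policy_all.append(policy)

    gt = GroundTruth(config=config, session_labels=labels, si=si,
                     responsive=responsive, p_success=p_success,
                     evoked_amplitude_mean=config.event_amplitude_mean,
                     evoked_success=evoked_success_all, spont_event_times=spont_all,
                     whisk_bouts=whisk_all, lick_policy=policy_all)
    return sessions, gt
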