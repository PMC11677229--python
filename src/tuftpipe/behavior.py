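"""Lick-based trial scoring, performance estimates and choice modulation.

A trial response is one or more licks inside the 0.5 s response window
after stimulus onset (window open at the onset, closed at the right edge).
CS+ trials with/without a response are hits/misses; CS− trials are false
alarms/correct rejections. Session performance per stimulus carries exact
binomial (Clopper–Pearson) 95% confidence intervals, and discrimination is
``P(lick | CS+) − P(lick | CS−)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import STIMULI, SessionData, TrialTable, TuftTrace
from .response import aligned_window_means
from .selectivity import _ranksum_p


def score_trials(trials: TrialTable, licks: np.ndarray,
                 response_window_s: float = 0.5) -> np.ndarray:
    """Outcome per trial: hit/miss for CS+, FA/CR for CS−.

    The response window is ``(onset, onset + response_window_s]`` — a lick
    exactly at onset does not count, one exactly at the right edge does.
    """
    licks = np.sort(np.asarray(licks, dtype=float))
    outcomes = np.empty(trials.n_trials, dtype=object)
    for i, (onset, stim) in enumerate(zip(trials.onset_time, trials.stimulus)):
        lo = np.searchsorted(licks, onset, side="right")
        hi = np.searchsorted(licks, onset + response_window_s, side="right")
        responded = hi > lo
        if stim == "CS+":
            outcomes[i] = "hit" if responded else "miss"
        else:
            outcomes[i] = "FA" if responded else "CR"
    trials.outcome = outcomes
    return outcomes


def performance_ci(k: int, n: int, confidence: float = 0.95):
    """Response-probability estimate with exact Clopper–Pearson interval."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return k / n, float(ci.low), float(ci.high)


@dataclass
class BehaviorSummary:
    p_lick_csp: float
    p_lick_csm: float
    ci_csp: tuple[float, float]
    ci_csm: tuple[float, float]
    discrimination: float
    n_trials: dict
    outcomes: np.ndarray


def session_behavior_summary(trials: TrialTable, licks: np.ndarray,
                             response_window_s: float = 0.5) -> BehaviorSummary:
    outcomes = score_trials(trials, licks, response_window_s)
    n_p = int((trials.stimulus == "CS+").sum())
    n_m = int((trials.stimulus == "CS-").sum())
    k_p = int((outcomes == "hit").sum())
    k_m = int((outcomes == "FA").sum())
    p_p, lo_p, hi_p = performance_ci(k_p, max(n_p, 1))
    p_m, lo_m, hi_m = performance_ci(k_m, max(n_m, 1))
    return BehaviorSummary(p_lick_csp=p_p, p_lick_csm=p_m,
                           ci_csp=(lo_p, hi_p), ci_csm=(lo_m, hi_m),
                           discrimination=p_p - p_m,
                           n_trials={"CS+": n_p, "CS-": n_m}, outcomes=outcomes)


def classify_behavioral_modulation(trace: TuftTrace, trials: TrialTable,
                                   outcomes: np.ndarray | None = None,
                                   alpha: float = 0.05, window_s: float = 1.5,
                                   min_fa_trials: int = 12):
    """Choice modulation on CS− trials: rank-sum of post-stimulus window
    means on false-alarm vs correct-rejection trials. Sessions with fewer
    than 12 FA trials are unclassifiable.
    """
    if outcomes is None:
        outcomes = trials.outcome
    if outcomes is None:
        raise ValueError("trials must be scored first (no outcomes)")
    fa_onsets = trials.onset_time[outcomes == "FA"]
    cr_onsets = trials.onset_time[outcomes == "CR"]
    if fa_onsets.size < min_fa_trials or cr_onsets.size == 0:
        return "unclassifiable", float("nan")
    _, fa_means, _ = aligned_window_means(trace, fa_onsets, 0.0, window_s)
    _, cr_means, _ = aligned_window_means(trace, cr_onsets, 0.0, window_s)
    p = _ranksum_p(fa_means, cr_means)
    return ("modulated" if p < alpha else "not_modulated"), p


def extinction_blocks(trials: TrialTable, licks: np.ndarray,
                      block_size: int = 20, response_window_s: float = 0.5):
    """CS+ response probability per consecutive block of CS+ trials.

    Returns ``(block_probs, warning)``; ``warning`` is True with fewer than
    two full blocks. Trailing partial blocks are dropped.
    """
    outcomes = score_trials(trials, licks, response_window_s)
    csp = outcomes[trials.stimulus == "CS+"]
    n_blocks = csp.size // block_size
    probs = np.array([
        (csp[b * block_size:(b + 1) * block_size] == "hit").mean()
        for b in range(n_blocks)
    ])
    return probs, n_blocks < 2
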