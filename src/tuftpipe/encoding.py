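"""Per-tuft linear encoding models and population stimulus decoding.

Encoding: the calcium time series is excerpted 2 s before to 6 s after each
stimulus onset and concatenated. Predictors on the same frame grid are a
binary stimulus vector with an 800 ms 'on' period (24 frames at 30 Hz)
centered at onset and shifted by the tuft's response-peak latency, the
normalized whisking amplitude resampled to the frame rate and shifted by
the calcium–whisking cross-correlation peak lag (searched within ±1 s),
and a binary lick-bout vector (a bout is ≥2 licks with gaps ≤200 ms).
Models are ordinary least squares with an intercept.

Decoding: per-trial, per-tuft mean ΔF/F in a pre-stimulus epoch (the 1 s
before onset, a negative control) and a post-stimulus epoch (0.1–1.1 s
after onset) feed linear-kernel SVMs; accuracy is averaged over 10 random
stratified 75/25 train/test splits.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .datamodel import SessionData, TrialTable, TuftTrace
from .response import window_frames
from .whisker import WhiskSignal


@dataclass
class DesignMatrix:
    y: np.ndarray
    predictors: dict            # name -> column vector (same length as y)
    whisk_lag_frames: int
    stim_latency_frames: int
    n_dropped: int


@dataclass
class EncodingFit:
    r2: float
    coef: float
    intercept: float
    degenerate: bool = False


@dataclass
class DecodeResult:
    accuracy_pre: float
    accuracy_post: float
    n_iterations: int = 10


def lick_bouts(licks: np.ndarray, min_licks: int = 2,
               max_gap_s: float = 0.2) -> np.ndarray:
    """(n, 2) array of lick-bout intervals; single licks form no bout."""
    licks = np.sort(np.asarray(licks, dtype=float))
    if licks.size == 0:
        return np.zeros((0, 2))
    splits = np.flatnonzero(np.diff(licks) > max_gap_s) + 1
    bouts = []
    for grp in np.split(licks, splits):
        if grp.size >= min_licks:
            bouts.append([grp[0], grp[-1]])
    return np.asarray(bouts).reshape(-1, 2)


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift right (delay) by ``lag`` frames, zero filled; negative advances."""
    out = np.zeros_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
    elif lag < 0:
        out[:lag] = x[-lag:]
    else:
        out[:] = x
    return out


def crosscorr_peak_lag(y: np.ndarray, x: np.ndarray, max_lag: int = 30) -> int:
    """Lag k in [−max_lag, max_lag] maximizing corr(y[t], x[t+k])."""
    y = y - y.mean()
    x = x - x.mean()
    if not (y.std() > 0 and x.std() > 0):
        return 0
    best_lag, best_c = 0, -np.inf
    for k in range(-max_lag, max_lag + 1):
        xk = _shift(x, -k)  # x[t+k]
        c = float(np.dot(y, xk))
        if c > best_c:
            best_c, best_lag = c, k
    return best_lag


def stimulus_peak_latency(trace: TuftTrace, trials: TrialTable,
                          window_s: float = 1.5) -> int:
    """Latency (frames ≥ 0) of the peak of the mean stimulus-aligned ΔF/F
    within the first ``window_s`` after onset, over all trials (both stimuli)."""
    n_post = window_frames(trace.fs, window_s)
    f0 = np.floor(trials.onset_time * trace.fs).astype(int)
    segs = [trace.dff[i:i + n_post] for i in f0 if 0 <= i and i + n_post <= trace.n_frames]
    if not segs:
        return 0
    return int(np.argmax(np.mean(segs, axis=0)))


def build_design(trace: TuftTrace, trials: TrialTable, licks: np.ndarray,
                 whisk: WhiskSignal, pre_s: float = 2.0, post_s: float = 6.0,
                 stim_on_frames: int = 24, max_lag_frames: int = 30) -> DesignMatrix:
    """Response vector and predictor matrix for one tuft."""
    fs = trace.fs
    n = trace.n_frames
    frame_t = np.arange(n) / fs

    # full-session binary stimulus vectors, 'on' period centered at onset
    stim_cols = {"cs_plus": np.zeros(n), "cs_minus": np.zeros(n)}
    half = stim_on_frames // 2
    for onset, stim in zip(trials.onset_time, trials.stimulus):
        i = int(np.floor(onset * fs))
        col = stim_cols["cs_plus"] if stim == "CS+" else stim_cols["cs_minus"]
        col[max(i - half, 0):min(i + stim_on_frames - half, n)] = 1.0

    latency = stimulus_peak_latency(trace, trials)
    for k in stim_cols:
        stim_cols[k] = _shift(stim_cols[k], latency)
    stimulus_any = np.clip(stim_cols["cs_plus"] + stim_cols["cs_minus"], 0, 1)

    whisk_frames = np.interp(frame_t, whisk.times, whisk.amplitude_norm)
    lag = crosscorr_peak_lag(trace.dff, whisk_frames, max_lag=max_lag_frames)
    whisk_aligned = _shift(whisk_frames, -lag)

    lick_col = np.zeros(n)
    for b0, b1 in lick_bouts(licks):
        lick_col[int(np.floor(b0 * fs)):int(np.ceil(b1 * fs)) + 1] = 1.0

    # concatenated per-trial excerpts
    n_pre, n_post = int(round(pre_s * fs)), int(round(post_s * fs))
    rows, n_dropped = [], 0
    for onset in trials.onset_time:
        i = int(np.floor(onset * fs))
        if i - n_pre < 0 or i + n_post > n:
            n_dropped += 1
            continue
        rows.append(np.arange(i - n_pre, i + n_post))
    idx = np.concatenate(rows) if rows else np.zeros(0, dtype=int)

    return DesignMatrix(
        y=trace.dff[idx],
        predictors={
            "cs_plus": stim_cols["cs_plus"][idx],
            "cs_minus": stim_cols["cs_minus"][idx],
            "stimulus": stimulus_any[idx],
            "whisking": whisk_aligned[idx],
            "licking": lick_col[idx],
        },
        whisk_lag_frames=lag,
        stim_latency_frames=latency,
        n_dropped=n_dropped,
    )


def fit_single_predictor(y: np.ndarray, x: np.ndarray) -> EncodingFit:
    """OLS with intercept for one predictor; R² = 0 with a degenerate flag
    when the predictor has zero variance."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.size != x.size or y.size < 100:
        raise ValueError("need equal-length inputs with >= 100 samples")
    if np.ptp(x) == 0:
        return EncodingFit(r2=0.0, coef=0.0, intercept=float(y.mean()), degenerate=True)
    if np.ptp(y) == 0:
        return EncodingFit(r2=0.0, coef=0.0, intercept=float(y.mean()), degenerate=True)
    res = stats.linregress(x, y)
    return EncodingFit(r2=float(res.rvalue ** 2), coef=float(res.slope),
                       intercept=float(res.intercept))


def fit_multivariate(y: np.ndarray, predictors: dict) -> dict:
    """Joint OLS over named predictors (with intercept).

    Rank-deficient columns are dropped greedily and reported under
    ``'dropped'``; returns coefficients by name plus ``'intercept'``.
    """
    y = np.asarray(y, float)
    names = list(predictors)
    cols, kept, dropped = [np.ones(y.size)], [], []
    for name in names:
        c = np.asarray(predictors[name], float)
        trial_X = np.column_stack(cols + [c])
        if np.linalg.matrix_rank(trial_X) > len(cols):
            cols.append(c)
            kept.append(name)
        else:
            dropped.append(name)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = {"intercept": float(beta[0]), "dropped": dropped}
    for name, b in zip(kept, beta[1:]):
        out[name] = float(b)
    for name in dropped:
        out[name] = float("nan")
    return out


def epoch_features(session: SessionData, pre_s: float = 1.0,
                   post_window: tuple[float, float] = (0.1, 1.1)):
    """Per-trial, per-tuft epoch-mean features for decoding.

    Returns ``(X_pre, X_post, labels)`` with shape (n_trials, n_tufts);
    trials too close to the session edge are dropped consistently.
    """
    fs = session.fs
    onsets = session.trials.onset_time
    n_pre = window_frames(fs, pre_s)
    f_lo = np.floor((onsets + post_window[0]) * fs).astype(int)
    n_post = window_frames(fs, post_window[1] - post_window[0])
    f0 = np.floor(onsets * fs).astype(int)
    n = session.tufts[0].n_frames
    keep = (f0 - n_pre >= 0) & (f_lo + n_post <= n)
    X_pre = np.stack([
        [t.dff[i - n_pre:i].mean() for i in f0[keep]] for t in session.tufts
    ], axis=1)
    X_post = np.stack([
        [t.dff[j:j + n_post].mean() for j in f_lo[keep]] for t in session.tufts
    ], axis=1)
    labels = np.asarray(session.trials.stimulus[keep] == "CS+", dtype=int)
    return X_pre, X_post, labels


def decode_stimulus(features_pre: np.ndarray, features_post: np.ndarray,
                    labels: np.ndarray, n_iterations: int = 10, C: float = 1.0,
                    seed: int = 0) -> DecodeResult:
    """Linear-SVM decoding accuracy for the pre- and post-stimulus epochs."""
    labels = np.asarray(labels)
    if labels.size < 40 or features_post.shape[1] < 2:
        raise ValueError("need >= 40 trials and >= 2 tufts")
    if np.unique(labels).size < 2:
        return DecodeResult(accuracy_pre=float("nan"), accuracy_post=float("nan"),
                            n_iterations=n_iterations)
    rng = np.random.default_rng(seed)
    accs = {"pre": [], "post": []}
    for _ in range(n_iterations):
        state = int(rng.integers(0, 2 ** 31 - 1))
        for name, X in (("pre", features_pre), ("post", features_post)):
            Xtr, Xte, ytr, yte = train_test_split(
                X, labels, test_size=0.25, stratify=labels, random_state=state)
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xtr, ytr)
            accs[name].append(clf.score(Xte, yte))
    return DecodeResult(accuracy_pre=float(np.mean(accs["pre"])),
                        accuracy_post=float(np.mean(accs["post"])),
                        n_iterations=n_iterations)


def decode_session(session: SessionData, n_iterations: int = 10, C: float = 1.0,
                   seed: int = 0) -> DecodeResult:
    X_pre, X_post, labels = epoch_features(session)
    return decode_stimulus(X_pre, X_post, labels, n_iterations=n_iterations,
                           C=C, seed=seed)
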