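"""Whisking amplitude, phase, and bout segmentation from the median angle.

The median whisker angle (125 Hz) is zero-phase bandpass filtered in the
4–30 Hz whisking band; the Hilbert transform of the filtered signal gives
the whisk-cycle phase. Envelope anchor points are the *unfiltered* angle
sampled where the phase crosses 0 (most protracted) and ±π (most
retracted); envelopes are linearly interpolated between anchors, and
whisking amplitude is their difference. Amplitude is normalized to the
session maximum (99.9th percentile, to guard single-sample artifacts).
Whisking bouts are runs where normalized amplitude exceeds 20% of maximum
for at least 250 ms; shorter supra-threshold runs are ambiguous and are
excluded from whisking-vs-quiescence contrasts but retained in the output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .datamodel import TrialTable


@dataclass
class WhiskSignal:
    angle: np.ndarray
    fs: float
    filtered: np.ndarray
    phase: np.ndarray
    upper_env: np.ndarray
    lower_env: np.ndarray
    amplitude: np.ndarray
    amplitude_norm: np.ndarray
    amp_max: float           # true maximum of the amplitude series
    amp_norm_ref: float      # normalization reference (99.9th percentile)
    degenerate: bool = False

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.angle.size) / self.fs


@dataclass
class WhiskBout:
    start_s: float
    end_s: float
    classification: str      # 'whisking' | 'ambiguous'

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _interp_at(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Quadratic (3-point) interpolation of samples x at fractional indices.

    Anchors sit at protraction/retraction extremes of the whisk cycle where
    the angle is locally parabolic; linear interpolation would systematically
    undershoot the envelope between samples. Falls back to linear at edges.
    """
    idx = np.asarray(idx, dtype=float)
    out = np.interp(idx, np.arange(x.size), x)
    j = np.clip(np.round(idx).astype(int), 1, x.size - 2)
    g = idx - j
    y0, y1, y2 = x[j - 1], x[j], x[j + 1]
    quad = y1 + 0.5 * g * (y2 - y0) + 0.5 * g * g * (y2 - 2 * y1 + y0)
    inner = (idx >= 1) & (idx <= x.size - 2)
    out[inner] = quad[inner]
    return out


def whisking_amplitude(angle: np.ndarray, fs: float = 125.0,
                       band: tuple[float, float] = (4.0, 30.0),
                       order: int = 4, norm_percentile: float = 99.9) -> WhiskSignal:
    """Extract filtered signal, phase, envelopes and whisking amplitude."""
    angle = np.asarray(angle, dtype=float)
    if angle.size < 2 * fs:
        raise ValueError("need at least 2 s of whisker angle")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, angle)
    phase = np.angle(hilbert(filt))

    d = np.diff(phase)
    # upward 0-crossings of the wrapped phase (excluding the ±π wrap jumps)
    zc = np.flatnonzero((phase[:-1] < 0) & (phase[1:] >= 0) & (np.abs(d) < np.pi))
    zc_idx = zc + (0.0 - phase[zc]) / (phase[zc + 1] - phase[zc])
    # ±π crossings appear as wrap jumps from near +π to near −π
    pc = np.flatnonzero(d < -np.pi)
    pc_idx = pc + (np.pi - phase[pc]) / ((phase[pc + 1] + 2 * np.pi) - phase[pc])

    degenerate = zc_idx.size < 2 or pc_idx.size < 2
    n = angle.size
    if degenerate:
        zeros = np.zeros(n)
        return WhiskSignal(angle=angle, fs=fs, filtered=filt, phase=phase,
                           upper_env=zeros.copy(), lower_env=zeros.copy(),
                           amplitude=zeros.copy(), amplitude_norm=zeros.copy(),
                           amp_max=0.0, amp_norm_ref=0.0, degenerate=True)

    grid = np.arange(n, dtype=float)
    upper = np.interp(grid, zc_idx, _interp_at(angle, zc_idx))
    lower = np.interp(grid, pc_idx, _interp_at(angle, pc_idx))
    amplitude = upper - lower
    # enforce upper >= lower where anchor interpolation crosses
    swap = amplitude < 0
    if swap.any():
        upper2 = np.where(swap, lower, upper)
        lower = np.where(swap, upper, lower)
        upper = upper2
        amplitude = upper - lower
    ref = float(np.percentile(amplitude, norm_percentile))
    norm = amplitude / ref if ref > 0 else np.zeros(n)
    return WhiskSignal(angle=angle, fs=fs, filtered=filt, phase=phase,
                       upper_env=upper, lower_env=lower, amplitude=amplitude,
                       amplitude_norm=np.clip(norm, 0.0, 1.0),
                       amp_max=float(amplitude.max()), amp_norm_ref=ref)


def detect_bouts(ws: WhiskSignal, threshold_frac: float = 0.2,
                 min_dur_s: float = 0.25) -> list[WhiskBout]:
    """Segment supra-threshold runs of normalized amplitude into whisking
    bouts (≥ ``min_dur_s``) and ambiguous shorter runs."""
    above = ws.amplitude_norm > threshold_frac
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    bouts = []
    for s, e in zip(starts, ends):
        dur = (e - s) / ws.fs
        cls = "whisking" if dur >= min_dur_s else "ambiguous"
        bouts.append(WhiskBout(start_s=s / ws.fs, end_s=e / ws.fs, classification=cls))
    return bouts


def whisk_triggered_average(traces, bouts, trials: TrialTable,
                            pre_s: float = 1.0, post_s: float = 2.0,
                            iti_window_s: tuple[float, float] = (2.0, 8.0)):
    """Calcium aligned to inter-trial whisking-bout starts.

    Only bouts starting 2–8 s after the preceding stimulus (and before the
    next one) qualify. Alignment is by time stamp: the calcium frame whose
    interval contains the bout start is index 0. Returns
    ``(lag_times, mean, sem, n_bouts)``; empty arrays when nothing
    qualifies.
    """
    starts = np.array([b.start_s for b in bouts
                       if getattr(b, "classification", "whisking") == "whisking"])
    onsets = trials.onset_time
    qualify = []
    for t0 in starts:
        i = np.searchsorted(onsets, t0) - 1
        if i < 0:
            continue
        since = t0 - onsets[i]
        before_next = i + 1 >= onsets.size or t0 < onsets[i + 1]
        if iti_window_s[0] <= since <= iti_window_s[1] and before_next:
            qualify.append(t0)
    fs = traces[0].fs
    n_pre, n_post = int(round(pre_s * fs)), int(round(post_s * fs))
    segs = []
    for trace in traces:
        for t0 in qualify:
            i0 = int(np.floor(t0 * fs))
            if i0 - n_pre < 0 or i0 + n_post > trace.n_frames:
                continue
            segs.append(trace.dff[i0 - n_pre:i0 + n_post])
    lag = np.arange(-n_pre, n_post) / fs
    if not segs:
        return lag, np.zeros(0), np.zeros(0), 0
    segs = np.asarray(segs)
    return lag, segs.mean(axis=0), segs.std(axis=0) / np.sqrt(segs.shape[0]), len(qualify)
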