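"""Core containers for a single behavioral imaging session.

A session couples four time bases: tuft ΔF/F traces sampled at the imaging
frame rate (30 Hz for two-photon, 10 Hz for volumetric recordings), a trial
table in seconds from session start, lick event times, and the median
whisker angle at the whisker-camera rate (125 Hz). All alignment elsewhere
in the package is done by time stamp, never by index ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STIMULI = ("CS+", "CS-")
OUTCOMES = ("hit", "miss", "FA", "CR")
CATEGORIES = ("unresponsive", "selective", "unselective")


class FormatError(ValueError):
    """A stored session is missing a required field."""


class ConsistencyError(ValueError):
    """Field lengths or values are mutually inconsistent."""


class ConfigError(ValueError):
    """A simulation or analysis configuration value is invalid."""


@dataclass
class TuftTrace:
    """ΔF/F trace of one segmented apical tuft.

    ``tuft_id`` is stable across sessions and is the key used for
    longitudinal matching.
    """

    tuft_id: str
    dff: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 1:
            raise ConsistencyError(f"dff for {self.tuft_id!r} must be 1-D")
        if not np.all(np.isfinite(self.dff)):
            raise ConsistencyError(f"non-finite ΔF/F samples in {self.tuft_id!r}")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise ConsistencyError("fs must be > 0")

    @property
    def n_frames(self) -> int:
        return self.dff.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs

    @property
    def times(self) -> np.ndarray:
        """Start time of each frame, in seconds from session start."""
        return np.arange(self.n_frames) / self.fs


@dataclass
class TrialTable:
    """Per-trial stimulus onsets, identities and (derived) outcomes."""

    onset_time: np.ndarray
    stimulus: np.ndarray
    rewarded: np.ndarray
    outcome: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onset_time = np.asarray(self.onset_time, dtype=float)
        self.stimulus = np.asarray(self.stimulus, dtype=object)
        self.rewarded = np.asarray(self.rewarded, dtype=bool)
        n = self.onset_time.size
        if self.stimulus.size != n or self.rewarded.size != n:
            raise ConsistencyError("trial table columns have mismatched lengths")
        if n and np.any(np.diff(self.onset_time) <= 0):
            raise ConsistencyError("trial onsets must be strictly increasing")
        bad = set(self.stimulus) - set(STIMULI)
        if bad:
            raise ConsistencyError(f"unknown stimulus labels: {sorted(map(str, bad))}")
        if self.outcome is not None:
            self.outcome = np.asarray(self.outcome, dtype=object)
            if self.outcome.size != n:
                raise ConsistencyError("outcome column has mismatched length")

    @property
    def n_trials(self) -> int:
        return self.onset_time.size

    def onsets(self, stimulus: str | None = None) -> np.ndarray:
        if stimulus is None:
            return self.onset_time
        return self.onset_time[self.stimulus == stimulus]

    def to_frame(self) -> pd.DataFrame:
        d = {
            "onset_time": self.onset_time,
            "stimulus": self.stimulus,
            "rewarded": self.rewarded,
        }
        if self.outcome is not None:
            d["outcome"] = self.outcome
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        for col in ("onset_time", "stimulus", "rewarded"):
            if col not in df.columns:
                raise FormatError(f"trial table missing column {col!r}")
        return cls(
            onset_time=df["onset_time"].to_numpy(float),
            stimulus=df["stimulus"].to_numpy(object),
            rewarded=df["rewarded"].to_numpy(bool),
            outcome=df["outcome"].to_numpy(object) if "outcome" in df.columns else None,
        )


@dataclass
class SessionData:
    """All inputs for one session of one animal."""

    session_label: str
    tufts: list[TuftTrace]
    trials: TrialTable
    licks: np.ndarray
    whisker_angle: np.ndarray
    whisker_fps: float = 125.0

    def __post_init__(self) -> None:
        self.licks = np.sort(np.asarray(self.licks, dtype=float))
        self.whisker_angle = np.asarray(self.whisker_angle, dtype=float)
        if self.tufts:
            fs0, n0 = self.tufts[0].fs, self.tufts[0].n_frames
            for t in self.tufts:
                if t.fs != fs0 or t.n_frames != n0:
                    raise ConsistencyError("all tufts must share fs and frame count")
            dur = self.duration_s
            for name, ev in (("lick", self.licks), ("trial onset", self.trials.onset_time)):
                if ev.size and (ev.min() < 0 or ev.max() > dur):
                    raise ConsistencyError(f"{name} times fall outside [0, {dur:.1f}] s")

    @property
    def fs(self) -> float:
        return self.tufts[0].fs if self.tufts else float("nan")

    @property
    def duration_s(self) -> float:
        return self.tufts[0].duration_s if self.tufts else self.whisker_angle.size / self.whisker_fps

    @property
    def tuft_ids(self) -> list[str]:
        return [t.tuft_id for t in self.tufts]


@dataclass
class EventTrain:
    """Detected spontaneous calcium events on one trace."""

    event_times: np.ndarray
    event_amplitudes: np.ndarray
    rate_per_min: float
    noise_sd: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_amplitudes = np.asarray(self.event_amplitudes, dtype=float)

    @property
    def n_events(self) -> int:
        return self.event_times.size
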