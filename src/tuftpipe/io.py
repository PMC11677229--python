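"""Read/write the session container and cohort directories.

One hierarchical HDF5 file per session holds the tuft traces (2-D ΔF/F
matrix plus ids), the trial table, lick times and the whisker-angle series;
trial and lick tables can additionally be exported as CSV. A cohort is a
directory of ``session_NN_<label>.h5`` files plus a ground-truth sidecar.
"""
from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datamodel import FormatError, SessionData, TrialTable, TuftTrace
from .simulate import GroundTruth, SimConfig


def write_session(session: SessionData, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["session_label"] = session.session_label
        f.attrs["whisker_fps"] = float(session.whisker_fps)
        g = f.create_group("traces")
        g.attrs["fs"] = float(session.fs)
        g.create_dataset("dff", data=np.stack([t.dff for t in session.tufts]))
        g.create_dataset("tuft_ids",
                         data=np.array(session.tuft_ids, dtype=h5py.string_dtype()))
        tr = f.create_group("trials")
        tr.create_dataset("onset_time", data=session.trials.onset_time)
        tr.create_dataset("stimulus",
                          data=np.array(session.trials.stimulus, dtype=h5py.string_dtype()))
        tr.create_dataset("rewarded", data=session.trials.rewarded)
        if session.trials.outcome is not None:
            tr.create_dataset("outcome",
                              data=np.array(session.trials.outcome, dtype=h5py.string_dtype()))
        f.create_dataset("licks", data=session.licks)
        w = f.create_group("whisker")
        w.create_dataset("angle", data=session.whisker_angle)


def read_session(path) -> SessionData:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in ("traces", "trials", "licks", "whisker"):
            if key not in f:
                raise FormatError(f"session file missing required field {key!r}")
        g = f["traces"]
        for key in ("dff", "tuft_ids"):
            if key not in g:
                raise FormatError(f"session file missing required field 'traces/{key}'")
        dff = g["dff"][()]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in g["tuft_ids"][()]]
        if dff.shape[0] != len(ids):
            raise FormatError("traces/dff and traces/tuft_ids have mismatched lengths")
        fs = float(g.attrs["fs"])
        tr = f["trials"]
        for key in ("onset_time", "stimulus", "rewarded"):
            if key not in tr:
                raise FormatError(f"session file missing required field 'trials/{key}'")
        stim = np.array([s.decode() if isinstance(s, bytes) else str(s)
                         for s in tr["stimulus"][()]], dtype=object)
        outcome = None
        if "outcome" in tr:
            outcome = np.array([s.decode() if isinstance(s, bytes) else str(s)
                                for s in tr["outcome"][()]], dtype=object)
        trials = TrialTable(onset_time=tr["onset_time"][()], stimulus=stim,
                            rewarded=tr["rewarded"][()], outcome=outcome)
        if "angle" not in f["whisker"]:
            raise FormatError("session file missing required field 'whisker/angle'")
        return SessionData(
            session_label=str(f.attrs["session_label"]),
            tufts=[TuftTrace(tuft_id=i, dff=d, fs=fs) for i, d in zip(ids, dff)],
            trials=trials,
            licks=f["licks"][()],
            whisker_angle=f["whisker"]["angle"][()],
            whisker_fps=float(f.attrs["whisker_fps"]),
        )


def export_tables(session: SessionData, out_dir) -> list[Path]:
    """CSV export of the trial and lick tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / "trials.csv", out / "licks.csv"]
    session.trials.to_frame().to_csv(paths[0], index=False)
    pd.DataFrame({"lick_time": session.licks}).to_csv(paths[1], index=False)
    return paths


def _session_filename(index: int, label: str) -> str:
    return f"session_{index:02d}_{label}.h5"


def write_cohort(sessions: list[SessionData], ground_truth: GroundTruth | None,
                 out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(sessions):
        write_session(s, out / _session_filename(i, s.session_label))
    if ground_truth is not None:
        write_ground_truth(ground_truth, out / "ground_truth.h5")


def read_cohort(in_dir) -> list[SessionData]:
    files = sorted(Path(in_dir).glob("session_*.h5"))
    if not files:
        raise FormatError(f"no session_*.h5 files in {in_dir}")
    return [read_session(p) for p in files]


def write_ground_truth(gt: GroundTruth, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(gt.config.to_dict())
        f.attrs["session_labels"] = json.dumps(gt.session_labels)
        f.attrs["lick_policy"] = json.dumps(gt.lick_policy)
        f.attrs["evoked_amplitude_mean"] = gt.evoked_amplitude_mean
        f.create_dataset("si", data=gt.si)
        f.create_dataset("responsive", data=gt.responsive)
        f.create_dataset("p_success", data=gt.p_success)
        for s in range(len(gt.session_labels)):
            g = f.create_group(f"session_{s:02d}")
            g.create_dataset("whisk_bouts", data=gt.whisk_bouts[s])
            for j, (succ, spont) in enumerate(zip(gt.evoked_success[s],
                                                  gt.spont_event_times[s])):
                g.create_dataset(f"evoked_success_{j:04d}", data=succ)
                g.create_dataset(f"spont_times_{j:04d}", data=spont)


def read_ground_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        cfg_d = json.loads(f.attrs["config"])
        cfg_d["iti_range_s"] = tuple(cfg_d["iti_range_s"])
        cfg_d["p_pref_range"] = tuple(cfg_d["p_pref_range"])
        cfg_d["whisk_bout_amp_range"] = tuple(cfg_d["whisk_bout_amp_range"])
        cfg_d["whisk_bout_dur_range"] = tuple(cfg_d["whisk_bout_dur_range"])
        labels = json.loads(f.attrs["session_labels"])
        n_s = len(labels)
        n_t = f["si"].shape[1]
        evoked, spont, bouts = [], [], []
        for s in range(n_s):
            g = f[f"session_{s:02d}"]
            bouts.append(g["whisk_bouts"][()])
            evoked.append([g[f"evoked_success_{j:04d}"][()] for j in range(n_t)])
            spont.append([g[f"spont_times_{j:04d}"][()] for j in range(n_t)])
        return GroundTruth(
            config=SimConfig(**cfg_d),
            session_labels=labels,
            si=f["si"][()],
            responsive=f["responsive"][()],
            p_success=f["p_success"][()],
            evoked_amplitude_mean=float(f.attrs["evoked_amplitude_mean"]),
            evoked_success=evoked,
            spont_event_times=spont,
            whisk_bouts=bouts,
            lick_policy=json.loads(f.attrs["lick_policy"]),
        )
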