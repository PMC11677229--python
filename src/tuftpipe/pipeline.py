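"""Cohort-level orchestration: per-session summaries, longitudinal tables,
and delimited-text / JSON reports.

``run_pipeline`` takes the sessions of one arm (in chronological order),
classifies every tuft, summarizes behavior and population selectivity per
session, decodes stimulus identity per session, and tabulates category
transitions between the first and last sessions. Every exclusion (dropped
trials, undefined SI, unclassifiable tufts) is counted in the report log,
and outputs embed the seed and a hash of the analysis configuration.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import session_behavior_summary
from .datamodel import CATEGORIES, SessionData
from .encoding import decode_session
from .longitudinal import TransitionResult, build_transitions
from .selectivity import (analyze_session, population_selectivity_summary,
                          selectivity_vs_performance)

DEFAULT_CONFIG = {
    "alpha": 0.05,
    "amp_threshold": 0.04,
    "response_window_s": 0.5,
    "decode_iterations": 10,
    "svm_C": 1.0,
    "include_unresponsive_in_si": False,
}


@dataclass
class CohortReport:
    session_summary: pd.DataFrame
    transitions: TransitionResult | None
    selectivity_performance_r: float
    selectivity_performance_p: float
    records: dict                  # session label -> list[SelectivityRecord]
    log: dict
    config: dict
    config_hash: str
    seed: int
    failed_stages: list = field(default_factory=list)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(sessions: list[SessionData], config: dict | None = None,
                 out_dir=None, seed: int = 0) -> CohortReport:
    """Analyze one arm's sessions; optionally write tables to ``out_dir``."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    log: dict = {"exclusions": {}}
    failed: list = []

    rows = []
    records_by_label: dict = {}
    for s_idx, session in enumerate(sessions):
        label = session.session_label
        row = {"session": label, "n_tufts": len(session.tufts)}
        try:
            beh = session_behavior_summary(session.trials, session.licks,
                                           cfg["response_window_s"])
            row.update(p_lick_csp=beh.p_lick_csp, p_lick_csm=beh.p_lick_csm,
                       discrimination=beh.discrimination)
        except Exception:
            failed.append((label, "behavior"))
        try:
            records = analyze_session(session, alpha=cfg["alpha"],
                                      amp_threshold=cfg["amp_threshold"])
            records_by_label[label] = records
            for cat in CATEGORIES:
                row[f"n_{cat}"] = sum(r.selectivity_class == cat for r in records)
            summ = population_selectivity_summary(
                records, include_unresponsive=cfg["include_unresponsive_in_si"])
            row["median_abs_si"] = summ["median_abs_si"]
            dps = [r.dprime for r in records
                   if np.isfinite(r.dprime) and r.responsiveness == "responsive"]
            row["mean_dprime"] = float(np.mean(dps)) if dps else float("nan")
            log["exclusions"][label] = {
                "undefined_si": sum(not r.si_defined for r in records),
                "unclassifiable": sum(r.responsiveness == "unclassifiable"
                                      for r in records),
            }
        except Exception:
            failed.append((label, "selectivity"))
        try:
            dec = decode_session(session, n_iterations=cfg["decode_iterations"],
                                 C=cfg["svm_C"], seed=seed + s_idx)
            row.update(decode_pre=dec.accuracy_pre, decode_post=dec.accuracy_post)
        except Exception:
            failed.append((label, "decoding"))
        rows.append(row)
    summary = pd.DataFrame(rows)

    transitions = None
    if len(sessions) >= 2:
        try:
            transitions = build_transitions(
                records_by_label[sessions[0].session_label],
                records_by_label[sessions[-1].session_label])
        except Exception:
            failed.append(("cohort", "transitions"))

    r = p = float("nan")
    if ("median_abs_si" in summary and "discrimination" in summary
            and len(summary) >= 3):
        try:
            r, p = selectivity_vs_performance(summary["median_abs_si"],
                                              summary["discrimination"])
        except Exception:
            failed.append(("cohort", "selectivity_vs_performance"))

    report = CohortReport(session_summary=summary, transitions=transitions,
                          selectivity_performance_r=r, selectivity_performance_p=p,
                          records=records_by_label, log=log, config=cfg,
                          config_hash=_config_hash(cfg), seed=seed,
                          failed_stages=failed)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: CohortReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={report.config_hash} seed={report.seed}\n"
    with open(out / "session_summary.tsv", "w") as f:
        f.write(header)
        report.session_summary.to_csv(f, sep="\t", index=False, float_format="%.6g")
    if report.transitions is not None:
        with open(out / "transitions.tsv", "w") as f:
            f.write(header)
            report.transitions.counts.to_csv(f, sep="\t")
    payload = {
        "config": report.config,
        "config_hash": report.config_hash,
        "seed": report.seed,
        "selectivity_performance_r": report.selectivity_performance_r,
        "selectivity_performance_p": report.selectivity_performance_p,
        "log": report.log,
        "failed_stages": report.failed_stages,
        "session_summary": report.session_summary.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as f:
        json.dump(payload, f, indent=2, default=float)


def make_figures(report: CohortReport, out_dir) -> list:
    """Optional figures: SI histograms per session and the learning curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    labels = list(report.records)
    if labels:
        fig, axes = plt.subplots(1, len(labels), figsize=(3 * len(labels), 3),
                                 sharey=True, squeeze=False)
        for ax, label in zip(axes[0], labels):
            s = population_selectivity_summary(report.records[label])
            if s["hist"] is not None:
                centers = 0.5 * (s["bin_edges"][:-1] + s["bin_edges"][1:])
                ax.bar(centers, s["hist"], width=0.1)
            ax.set_title(label)
            ax.set_xlabel("SI")
        axes[0][0].set_ylabel("tufts")
        p = out / "si_histograms.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    if {"p_lick_csp", "p_lick_csm"} <= set(report.session_summary.columns):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(report.session_summary["p_lick_csp"], "o-", label="CS+")
        ax.plot(report.session_summary["p_lick_csm"], "s-", label="CS-")
        ax.set_xlabel("session")
        ax.set_ylabel("P(lick in window)")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        p = out / "learning_curve.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
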