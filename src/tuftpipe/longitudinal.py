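"""Longitudinal matching of tufts and category-transition statistics.

Tufts are matched across sessions by their persistent ``tuft_id``. The
3×3 transition table counts tufts moving among the unresponsive / selective
/ unselective categories between a first and a last session; arm-level
contrasts use a two-sample t-test across animals between arms and a paired
t-test within an arm. Proportion differences between pooled tuft counts use
the pooled two-proportion Z approximation to the binomial.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CATEGORIES


@dataclass
class LongitudinalRecord:
    tuft_id: str
    categories: dict      # session label -> category
    si: dict              # session label -> SI
    delta_abs_si: float   # |SI|_last − |SI|_first


@dataclass
class TransitionResult:
    counts: pd.DataFrame        # rows = first-session, cols = last-session
    proportions: pd.DataFrame   # counts / matched total
    n_matched: int
    n_excluded: int


@dataclass
class TwoProportionResult:
    z: float
    p: float
    degenerate: bool = False


def track_tufts(records_first, records_last) -> list[LongitudinalRecord]:
    """Pair records of matched tuft ids between two sessions."""
    by_id_last = {r.tuft_id: r for r in records_last}
    out = []
    for rf in records_first:
        rl = by_id_last.get(rf.tuft_id)
        if rl is None:
            continue
        delta = (abs(rl.si) - abs(rf.si)
                 if rf.si_defined and rl.si_defined else float("nan"))
        out.append(LongitudinalRecord(
            tuft_id=rf.tuft_id,
            categories={"first": rf.selectivity_class, "last": rl.selectivity_class},
            si={"first": rf.si, "last": rl.si},
            delta_abs_si=delta))
    return out


def build_transitions(records_first, records_last) -> TransitionResult:
    """3×3 first→last category counts over matched tuft ids."""
    ids_f = {r.tuft_id for r in records_first}
    ids_l = {r.tuft_id for r in records_last}
    matched = ids_f & ids_l
    n_excluded = len(ids_f ^ ids_l)
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    by_id_l = {r.tuft_id: r for r in records_last}
    for rf in records_first:
        if rf.tuft_id not in matched:
            continue
        counts.loc[rf.selectivity_class, by_id_l[rf.tuft_id].selectivity_class] += 1
    n = counts.to_numpy().sum()
    props = counts / n if n else counts.astype(float)
    return TransitionResult(counts=counts, proportions=props,
                            n_matched=int(n), n_excluded=n_excluded)


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TwoProportionResult:
    """Pooled two-proportion z-test (Z approximation to the binomial).

    ``z = (k1/n1 − k2/n2) / sqrt(p̂(1−p̂)(1/n1 + 1/n2))`` with pooled
    ``p̂ = (k1+k2)/(n1+n2)``; two-sided p from the standard Normal. No
    continuity correction is applied.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n")
    p_pool = (k1 + k2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return TwoProportionResult(z=0.0, p=1.0, degenerate=True)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return TwoProportionResult(z=float(z), p=float(2 * stats.norm.sf(abs(z))))


def compare_arms(cond_props: pd.DataFrame, exp_props: pd.DataFrame) -> dict:
    """Arm contrasts on per-animal category proportions.

    ``*_props`` frames have one row per animal and columns 'selective' /
    'unselective' (extra columns are ignored). Returns two-sample t-tests
    between arms per category and within-arm paired t-tests between the
    selective and unselective proportions; entries are None with fewer than
    2 animals in an arm.
    """
    out = {"between": {}, "within": {}}
    if len(cond_props) < 2 or len(exp_props) < 2:
        return {"between": None, "within": None}
    for cat in ("selective", "unselective"):
        t, p = stats.ttest_ind(cond_props[cat], exp_props[cat])
        out["between"][cat] = {"t": float(t), "p": float(p)}
    for name, props in (("conditioned", cond_props), ("exposure", exp_props)):
        t, p = stats.ttest_rel(props["selective"], props["unselective"])
        if np.isnan(t):  # identical columns -> zero variance of differences
            t, p = 0.0, 1.0
        out["within"][name] = {"t": float(t), "p": float(p)}
    return out
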