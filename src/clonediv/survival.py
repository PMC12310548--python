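"""Time-to-first-treatment machinery: Kaplan-Meier, log-rank, maxstat.

Kaplan-Meier estimation and the plain two-group log-rank test are
delegated to lifelines.  The maximally selected log-rank cutpoint search —
used to derive the iSI 1.2 threshold separating ID_high from ID_low — is
implemented here: every distinct marker value inside an inner quantile
window is tried as a dichotomization point, the standardized log-rank
statistic (O - E)/sqrt(V) is computed for each, and the maximizing value
is reported with a multiplicity-adjusted p-value (Miller-Siegmund
improved-Bonferroni approximation for maximally selected statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as sps

from .io import SurvivalRecord

__all__ = [
    "KMCurve",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "standardized_logrank",
    "maxstat_cutpoint",
    "stratified_ttft_report",
]


@dataclass
class KMCurve:
    event_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray
    median_time: Optional[float]  # None when survival never reaches 0.5


@dataclass
class CutpointResult:
    candidate_cutoffs: np.ndarray  # reported split boundaries (midpoints)
    standardized_statistics: np.ndarray
    best_cutoff: float
    max_statistic: float
    p_adjusted: float


def _arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    return times, events


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit survival curve; simultaneous events share a time point."""
    if not records:
        raise ValueError("no survival records")
    times, events = _arrays(records)
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    surv = fitter.survival_function_["KM_estimate"]
    event_times = surv.index.to_numpy(dtype=float)
    probs = surv.to_numpy(dtype=float)
    at_risk = fitter.event_table["at_risk"].reindex(surv.index).ffill()\
        .to_numpy(dtype=float).astype(int)
    median = fitter.median_survival_time_
    return KMCurve(
        event_times=event_times,
        survival_probs=probs,
        n_at_risk=at_risk,
        median_time=None if np.isinf(median) else float(median),
    )


def logrank_test(group_a: list[SurvivalRecord],
                 group_b: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _arrays(group_a)
    tb, eb = _arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def standardized_logrank(times: np.ndarray, events: np.ndarray,
                         in_group: np.ndarray) -> float:
    """(O - E)/sqrt(V) for membership vector ``in_group`` (hypergeometric V)."""
    order = np.argsort(times, kind="stable")
    times, events, in_group = times[order], events[order], in_group[order]
    n = len(times)
    observed = expected = variance = 0.0
    i = 0
    at_risk_total = n
    at_risk_group = int(in_group.sum())
    while i < n:
        j = i
        d = d1 = 0
        removed = removed_group = 0
        while j < n and times[j] == times[i]:
            removed += 1
            removed_group += int(in_group[j])
            if events[j]:
                d += 1
                d1 += int(in_group[j])
            j += 1
        if d > 0 and at_risk_total > 1:
            frac = at_risk_group / at_risk_total
            observed += d1
            expected += d * frac
            variance += (d * frac * (1 - frac)
                         * (at_risk_total - d) / (at_risk_total - 1))
        at_risk_total -= removed
        at_risk_group -= removed_group
        i = j
    if variance <= 0:
        return 0.0
    return (observed - expected) / np.sqrt(variance)


def maxstat_cutpoint(values, records: list[SurvivalRecord],
                     quantile_window: tuple[float, float] = (0.1, 0.9)
                     ) -> CutpointResult:
    """Maximally selected log-rank cutpoint over an inner quantile window.

    Candidates are the distinct marker values v whose low group
    (value <= v) keeps both groups within the window proportions; the
    reported cutoff is the boundary above the optimal split value (the
    midpoint to the next distinct value).  ``p_adjusted`` uses the
    Miller-Siegmund approximation and is never below the unadjusted
    minimum p.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(records):
        raise ValueError("values and records must be aligned")
    if len(values) < 10:
        raise ValueError("at least 10 samples required for cutpoint search")
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("all marker values identical: no cutpoint exists")
    times, events = _arrays(records)
    eps1, eps2 = quantile_window
    n = len(values)
    candidates, stats_z, boundaries = [], [], []
    for k in range(distinct.size - 1):
        v = distinct[k]
        prop_low = np.mean(values <= v)
        if not (eps1 <= prop_low <= eps2):
            continue
        z = standardized_logrank(times, events, values <= v)
        candidates.append(v)
        stats_z.append(z)
        boundaries.append(0.5 * (v + distinct[k + 1]))
    if not candidates:  # window excluded everything; fall back to all splits
        for k in range(distinct.size - 1):
            v = distinct[k]
            z = standardized_logrank(times, events, values <= v)
            candidates.append(v)
            stats_z.append(z)
            boundaries.append(0.5 * (v + distinct[k + 1]))
    stats_z = np.asarray(stats_z)
    best = int(np.argmax(np.abs(stats_z)))
    b = float(np.abs(stats_z[best]))
    p_unadjusted = 2.0 * sps.norm.sf(b)
    p_adj = _miller_siegmund(b, eps1, eps2)
    p_adjusted = float(min(1.0, max(p_unadjusted, p_adj)))
    return CutpointResult(
        candidate_cutoffs=np.asarray(boundaries),
        standardized_statistics=stats_z,
        best_cutoff=float(boundaries[best]),
        max_statistic=float(stats_z[best]),
        p_adjusted=p_adjusted,
    )


def _miller_siegmund(b: float, eps1: float, eps2: float) -> float:
    """Approximate P(max |Z| > b) for a maximally selected log-rank statistic."""
    if b <= 1.0:
        return 1.0
    log_odds = np.log(eps2 * (1 - eps1) / (eps1 * (1 - eps2)))
    phi = sps.norm.pdf(b)
    return float(4.0 * phi / b + phi * (b - 1.0 / b) * log_odds)


def stratified_ttft_report(samples: pd.DataFrame) -> dict:
    """Four-group KM summary over IGHV status x ID class.

    ``samples`` needs columns sample_id, time_months, event,
    mutational_status (M/U) and id_class (ID_high/ID_low).  Returns per
    non-empty group the size, KM curve and median, plus pairwise log-rank
    tests within the M and within the U stratum.
    """
    required = {"sample_id", "time_months", "event", "mutational_status", "id_class"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    groups: dict[str, list[SurvivalRecord]] = {}
    for (status, id_class), sub in samples.groupby(["mutational_status", "id_class"]):
        name = f"{status}-{id_class}"
        groups[name] = [
            SurvivalRecord(sample_id=str(r.sample_id),
                           time_months=float(r.time_months),
                           event=bool(r.event))
            for r in sub.itertuples(index=False)
        ]
    report = {"groups": {}, "tests": {}}
    for name, recs in sorted(groups.items()):
        km = km_estimate(recs)
        report["groups"][name] = {"n": len(recs), "km": km,
                                  "median_ttft": km.median_time}
    for stratum in ("M", "U"):
        members = [g for g in groups if g.startswith(f"{stratum}-")]
        for a, b in combinations(sorted(members), 2):
            chi2, p = logrank_test(groups[a], groups[b])
            report["tests"][f"{a} vs {b}"] = {"chi_square": chi2, "p_value": p}
    return report
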