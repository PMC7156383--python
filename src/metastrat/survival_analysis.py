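"""Kaplan-Meier estimation, median survival, and log-rank (Mantel-Cox) tests
between expression-defined patient clusters.

Estimation and testing are delegated to lifelines; this module fixes the
conventions the pipeline relies on (months as the time unit, deaths processed
before censorings at tied times, median survival as the smallest event time at
which S(t) drops to 0.5 or below, reported as not-reached when it never does)
and adds the cluster-level reporting layout: per-cluster curves and medians,
each cluster tested pairwise against a reference cluster, and the reference
tested against all remaining clusters pooled. Pairwise p-values are reported
unadjusted (the reporting convention for per-cluster comparisons); a
BH-adjusted column is emitted alongside for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .io_formats import ClinicalTable

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "cluster_survival_report",
]


@dataclass
class SurvivalCurve:
    event_times: np.ndarray  # distinct death times, increasing
    survival_probs: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray  # deaths at each event time
    n_subjects: int


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p_value: float
    group_sizes: list[int]


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events differ in length")
    if (times <= 0).any() or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and > 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 (censored) or 1 (death)")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator; deaths precede censorings at tied times."""
    times, events = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    death_rows = tbl[tbl["observed"] > 0]
    death_rows = death_rows[death_rows.index > 0]
    et = death_rows.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    probs = np.array([float(sf.loc[t]) for t in et])
    return SurvivalCurve(
        event_times=et,
        survival_probs=probs,
        at_risk=death_rows["at_risk"].to_numpy(dtype=int),
        n_events=death_rows["observed"].to_numpy(dtype=int),
        n_subjects=int(times.size),
    )


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5; NaN (not reached) otherwise."""
    hit = curve.survival_probs <= 0.5 + 1e-12
    if not hit.any():
        return math.nan
    return float(curve.event_times[np.argmax(hit)])


def logrank_test(groups) -> LogrankResult:
    """Mantel-Cox test over >= 2 groups of (times, events); df = groups - 1."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    all_t, all_e, all_g = [], [], []
    sizes = []
    for gi, (t, e) in enumerate(groups):
        t, e = _check_times_events(t, e)
        sizes.append(t.size)
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.full(t.size, gi))
    res = multivariate_logrank_test(
        np.concatenate(all_t), np.concatenate(all_g), np.concatenate(all_e)
    )
    return LogrankResult(
        chi_square=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
        group_sizes=sizes,
    )


def cluster_survival_report(
    clinical: ClinicalTable,
    labels: pd.Series | dict,
    reference_cluster: int = 1,
    pooled_comparison: list[int] | None = None,
) -> pd.DataFrame:
    """Per-cluster KM summary plus log-rank comparisons against a reference.

    ``labels`` maps sample_id -> cluster. Every labeled sample must have a
    clinical row. Rows of the returned frame: one per cluster with n, events,
    median survival, and the unadjusted p of that cluster vs the reference;
    plus a pooled row comparing the reference against ``pooled_comparison``
    (default: all other clusters) combined. A BH-adjusted column covers the
    pairwise family.
    """
    labels = pd.Series(labels)
    missing = labels.index.difference(clinical.data.index)
    if len(missing):
        raise ValueError(f"samples without clinical data: {sorted(missing)[:10]}")
    df = clinical.data.loc[labels.index]
    clusters = sorted(pd.unique(labels))
    if reference_cluster not in clusters:
        raise ValueError(f"reference cluster {reference_cluster} has no samples")

    def _group(cl_list):
        mask = labels.isin(cl_list).to_numpy()
        sub = df[mask]
        return sub["os_time"].to_numpy(dtype=float), sub["os_event"].to_numpy(dtype=int)

    ref = _group([reference_cluster])
    rows = []
    pairwise_p = {}
    for c in clusters:
        t, e = _group([c])
        curve = km_estimate(t, e)
        row = {
            "cluster": c,
            "n": int(t.size),
            "n_events": int(e.sum()),
            "median_survival": median_survival(curve),
            "p_vs_reference": math.nan,
        }
        if c != reference_cluster and len(clusters) > 1:
            lr = logrank_test([ref, (t, e)])
            row["p_vs_reference"] = lr.p_value
            pairwise_p[c] = lr.p_value
        rows.append(row)
    report = pd.DataFrame(rows).set_index("cluster")
    report["p_vs_reference_bh"] = math.nan
    if pairwise_p:
        adj = multipletests(list(pairwise_p.values()), method="fdr_bh")[1]
        for c, p in zip(pairwise_p, adj):
            report.loc[c, "p_vs_reference_bh"] = p
    others = pooled_comparison if pooled_comparison is not None else [
        c for c in clusters if c != reference_cluster
    ]
    others = [c for c in others if c in clusters and c != reference_cluster]
    if others:
        pooled = _group(others)
        lr = logrank_test([ref, pooled])
        pooled_row = {
            "n": int(pooled[0].size),
            "n_events": int(pooled[1].sum()),
            "median_survival": median_survival(km_estimate(*pooled)),
            "p_vs_reference": lr.p_value,
            "p_vs_reference_bh": math.nan,
        }
        report.loc[f"pooled_{'+'.join(map(str, others))}"] = pooled_row
    report.attrs["reference_cluster"] = reference_cluster
    return report
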