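"""Survival separation of a clustering: multi-group log-rank test and
Kaplan-Meier curves.

The C-sample log-rank statistic is the score test of a Cox proportional
hazards model with the cluster label as a single categorical covariate: at
each distinct event time, each group's observed event count is compared with
its expectation under the hypergeometric null, and the accumulated
differences are combined through the (generalized-)inverse covariance into a
chi-square statistic on C - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .clustering import ClusterAssignment
from .io import SurvivalTable

__all__ = ["LogRankResult", "KMCurve", "logrank_test", "km_curves", "neglog10_p"]


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    group_sizes: list[int]


@dataclass
class KMCurve:
    """Product-limit survival curve for one patient group."""

    group: int
    times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_patients: int


def _group_labels(assignment) -> np.ndarray:
    if isinstance(assignment, ClusterAssignment):
        return assignment.labels
    return np.asarray(assignment, dtype=int)


def logrank_test(survival: SurvivalTable, assignment) -> LogRankResult:
    """C-sample log-rank test for survival differences between clusters.

    Ties are handled with the standard hypergeometric (Mantel-Haenszel)
    variance. The statistic is d^T V^- d over C - 1 groups, referred to the
    upper tail of chi-square(C - 1).

    ``assignment`` may be a :class:`ClusterAssignment` (patient lists must
    match) or any integer label array aligned with the survival table.
    """
    if isinstance(assignment, ClusterAssignment) and assignment.patient_ids != survival.patient_ids:
        raise ValueError("assignment and survival table patient lists differ")
    labels = _group_labels(assignment)
    if labels.shape != survival.time.shape:
        raise ValueError("label length does not match survival table")
    groups, labels = np.unique(labels, return_inverse=True)
    n_groups = len(groups)
    if n_groups < 2:
        raise ValueError("log-rank test needs at least two nonempty groups")
    time, event = survival.time, survival.event
    if event.sum() == 0:
        raise ValueError("no events observed")

    event_times = np.unique(time[event == 1])
    m = len(event_times)
    # at-risk counts per group at each event time: #{t_i >= tau}
    at_risk = np.empty((n_groups, m))
    deaths = np.zeros((n_groups, m))
    for g in range(n_groups):
        tg = np.sort(time[labels == g])
        at_risk[g] = len(tg) - np.searchsorted(tg, event_times, side="left")
        tg_d = time[(labels == g) & (event == 1)]
        idx = np.searchsorted(event_times, tg_d)
        np.add.at(deaths[g], idx, 1.0)

    n_tot = at_risk.sum(axis=0)
    d_tot = deaths.sum(axis=0)
    frac = at_risk / n_tot
    observed = deaths.sum(axis=1)
    expected = (d_tot * frac).sum(axis=1)

    # hypergeometric covariance, summed over event times (skip n_tot == 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    cov = -np.einsum("t,gt,ht->gh", scale, frac, frac)
    cov[np.diag_indices_from(cov)] += (scale * frac).sum(axis=1)

    d = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    chi2 = float(d @ np.linalg.pinv(v) @ d)
    chi2 = max(chi2, 0.0)
    df = n_groups - 1
    p = float(stats.chi2.sf(chi2, df))
    p = min(max(p, 5e-324), 1.0)
    sizes = np.bincount(labels, minlength=n_groups).tolist()
    return LogRankResult(chi2, df, p, sizes)


def km_curves(survival: SurvivalTable, assignment) -> list[KMCurve]:
    """Kaplan-Meier product-limit curve per cluster.

    Censored patients leave the risk set without producing a step. Curves
    start at probability 1 (time 0) and are non-increasing.
    """
    if isinstance(assignment, ClusterAssignment) and assignment.patient_ids != survival.patient_ids:
        raise ValueError("assignment and survival table patient lists differ")
    labels = _group_labels(assignment)
    curves = []
    for g in np.unique(labels):
        sel = labels == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g}")
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[sel], survival.event[sel])
        sf = kmf.survival_function_
        times = sf.index.to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
        curves.append(
            KMCurve(
                group=int(g),
                times=times,
                survival_prob=sf.iloc[:, 0].to_numpy(dtype=float),
                at_risk=at_risk,
                n_patients=int(sel.sum()),
            )
        )
    return curves


def neglog10_p(p: float) -> float:
    """-log10 of a p-value; the scale used to compare cluster numbers."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return float(-np.log10(p))
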