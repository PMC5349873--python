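"""ROC-based marker screening, operating points, inference and FDR control.

Conventions: the positive class is high grade (label 1); classification
uses the "score >= threshold => positive" rule; ROC curves are empirical
step functions over observed thresholds, no interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .tables import grade_labels, marker_columns

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: thresholds in decreasing order with FPR/TPR arrays."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass(frozen=True)
class YoudenPoint:
    J: float
    sensitivity: float
    specificity: float
    threshold: float


@dataclass(frozen=True)
class MarkerStats:
    """Per-marker screening summary."""

    name: str
    auc: float
    p_value: float
    roc05: float
    youden: YoudenPoint
    orientation: int = 1
    auc_ci: tuple[float, float] | None = None
    fdr_q: float | None = None
    criteria: str | None = None  # "AUC" | "ROC(0.05)" | "BOTH" | None


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos, neg


def auc_mannwhitney(scores, labels) -> float:
    """AUC = P(pos > neg) + 0.5 P(pos = neg), via midranks."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical step-function ROC at every distinct observed score.

    Includes the (0,0) endpoint (threshold +inf); the lowest observed
    threshold classifies everything positive, giving (1,1).  The
    trapezoidal area equals :func:`auc_mannwhitney`.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.array([(scores[pos] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[neg] >= t).mean() for t in thresholds])
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def roc_auc_trapezoid(roc: ROCCurve) -> float:
    return float(np.trapezoid(roc.tpr, roc.fpr))


def tpr_at_fixed_fpr(roc: ROCCurve, fpr_cap: float = 0.05) -> float:
    """Maximum TPR over thresholds with empirical FPR <= cap (ROC(0.05))."""
    if not 0.0 <= fpr_cap <= 1.0:
        raise ValueError("fpr_cap must be in [0, 1]")
    ok = roc.fpr <= fpr_cap
    return float(roc.tpr[ok].max()) if ok.any() else 0.0


def youden_max(roc: ROCCurve) -> YoudenPoint:
    """Maximize J = TPR - FPR over thresholds; ties go to higher specificity."""
    j = roc.tpr - roc.fpr
    best = np.lexsort((roc.fpr, -j))[0]
    return YoudenPoint(
        J=float(j[best]),
        sensitivity=float(roc.tpr[best]),
        specificity=float(1.0 - roc.fpr[best]),
        threshold=float(roc.thresholds[best]),
    )


def marker_pvalue(scores, labels) -> float:
    """Two-sided Mann-Whitney p: normal approximation with tie correction.

    Degenerate variance (all scores tied) yields p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    n1, n2 = int(pos.sum()), int(neg.sum())
    if min(n1, n2) < 3:
        raise ValueError("need at least 3 subjects per class")
    n = n1 + n2
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return 1.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)  # continuity-corrected
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bootstrap_ci(
    scores,
    labels,
    statistic=auc_mannwhitney,
    draws: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile interval of a two-class statistic."""
    if draws < 100:
        raise ValueError("draws must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = _check_labels(labels)
    idx_pos = np.flatnonzero(pos)
    idx_neg = np.flatnonzero(neg)
    rng = np.random.default_rng(seed)
    stats = np.empty(draws)
    for b in range(draws):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=idx_pos.size, replace=True),
                rng.choice(idx_neg, size=idx_neg.size, replace=True),
            ]
        )
        stats[b] = statistic(scores[take], labels[take])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate_marker(
    scores,
    labels,
    name: str = "marker",
    bootstrap_draws: int = 0,
    level: float = 0.95,
    seed: int | None = None,
) -> MarkerStats:
    """Full screening summary for one marker, orienting so AUC >= 0.5."""
    scores = np.asarray(scores, dtype=float)
    p_value = marker_pvalue(scores, labels)
    orientation = 1
    if auc_mannwhitney(scores, labels) < 0.5:
        orientation = -1
        scores = -scores
    roc = roc_curve(scores, labels)
    ci = None
    if bootstrap_draws:
        ci = bootstrap_ci(scores, labels, draws=bootstrap_draws, level=level, seed=seed)
    return MarkerStats(
        name=name,
        auc=auc_mannwhitney(scores, labels),
        p_value=p_value,
        roc05=tpr_at_fixed_fpr(roc),
        youden=youden_max(roc),
        orientation=orientation,
        auc_ci=ci,
    )


def screen_and_select(
    table: pd.DataFrame,
    k_auc: int = 10,
    k_roc: int = 5,
    bootstrap_draws: int = 0,
    seed: int | None = None,
) -> tuple[list[MarkerStats], list[str]]:
    """Rank all markers and select the candidate set for panel building.

    Candidates are the union of the top ``k_auc`` markers by AUC and the
    top ``k_roc`` by ROC(0.05) (TPR at 5% FPR); each selected marker is
    tagged ``AUC``, ``ROC(0.05)`` or ``BOTH``.  Markers are oriented so
    AUC >= 0.5 before ranking, and BH q-values are attached.  The stats
    list is returned sorted by AUC (descending); candidate names preserve
    that order.
    """
    names = marker_columns(table)
    if len(names) < k_auc:
        raise ValueError(f"need at least k_auc={k_auc} markers, got {len(names)}")
    labels = grade_labels(table)
    rng = np.random.default_rng(seed)
    stats = [
        evaluate_marker(
            table[name].to_numpy(dtype=float),
            labels,
            name=name,
            bootstrap_draws=bootstrap_draws,
            seed=int(rng.integers(2**31)) if bootstrap_draws else None,
        )
        for name in names
    ]
    qs = bh_fdr([s.p_value for s in stats])
    by_auc = sorted(stats, key=lambda s: (-s.auc, s.name))
    by_roc = sorted(stats, key=lambda s: (-s.roc05, -s.auc, s.name))
    top_auc = {s.name for s in by_auc[:k_auc]}
    top_roc = {s.name for s in by_roc[:k_roc]}
    out = []
    for s, q in zip(stats, qs):
        tag = None
        if s.name in top_auc and s.name in top_roc:
            tag = "BOTH"
        elif s.name in top_auc:
            tag = "AUC"
        elif s.name in top_roc:
            tag = "ROC(0.05)"
        out.append(
            MarkerStats(
                name=s.name,
                auc=s.auc,
                p_value=s.p_value,
                roc05=s.roc05,
                youden=s.youden,
                orientation=s.orientation,
                auc_ci=s.auc_ci,
                fdr_q=float(q),
                criteria=tag,
            )
        )
    out.sort(key=lambda s: (-s.auc, s.name))
    candidates = [s.name for s in out if s.criteria is not None]
    return out, candidates


def stats_to_frame(stats: list[MarkerStats]) -> pd.DataFrame:
    """Tabular (Table-1-like) report of a list of MarkerStats."""
    return pd.DataFrame(
        {
            "marker": [s.name for s in stats],
            "criteria": [s.criteria or "" for s in stats],
            "auc": [s.auc for s in stats],
            "auc_ci_lo": [s.auc_ci[0] if s.auc_ci else np.nan for s in stats],
            "auc_ci_hi": [s.auc_ci[1] if s.auc_ci else np.nan for s in stats],
            "p_value": [s.p_value for s in stats],
            "fdr_q": [s.fdr_q if s.fdr_q is not None else np.nan for s in stats],
            "roc05": [s.roc05 for s in stats],
            "youden_j": [s.youden.J for s in stats],
            "sensitivity": [s.youden.sensitivity for s in stats],
            "specificity": [s.youden.specificity for s in stats],
            "orientation": [s.orientation for s in stats],
        }
    )
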