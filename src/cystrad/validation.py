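"""Leave-1/3-out cross-validation schemes and refit-per-draw panel bootstrap.

Scheme 1 keeps the marker set fixed and refits coefficients per split;
scheme 2 re-runs the whole procedure (screening, candidate selection,
exhaustive AIC search, fitting) inside each training split, so selection
optimism is excluded from the test AUC.  All splits and resamples are
stratified by grade and reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import FitFailure, exhaustive_aic_search, fit_logistic_ml, panel_predict
from .screening import (
    auc_mannwhitney,
    roc_curve,
    screen_and_select,
    youden_max,
    YoudenPoint,
)
from .tables import grade_labels, marker_matrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVResult:
    scheme: int
    repeats: int
    per_repeat_auc: np.ndarray
    mean_auc: float
    sd_auc: float
    n_failed: int
    seed: int | None


@dataclass(frozen=True)
class PanelBootstrap:
    auc: float
    auc_ci: tuple[float, float]
    youden: YoudenPoint
    youden_j_ci: tuple[float, float]
    draws: int
    n_redrawn: int
    seed: int | None


def _stratified_split(
    labels: np.ndarray, rng: np.random.Generator, test_frac: float = 1.0 / 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffle; ~test_frac of each class goes to the test set."""
    train, test = [], []
    for value in (0, 1):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        n_test = max(1, int(round(len(idx) * test_frac)))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.concatenate(train), np.concatenate(test)


def _finish(scheme, aucs, failed, seed):
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size == 0:
        raise FitFailure("every cross-validation repeat failed")
    return CVResult(
        scheme=scheme,
        repeats=aucs.size,
        per_repeat_auc=aucs,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        n_failed=failed,
        seed=seed,
    )


def cv_fixed_panel(
    table: pd.DataFrame,
    marker_names: list[str],
    repeats: int = 1000,
    seed: int | None = None,
    test_frac: float = 1.0 / 3.0,
) -> CVResult:
    """Scheme 1: fixed marker set, coefficients refit per stratified split."""
    labels = grade_labels(table)
    if min((labels == 0).sum(), (labels == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per class")
    x = marker_matrix(table, list(marker_names))
    rng = np.random.default_rng(seed)
    aucs, failed = [], 0
    for _ in range(repeats):
        train, test = _stratified_split(labels, rng, test_frac)
        try:
            model = fit_logistic_ml(x[train], labels[train], tuple(marker_names))
        except (FitFailure, ValueError) as exc:
            failed += 1
            log.warning("scheme-1 repeat failed: %s", exc)
            continue
        scores = panel_predict(model, x[test])
        aucs.append(auc_mannwhitney(scores, labels[test]))
    return _finish(1, aucs, failed, seed)


def cv_full_procedure(
    table: pd.DataFrame,
    repeats: int = 10,
    seed: int | None = None,
    k_auc: int = 10,
    k_roc: int = 5,
    test_frac: float = 1.0 / 3.0,
) -> CVResult:
    """Scheme 2: screening, selection, AIC search and fitting all in-train.

    Per repeat the full marker table is split 2/3-1/3 (stratified); the
    candidate set and the AIC-best panel are derived from the training
    split alone, the fitted coefficients are frozen, and the test-split
    AUC of the frozen model is recorded.
    """
    labels = grade_labels(table)
    if min((labels == 0).sum(), (labels == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per class")
    rng = np.random.default_rng(seed)
    aucs, failed = [], 0
    for _ in range(repeats):
        train, test = _stratified_split(labels, rng, test_frac)
        train_table = table.iloc[train].reset_index(drop=True)
        test_table = table.iloc[test].reset_index(drop=True)
        try:
            _, candidates = screen_and_select(train_table, k_auc=k_auc, k_roc=k_roc)
            model, _ = exhaustive_aic_search(train_table, candidates)
        except (FitFailure, ValueError) as exc:
            failed += 1
            log.warning("scheme-2 repeat failed: %s", exc)
            continue
        scores = panel_predict(model, test_table)
        aucs.append(auc_mannwhitney(scores, grade_labels(test_table)))
    return _finish(2, aucs, failed, seed)


def bootstrap_panel_ci(
    table: pd.DataFrame,
    marker_names: list[str],
    draws: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    max_redraws: int = 100,
) -> PanelBootstrap:
    """Refit-per-draw stratified bootstrap of the panel AUC and Youden J.

    Each draw resamples subjects within class, refits the coefficients on
    the resample and evaluates the in-draw AUC, so coefficient variance is
    part of the interval.  Failed fits are redrawn (counted, logged).
    """
    if draws < 100:
        raise ValueError("draws must be >= 100")
    labels = grade_labels(table)
    x = marker_matrix(table, list(marker_names))
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    full_model = fit_logistic_ml(x, labels, tuple(marker_names))
    full_scores = panel_predict(full_model, x)
    point_auc = auc_mannwhitney(full_scores, labels)
    point_youden = youden_max(roc_curve(full_scores, labels))
    rng = np.random.default_rng(seed)
    aucs = np.empty(draws)
    js = np.empty(draws)
    redrawn = 0
    for b in range(draws):
        for _attempt in range(max_redraws):
            take = np.concatenate(
                [
                    rng.choice(idx_pos, size=idx_pos.size, replace=True),
                    rng.choice(idx_neg, size=idx_neg.size, replace=True),
                ]
            )
            try:
                model = fit_logistic_ml(x[take], labels[take], tuple(marker_names))
            except (FitFailure, ValueError) as exc:
                redrawn += 1
                log.warning("bootstrap draw redrawn: %s", exc)
                continue
            scores = panel_predict(model, x[take])
            aucs[b] = auc_mannwhitney(scores, labels[take])
            js[b] = youden_max(roc_curve(scores, labels[take])).J
            break
        else:
            raise FitFailure("bootstrap draw kept failing after redraws")
    alpha = (1.0 - level) / 2.0
    auc_ci = tuple(float(v) for v in np.quantile(aucs, [alpha, 1.0 - alpha]))
    j_ci = tuple(float(v) for v in np.quantile(js, [alpha, 1.0 - alpha]))
    return PanelBootstrap(
        auc=point_auc,
        auc_ci=auc_ci,
        youden=point_youden,
        youden_j_ci=j_ci,
        draws=draws,
        n_redrawn=redrawn,
        seed=seed,
    )
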