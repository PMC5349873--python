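"""Maximum-likelihood logistic panels and the exhaustive AIC subset search.

Fitting is plain IRLS on z-scored markers (predictions are invariant to the
scaling).  Quasi-separation — likely at n ~ 53 with up to 15 markers — is
detected by coefficient divergence and handled by a flagged refit with a
small L2 penalty on the non-intercept coefficients, which keeps the
exhaustive search total.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .tables import grade_labels, marker_matrix

log = logging.getLogger(__name__)

_COEF_BOUND = 15.0  # |standardized coefficient| beyond this ~ separation
_RIDGE_FALLBACK = 1e-4


class FitFailure(RuntimeError):
    """The likelihood maximization could not produce a usable model."""


@dataclass(frozen=True)
class PanelModel:
    """A fitted logistic model over a named marker subset.

    Coefficients are stored in the standardized (z-scored) marker space
    together with the training means/SDs used for the scaling, so
    predictions on raw marker values are exact.
    """

    marker_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    aic: float
    converged: bool
    separation_flag: bool
    n_obs: int

    @property
    def k(self) -> int:
        """Number of free parameters (intercept + markers)."""
        return 1 + len(self.marker_names)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    return float(y @ np.log(mu) + (1.0 - y) @ np.log(1.0 - mu))


def _irls(
    x1: np.ndarray, y: np.ndarray, ridge: float, max_iter: int, tol: float
) -> tuple[np.ndarray, bool, bool]:
    """Returns (beta, converged, diverged). Ridge skips the intercept."""
    n, p1 = x1.shape
    beta = np.zeros(p1)
    penalty = np.zeros(p1)
    penalty[1:] = ridge
    for _ in range(max_iter):
        eta = x1 @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        xw = x1 * w[:, None]
        lhs = x1.T @ xw + np.diag(penalty)
        try:
            new = np.linalg.solve(lhs, xw.T @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(lhs, xw.T @ z, rcond=None)[0]
        step = np.max(np.abs(new - beta))
        beta = new
        if np.max(np.abs(beta)) > _COEF_BOUND:
            return beta, False, True
        if step < tol:
            return beta, True, False
    return beta, False, False


def fit_logistic_ml(
    design: np.ndarray,
    labels: np.ndarray,
    marker_names: tuple[str, ...] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PanelModel:
    """IRLS maximum-likelihood logistic fit of grade on a marker matrix.

    ``design`` is subjects x markers (may have zero columns for the
    intercept-only model).  On detected separation the model is refit with
    an L2 penalty of 1e-4 on non-intercept coefficients and flagged.
    """
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=float)
    n, p = x.shape
    if marker_names is None:
        marker_names = tuple(f"m{j}" for j in range(p))
    if len(marker_names) != p:
        raise ValueError("marker_names length must match design columns")
    if n <= p + 1:
        raise ValueError(f"need n > number of coefficients ({p + 1}), got n = {n}")
    means = x.mean(axis=0) if p else np.empty(0)
    sds = x.std(axis=0) if p else np.empty(0)
    if p and np.any(sds == 0):
        bad = [marker_names[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance marker column(s): {bad}")
    xz = (x - means) / sds if p else x
    x1 = np.column_stack([np.ones(n), xz])
    beta, converged, diverged = _irls(x1, y, 0.0, max_iter, tol)
    separation = bool(diverged)
    if diverged:
        beta, converged, diverged = _irls(x1, y, _RIDGE_FALLBACK, max_iter, tol)
        if diverged:
            converged = False  # keep bounded estimate, still flagged
    if not np.all(np.isfinite(beta)):
        raise FitFailure("non-finite coefficients after fallback")
    ll = _loglik(y, x1 @ beta)
    return PanelModel(
        marker_names=tuple(marker_names),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        means=means,
        sds=sds,
        log_likelihood=ll,
        aic=2.0 * (1 + p) - 2.0 * ll,
        converged=bool(converged),
        separation_flag=separation,
        n_obs=n,
    )


def model_aic(model: PanelModel) -> float:
    """AIC = 2k - 2 log L with k = 1 + number of markers."""
    return 2.0 * model.k - 2.0 * model.log_likelihood


def panel_predict(model: PanelModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Logistic risk scores in (0,1) for new subjects.

    ``features`` is either a DataFrame containing all of the model's marker
    columns or an array whose columns follow ``model.marker_names``.
    """
    if isinstance(features, pd.DataFrame):
        missing = [m for m in model.marker_names if m not in features.columns]
        if missing:
            raise ValueError(f"features lack model markers: {missing}")
        x = features.loc[:, list(model.marker_names)].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != len(model.marker_names):
            raise ValueError("feature array has wrong number of columns")
    if len(model.marker_names):
        x = (x - model.means) / model.sds
        eta = model.intercept + x @ model.coefficients
    else:
        eta = np.full(x.shape[0] if x.size else 0, model.intercept)
    return expit(eta)


def exhaustive_aic_search(
    table: pd.DataFrame,
    candidates: list[str],
    max_candidates: int = 15,
) -> tuple[PanelModel, pd.DataFrame]:
    """Fit every non-empty subset of the candidates; return the AIC minimizer.

    Tie-breaking is deterministic: lower AIC, then fewer markers, then
    lexicographic marker names.  Subsets whose fit fails are excluded with
    a logged reason.  Also returns the full ranking as a DataFrame
    (columns: markers, k, log_likelihood, aic, converged, separation).
    """
    candidates = sorted(candidates)
    if not 1 <= len(candidates) <= max_candidates:
        raise ValueError(
            f"need 1..{max_candidates} candidates, got {len(candidates)}"
        )
    y = grade_labels(table)
    x_all = marker_matrix(table, candidates)
    col = {name: j for j, name in enumerate(candidates)}
    rows = []
    best: PanelModel | None = None
    best_key = None
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            idx = [col[m] for m in subset]
            try:
                model = fit_logistic_ml(x_all[:, idx], y, marker_names=subset)
            except (FitFailure, ValueError) as exc:
                log.warning("subset %s excluded: %s", subset, exc)
                continue
            rows.append(
                {
                    "markers": "+".join(subset),
                    "k": model.k,
                    "log_likelihood": model.log_likelihood,
                    "aic": model.aic,
                    "converged": model.converged,
                    "separation": model.separation_flag,
                }
            )
            key = (model.aic, size, subset)
            if best_key is None or key < best_key:
                best, best_key = model, key
    if best is None:
        raise FitFailure("every candidate subset failed to fit")
    ranking = pd.DataFrame(rows).sort_values(
        ["aic", "k", "markers"], kind="stable", ignore_index=True
    )
    return best, ranking
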