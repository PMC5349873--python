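"""Standardized principal-component projections of feature tables.

Correlation-matrix PCA: columns are z-scored (population SD), the
population covariance of the standardized table is eigendecomposed, and
subjects are projected onto the leading components.  Class separation in
the projected plane is summarized by the standardized centroid distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import GRADE_COLUMN, ID_COLUMN, grade_labels, marker_columns

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCAProjection:
    component_loadings: np.ndarray  # markers x components, orthonormal columns
    explained_variance_fractions: np.ndarray
    scores: np.ndarray  # subjects x components
    labels: np.ndarray
    marker_names: tuple[str, ...]


def standardize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every marker column (population SD); drop constant columns.

    Dropping is logged; an all-constant table is an error.
    """
    names = marker_columns(table)
    keep, dropped = [], []
    for name in names:
        if table[name].to_numpy(dtype=float).std() == 0:
            dropped.append(name)
        else:
            keep.append(name)
    if dropped:
        log.warning("dropping %d zero-variance marker(s): %s", len(dropped), dropped)
    if not keep:
        raise ValueError("all marker columns have zero variance")
    out = table[[c for c in (ID_COLUMN, GRADE_COLUMN) if c in table.columns] + keep].copy()
    for name in keep:
        v = out[name].to_numpy(dtype=float)
        out[name] = (v - v.mean()) / v.std()
    return out


def pca_project(standardized: pd.DataFrame, n_components: int = 2) -> PCAProjection:
    """Project subjects onto the leading principal components.

    Components are eigenvectors of the population covariance, ordered by
    decreasing eigenvalue, with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).
    """
    names = marker_columns(standardized)
    x = standardized.loc[:, names].to_numpy(dtype=float)
    n, m = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if m < n_components:
        raise ValueError(f"need >= {n_components} markers, got {m}")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    for j in range(m):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] *= -1.0
    total = eigvals.sum()
    loadings = eigvecs[:, :n_components]
    labels = (
        grade_labels(standardized)
        if GRADE_COLUMN in standardized.columns
        else np.zeros(n, dtype=int)
    )
    return PCAProjection(
        component_loadings=loadings,
        explained_variance_fractions=eigvals[:n_components] / total if total > 0 else eigvals[:n_components],
        scores=xc @ loadings,
        labels=labels,
        marker_names=tuple(names),
    )


def class_separation(projection: PCAProjection) -> float:
    """Between-class centroid distance in units of pooled within-class SD.

    Pooled SD is the square root of the mean within-class variance over
    the projected components.
    """
    scores, labels = projection.scores, projection.labels
    if len(set(labels.tolist())) != 2:
        raise ValueError("separation needs exactly two classes")
    a, b = scores[labels == 1], scores[labels == 0]
    centroid_dist = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    pooled_var = float(np.concatenate([a - a.mean(axis=0), b - b.mean(axis=0)]).var())
    if pooled_var == 0:
        return float("inf") if centroid_dist > 0 else 0.0
    return centroid_dist / np.sqrt(pooled_var)
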