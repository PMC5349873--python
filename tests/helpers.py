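"""Independent oracles used by the unit and acceptance tests.

These stay deliberately naive (triple loops, generic optimizers, direct
formulas) so they exercise the library through a different route than the
implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def naive_glcm(
    quantized: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int, int],
    levels: int,
    symmetric: bool = True,
) -> np.ndarray:
    """Pair-enumeration GLCM: normalized counts via an explicit triple loop."""
    counts = np.zeros((levels, levels), dtype=float)
    nx, ny, nz = quantized.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                x2, y2, z2 = x + offset[0], y + offset[1], z + offset[2]
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                if not mask[x2, y2, z2]:
                    continue
                counts[quantized[x, y, z], quantized[x2, y2, z2]] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by brute-force enumeration of all (positive, negative) pairs."""
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def bfgs_logistic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ML logistic coefficients (intercept first) on z-scored columns,
    via a generic second-order-ish optimizer."""
    x = np.asarray(x, dtype=float)
    if x.size:
        x = (x - x.mean(axis=0)) / x.std(axis=0)
    x1 = np.column_stack([np.ones(len(y)), x])
    y = np.asarray(y, dtype=float)

    def nll(beta):
        mu = np.clip(expit(x1 @ beta), 1e-12, 1 - 1e-12)
        return -(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))

    res = minimize(nll, np.zeros(x1.shape[1]), method="BFGS",
                   options={"gtol": 1e-11, "maxiter": 2000})
    return res.x


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """BH adjusted values by the literal step-up definition (no vectorizing)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q
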