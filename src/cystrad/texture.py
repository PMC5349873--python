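"""ROI quantization, gray-level co-occurrence matrices and first-order stats.

The feature family of interest is the Haralick *correlation* statistic of
the GLCM, computed over a masked region of a 3D volume for a set of integer
voxel offsets, either fully volumetric (``3D``) or per-slice in-plane
(``2.5D``).  Secondary GLCM statistics (contrast, entropy, energy,
homogeneity) and first-order intensity statistics are also provided.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import GRADE_COLUMN, ID_COLUMN, parse_grade

log = logging.getLogger(__name__)

#: The 13 unique 3D direction vectors (up to sign) on the 26-neighbourhood.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0),
    (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: The 4 unique in-plane directions (dz = 0) for 2.5D accumulation.
DIRECTIONS_2D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0),
)

DEFAULT_DISTANCES: tuple[int, ...] = (1, 4, 7)
DEFAULT_LEVELS = 32


class NoPairsError(ValueError):
    """No voxel pair with both endpoints in-mask exists for the offset."""


@dataclass(frozen=True)
class ImageVolume:
    """3D gray-level array with (informational) voxel spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"image must be 3D with all dims >= 1, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "voxels", v)


@dataclass(frozen=True)
class ROIMask:
    """Binary mask, voxel-aligned with its image."""

    voxels: np.ndarray
    region_kind: str = "cyst"

    def __post_init__(self):
        m = np.asarray(self.voxels, dtype=bool)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        if m.sum() < 2:
            raise ValueError("mask must select at least 2 voxels")
        object.__setattr__(self, "voxels", m)


@dataclass(frozen=True)
class GLCMSpec:
    """One co-occurrence configuration: mode, direction, distance, levels."""

    direction: tuple[int, int, int]
    distance: int = 1
    levels: int = DEFAULT_LEVELS
    mode: str = "3D"
    symmetric: bool = True

    def __post_init__(self):
        d = tuple(int(x) for x in self.direction)
        if d == (0, 0, 0):
            raise ValueError("direction must be nonzero")
        if int(np.gcd.reduce([abs(x) for x in d if x] or [1])) != 1:
            raise ValueError(f"direction components must have gcd 1: {d}")
        if self.distance < 1:
            raise ValueError("distance must be a positive integer")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.mode not in ("3D", "2.5D"):
            raise ValueError(f"mode must be '3D' or '2.5D', got {self.mode!r}")
        if self.mode == "2.5D" and d[2] != 0:
            raise ValueError("2.5D mode requires dz = 0")
        object.__setattr__(self, "direction", d)

    @property
    def offset(self) -> tuple[int, int, int]:
        return tuple(c * self.distance for c in self.direction)

    @property
    def column_tag(self) -> str:
        kind = "GLCM3" if self.mode == "3D" else "GLCM25"
        dx, dy, dz = self.direction
        return f"{kind}_{dx}{dy}{dz}-{self.distance}"


@dataclass(frozen=True)
class GLCMMatrix:
    """Normalized co-occurrence probabilities with marginal moments."""

    p: np.ndarray
    n_pairs: int
    mu_i: float = field(init=False)
    mu_j: float = field(init=False)
    sigma_i: float = field(init=False)
    sigma_j: float = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("p must be a square matrix")
        if (p < 0).any():
            raise ValueError("p must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("p must sum to 1")
        levels = np.arange(p.shape[0], dtype=float)
        pi, pj = p.sum(axis=1), p.sum(axis=0)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "mu_i", float(levels @ pi))
        object.__setattr__(self, "mu_j", float(levels @ pj))
        object.__setattr__(self, "sigma_i", float(np.sqrt(max(levels**2 @ pi - (levels @ pi) ** 2, 0.0))))
        object.__setattr__(self, "sigma_j", float(np.sqrt(max(levels**2 @ pj - (levels @ pj) ** 2, 0.0))))

    @property
    def levels(self) -> int:
        return self.p.shape[0]


def quantize_roi(image: ImageVolume, mask: ROIMask, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Equal-width quantization of masked voxels to integers 0..levels-1.

    Bins span the min-max range of the masked voxels; the maximum maps to
    ``levels - 1`` and a constant ROI maps everywhere to level 0.  Voxels
    outside the mask are set to -1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if image.voxels.shape != mask.voxels.shape:
        raise ValueError("image and mask shapes differ")
    values = image.voxels[mask.voxels]
    if values.size < 2:
        raise ValueError("mask must select at least 2 voxels")
    lo, hi = float(values.min()), float(values.max())
    out = np.full(image.voxels.shape, -1, dtype=np.int32)
    if hi == lo:
        out[mask.voxels] = 0
        return out
    scaled = np.floor((values - lo) / (hi - lo) * levels).astype(np.int32)
    out[mask.voxels] = np.minimum(scaled, levels - 1)
    return out


def _accumulate(quantized: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int], levels: int) -> np.ndarray:
    """Directed pair counts for one offset, both endpoints in-mask."""
    shape = quantized.shape
    src, dst = [], []
    for o, s in zip(offset, shape):
        if abs(o) >= s:
            return np.zeros((levels, levels), dtype=np.int64)
        src.append(slice(max(0, -o), min(s, s - o)))
        dst.append(slice(max(0, o), min(s, s + o)))
    src, dst = tuple(src), tuple(dst)
    valid = mask[src] & mask[dst]
    i = quantized[src][valid]
    j = quantized[dst][valid]
    flat = np.bincount(i * levels + j, minlength=levels * levels)
    return flat.reshape(levels, levels).astype(np.int64)


def compute_glcm(quantized: np.ndarray, mask: ROIMask, spec: GLCMSpec) -> GLCMMatrix:
    """Co-occurrence matrix of a quantized ROI for one offset.

    Counts only pairs with both endpoints inside the mask.  In ``2.5D``
    mode counts are accumulated slice by slice (in-plane offsets, pooled
    across slices before normalizing); symmetric mode adds the transposed
    counts.  Raises :class:`NoPairsError` when no valid pair exists.
    """
    m = mask.voxels
    if quantized.shape != m.shape:
        raise ValueError("quantized array and mask shapes differ")
    offset = spec.offset
    levels = spec.levels
    if spec.mode == "2.5D":
        counts = np.zeros((levels, levels), dtype=np.int64)
        off2 = offset[:2] + (0,)
        for k in range(quantized.shape[2]):
            counts += _accumulate(
                quantized[:, :, k : k + 1], m[:, :, k : k + 1], off2, levels
            )
    else:
        counts = _accumulate(quantized, m, offset, levels)
    if spec.symmetric:
        counts = counts + counts.T
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise NoPairsError(f"no in-mask voxel pair for offset {offset}")
    return GLCMMatrix(p=counts / n_pairs, n_pairs=n_pairs)


def glcm_correlation(glcm: GLCMMatrix) -> float:
    """Haralick correlation: normalized cross-moment of the GLCM.

    Returns 1.0 by convention when either marginal SD is zero (homogeneous
    region), keeping feature tables rectangular.
    """
    denom = glcm.sigma_i * glcm.sigma_j
    if denom == 0.0:
        return 1.0
    idx = np.arange(glcm.levels, dtype=float)
    cross = float((idx - glcm.mu_i) @ glcm.p @ (idx - glcm.mu_j))
    return float(np.clip(cross / denom, -1.0, 1.0))


def glcm_secondary_stats(glcm: GLCMMatrix) -> dict[str, float]:
    """Contrast, entropy (bits), energy and homogeneity of a GLCM."""
    idx = np.arange(glcm.levels, dtype=float)
    diff = idx[:, None] - idx[None, :]
    p = glcm.p
    nz = p[p > 0]
    return {
        "contrast": float((p * diff**2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "energy": float((p**2).sum()),
        "homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
    }

_GLCM_STATS = ("correlation", "contrast", "entropy", "energy", "homogeneity")


def glcm_statistic(glcm: GLCMMatrix, statistic: str) -> float:
    if statistic == "correlation":
        return glcm_correlation(glcm)
    if statistic in _GLCM_STATS:
        return glcm_secondary_stats(glcm)[statistic]
    raise ValueError(f"unknown GLCM statistic {statistic!r}")


def first_order_stats(
    image: ImageVolume, mask: ROIMask, entropy_bins: int = DEFAULT_LEVELS
) -> dict[str, float]:
    """Mean, population SD, (non-excess) kurtosis and histogram entropy.

    Kurtosis is the standardized fourth central moment (Gaussian -> 3);
    reported as NaN when the ROI variance is zero or fewer than 4 voxels
    are masked.  Entropy uses an equal-width histogram of the masked
    voxels, in bits.
    """
    if image.voxels.shape != mask.voxels.shape:
        raise ValueError("image and mask shapes differ")
    values = image.voxels[mask.voxels]
    if values.size < 2:
        raise ValueError("need at least 2 masked voxels")
    mean = float(values.mean())
    var = float(values.var())  # population
    sd = float(np.sqrt(var))
    if var > 0 and values.size >= 4:
        kurtosis = float(((values - mean) ** 4).mean() / var**2)
    else:
        kurtosis = float("nan")
    if values.max() > values.min():
        counts, _ = np.histogram(values, bins=entropy_bins)
    else:
        counts = np.array([values.size])
    freq = counts[counts > 0] / values.size
    entropy = float(-(freq * np.log2(freq)).sum())
    return {"mean": mean, "sd": sd, "kurtosis": kurtosis, "entropy": entropy}


def default_specs(
    mode: str = "3D",
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
    levels: int = DEFAULT_LEVELS,
    symmetric: bool = True,
) -> list[GLCMSpec]:
    """Canonical direction set crossed with the requested distances."""
    directions = DIRECTIONS_3D if mode == "3D" else DIRECTIONS_2D
    return [
        GLCMSpec(direction=d, distance=dist, levels=levels, mode=mode, symmetric=symmetric)
        for d, dist in itertools.product(directions, distances)
    ]


def extract_features(
    cohort: list[tuple[ImageVolume, ROIMask, str]],
    specs: list[GLCMSpec] | None = None,
    levels: int = DEFAULT_LEVELS,
    statistics: tuple[str, ...] = ("correlation",),
    include_first_order: bool = True,
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Extract a feature table (one row per subject) from image/mask pairs.

    GLCM columns are named ``{GLCM3|GLCM25}_{dx}{dy}{dz}-{distance}_{stat}``;
    first-order columns are prefixed ``FO_``.  A feature that cannot be
    computed for some subject (no valid pairs) is recorded as missing, and
    any column missing for at least one subject is dropped with a warning.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    if specs is None:
        specs = default_specs(levels=levels)
    if not specs:
        raise ValueError("specs must be nonempty")
    if subject_ids is None:
        subject_ids = [f"S{k + 1:03d}" for k in range(len(cohort))]
    rows = []
    for sid, (image, mask, grade) in zip(subject_ids, cohort):
        if image.voxels.shape != mask.voxels.shape:
            raise ValueError(f"subject {sid}: image and mask shapes differ")
        row: dict[str, object] = {ID_COLUMN: sid, GRADE_COLUMN: parse_grade(grade)}
        cache: dict[int, np.ndarray] = {}
        for spec in specs:
            if spec.levels not in cache:
                cache[spec.levels] = quantize_roi(image, mask, spec.levels)
            try:
                glcm = compute_glcm(cache[spec.levels], mask, spec)
            except NoPairsError:
                for stat in statistics:
                    row[f"{spec.column_tag}_{stat}"] = np.nan
                continue
            for stat in statistics:
                row[f"{spec.column_tag}_{stat}"] = glcm_statistic(glcm, stat)
        if include_first_order:
            for name, value in first_order_stats(image, mask).items():
                row[f"FO_{name}"] = value
        rows.append(row)
    table = pd.DataFrame(rows)
    feature_cols = [c for c in table.columns if c not in (ID_COLUMN, GRADE_COLUMN)]
    incomplete = [c for c in feature_cols if table[c].isna().any()]
    if incomplete:
        log.warning("dropping %d feature(s) missing in some subject: %s", len(incomplete), incomplete)
        table = table.drop(columns=incomplete)
    return table
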