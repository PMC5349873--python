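"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators:

- smoothed-Gaussian-field texture volumes with ellipsoidal ROI masks, where
  the per-class spatial correlation length controls how discriminative the
  GLCM correlation features are;
- binormal feature tables with markers dialled to designed AUCs
  (``AUC = Phi(delta / sqrt(2))`` for mean separation ``delta``);
- worrisome-feature records allocated to exact per-grade criterion margins,
  with every record triggering at least one criterion when feasible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtri

from .tables import GRADE_COLUMN, ID_COLUMN
from .texture import ImageVolume, ROIMask

#: Criterion keys in canonical order (matches record column order).
FUKUOKA_CRITERIA = (
    "main_duct_involvement",
    "cyst_gt_3cm",
    "mural_nodule",
    "mpd_gt_5mm",
    "positive_cytology",
    "symptomatic",
)

#: Printed per-grade worrisome-feature margins of the 53-lesion cohort.
TABLE2_MARGINS: dict[str, dict[str, int]] = {
    "HG": {
        "n": 34,
        "main_duct_involvement": 2,
        "cyst_gt_3cm": 13,
        "mural_nodule": 6,
        "mpd_gt_5mm": 9,
        "positive_cytology": 4,
        "symptomatic": 8,
    },
    "LG": {
        "n": 19,
        "main_duct_involvement": 4,
        "cyst_gt_3cm": 10,
        "mural_nodule": 1,
        "mpd_gt_5mm": 3,
        "positive_cytology": 2,
        "symptomatic": 2,
    },
}


@dataclass(frozen=True)
class TextureClassSpec:
    """Generative parameters of one grade's texture class."""

    label: str
    field_smoothing: float
    intensity_mean: float = 100.0
    intensity_sd: float = 20.0
    noise_sd: float = 2.0

    def __post_init__(self):
        if self.field_smoothing <= 0:
            raise ValueError("field_smoothing must be positive")
        if self.intensity_sd <= 0:
            raise ValueError("intensity_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class BinormalMarkerSpec:
    """A marker with a designed AUC under the binormal two-class model."""

    name: str
    target_auc: float
    correlation_to_previous: float | None = None

    def __post_init__(self):
        if not 0.5 <= self.target_auc < 1.0:
            raise ValueError(f"target_auc must be in [0.5, 1), got {self.target_auc}")
        rho = self.correlation_to_previous
        if rho is not None and not -1.0 < rho < 1.0:
            raise ValueError("correlation_to_previous must be in (-1, 1)")

    @property
    def delta(self) -> float:
        """Class mean separation achieving the target AUC: sqrt(2)*Phi^-1(AUC)."""
        return float(np.sqrt(2.0) * ndtri(self.target_auc))


@dataclass(frozen=True)
class FukuokaRecord:
    """One lesion's worrisome-feature fields plus its pathological grade."""

    subject_id: str
    main_duct_involvement: bool
    cyst_size_cm: float
    mural_nodule: bool
    mpd_diameter_mm: float
    positive_cytology: bool
    symptomatic: bool
    grade: str

    def __post_init__(self):
        if self.cyst_size_cm < 0:
            raise ValueError("cyst_size_cm must be nonnegative")
        if self.mpd_diameter_mm < 0:
            raise ValueError("mpd_diameter_mm must be nonnegative")
        if self.grade not in ("HG", "LG"):
            raise ValueError(f"grade must be 'HG' or 'LG', got {self.grade!r}")


def _ellipsoid_mask(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    # Base semi-axes 0.425*dim with +-10% jitter keep coverage in ~[0.23, 0.43].
    radii = np.array([0.425 * s for s in shape]) * rng.uniform(0.9, 1.1, size=3)
    center = (np.asarray(shape) - 1) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist2 <= 1.0


def _texture_volume(shape, spec: TextureClassSpec, rng: np.random.Generator) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), spec.field_smoothing)
    field = (field - field.mean()) / field.std()
    voxels = spec.intensity_mean + spec.intensity_sd * field
    if spec.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=shape)
    return voxels


def generate_texture_cohort(
    n_hg: int,
    n_lg: int,
    shape: tuple[int, int, int],
    hg_spec: TextureClassSpec,
    lg_spec: TextureClassSpec,
    seed: int,
) -> list[tuple[ImageVolume, ROIMask, str]]:
    """Simulate a two-class cohort of textured volumes with ROI masks.

    Each volume is a Gaussian random field (white noise smoothed with the
    class's correlation length, rescaled to the class intensity scale) plus
    additive white noise; the ROI is a centered ellipsoid with seeded radius
    jitter covering at least 20% of the volume.  HG subjects come first.
    """
    if n_hg < 1 or n_lg < 1:
        raise ValueError("need at least one subject per class")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError(f"each volume dim must be >= 8, got {shape}")
    rng = np.random.default_rng(seed)
    cohort = []
    for grade, spec, count in (("HG", hg_spec, n_hg), ("LG", lg_spec, n_lg)):
        for _ in range(count):
            voxels = _texture_volume(shape, spec, rng)
            mask = _ellipsoid_mask(shape, rng)
            cohort.append((ImageVolume(voxels), ROIMask(mask, region_kind="cyst"), grade))
    return cohort


def generate_feature_table(
    n_hg: int,
    n_lg: int,
    specs: list[BinormalMarkerSpec],
    n_noise_markers: int = 0,
    seed: int = 0,
    noise_prefix: str = "noise",
) -> pd.DataFrame:
    """Binormal feature table: LG ~ N(0,1), HG ~ N(delta,1) per marker.

    ``correlation_to_previous`` induces the stated correlation between a
    marker's noise component and the previous spec's.  Noise markers are
    standard normal in both classes.
    """
    if n_hg < 1 or n_lg < 1:
        raise ValueError("need at least one subject per class")
    if not specs and n_noise_markers == 0:
        raise ValueError("specs must be nonempty")
    rng = np.random.default_rng(seed)
    n = n_hg + n_lg
    labels = np.concatenate([np.ones(n_hg, dtype=int), np.zeros(n_lg, dtype=int)])
    data: dict[str, np.ndarray] = {
        ID_COLUMN: [f"S{k + 1:03d}" for k in range(n)],
        GRADE_COLUMN: labels,
    }
    prev = None
    for spec in specs:
        eps = rng.standard_normal(n)
        if spec.correlation_to_previous is not None and prev is not None:
            rho = spec.correlation_to_previous
            base = rho * prev + np.sqrt(1.0 - rho**2) * eps
        else:
            base = eps
        data[spec.name] = base + spec.delta * labels
        prev = base
    for k in range(n_noise_markers):
        data[f"{noise_prefix}{k + 1:03d}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


def _allocate_criteria(
    n: int, counts: dict[str, int], rng: np.random.Generator
) -> list[set[str]]:
    """Greedy allocation hitting exact margins with every subject covered.

    Criteria are processed rarest-first; each criterion's quota goes to
    still-uncovered subjects before being filled round-robin among the
    covered, with seeded tie-breaking throughout.
    """
    total = sum(counts.values())
    if total < n:
        raise ValueError(
            f"infeasible margins: {total} criterion slots for {n} subjects"
        )
    for name, c in counts.items():
        if c < 0 or c > n:
            raise ValueError(f"count for {name!r} must be in [0, {n}], got {c}")
    flags: list[set[str]] = [set() for _ in range(n)]
    order = sorted(counts, key=lambda name: (counts[name], name))
    for name in order:
        quota = counts[name]
        uncovered = [i for i in range(n) if not flags[i]]
        rng.shuffle(uncovered)
        chosen = uncovered[:quota]
        if len(chosen) < quota:
            eligible = [i for i in range(n) if flags[i] and name not in flags[i]]
            rng.shuffle(eligible)
            eligible.sort(key=lambda i: len(flags[i]))  # stable: fewest flags first
            chosen += eligible[: quota - len(chosen)]
        if len(chosen) < quota:
            raise ValueError(f"cannot place {quota} subjects for criterion {name!r}")
        for i in chosen:
            flags[i].add(name)
    if any(not f for f in flags):
        raise ValueError("allocation left a subject with no criterion")
    return flags


def generate_fukuoka_cohort(
    table2_margins: dict[str, dict[str, int]],
    seed: int = 0,
) -> list[FukuokaRecord]:
    """Generate records whose per-grade criterion counts match the margins.

    ``table2_margins`` maps grade -> {"n": subjects, <criterion>: count, ...}
    (see :data:`TABLE2_MARGINS`).  Continuous fields are drawn strictly
    inside/outside their thresholds: cyst size Uniform(3.1, 6.0) cm when
    flagged else Uniform(0.5, 3.0); duct diameter Uniform(5.5, 10) mm when
    flagged else Uniform(1, 5).  Every record triggers >= 1 criterion.
    """
    rng = np.random.default_rng(seed)
    records: list[FukuokaRecord] = []
    for grade in sorted(table2_margins):
        margins = dict(table2_margins[grade])
        n = int(margins.pop("n"))
        if n < 1:
            raise ValueError(f"grade {grade!r} must have n >= 1")
        unknown = set(margins) - set(FUKUOKA_CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria in margins: {sorted(unknown)}")
        counts = {c: int(margins.get(c, 0)) for c in FUKUOKA_CRITERIA}
        flags = _allocate_criteria(n, counts, rng)
        for i, f in enumerate(flags):
            big_cyst = "cyst_gt_3cm" in f
            wide_duct = "mpd_gt_5mm" in f
            records.append(
                FukuokaRecord(
                    subject_id=f"{grade}-{i + 1:02d}",
                    main_duct_involvement="main_duct_involvement" in f,
                    cyst_size_cm=float(
                        rng.uniform(3.1, 6.0) if big_cyst else rng.uniform(0.5, 3.0)
                    ),
                    mural_nodule="mural_nodule" in f,
                    mpd_diameter_mm=float(
                        rng.uniform(5.5, 10.0) if wide_duct else rng.uniform(1.0, 5.0)
                    ),
                    positive_cytology="positive_cytology" in f,
                    symptomatic="symptomatic" in f,
                    grade=grade,
                )
            )
    return records
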