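"""End-to-end orchestration: extract -> screen -> panel -> validate -> PCA.

A :class:`RunConfig` fixes every stage parameter and a single root seed;
per-stage seeds are expanded deterministically from it, so one number
reproduces a whole run.  Artifacts are written to a run directory, each
stamped with the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .panel import exhaustive_aic_search, panel_predict
from .pca import class_separation, pca_project, standardize_features
from .screening import auc_mannwhitney, roc_curve, screen_and_select, stats_to_frame
from .tables import GRADE_COLUMN, ID_COLUMN, grade_labels, validate_feature_table
from .texture import default_specs, extract_features
from .validation import bootstrap_panel_ci, cv_fixed_panel, cv_full_procedure

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Every knob of the pipeline plus the root seed."""

    seed: int = 0
    # extraction
    levels: int = 32
    glcm_mode: str = "3D"
    distances: tuple[int, ...] = (1, 4, 7)
    symmetric: bool = True
    statistics: tuple[str, ...] = ("correlation",)
    # screening / panel
    k_auc: int = 10
    k_roc: int = 5
    marker_bootstrap_draws: int = 1000
    # validation
    cv1_repeats: int = 1000
    cv2_repeats: int = 10
    panel_bootstrap_draws: int = 1000
    ci_level: float = 0.95

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cleaned = dict(mapping)
        for key in ("distances", "statistics"):
            if key in cleaned:
                cleaned[key] = tuple(cleaned[key])
        return cls(**cleaned)


def extract_cohort_features(cohort_dir: str | Path, config: RunConfig) -> pd.DataFrame:
    cohort, ids = cio.load_cohort(cohort_dir)
    specs = default_specs(
        mode=config.glcm_mode,
        distances=config.distances,
        levels=config.levels,
        symmetric=config.symmetric,
    )
    return extract_features(
        cohort,
        specs=specs,
        levels=config.levels,
        statistics=config.statistics,
        subject_ids=ids,
    )


def run_pipeline(
    table: pd.DataFrame,
    config: RunConfig,
    outdir: str | Path,
    make_plots: bool = True,
) -> dict:
    """Screen, build the panel, validate, bootstrap and project one table.

    Writes a Table-1-like marker report, the subset ranking and best panel,
    both CV results, the panel bootstrap and the PCA view into ``outdir``.
    Returns a summary dict (also written as ``summary.json``).
    """
    table = validate_feature_table(table)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    cio.write_json(dataclasses.asdict(config) | stamp, outdir / "config.json")

    stats, candidates = screen_and_select(
        table,
        k_auc=config.k_auc,
        k_roc=config.k_roc,
        bootstrap_draws=config.marker_bootstrap_draws,
        seed=config.stage_seed("marker_bootstrap"),
    )
    stats_to_frame(stats).to_csv(outdir / "marker_report.csv", index=False)

    best, ranking = exhaustive_aic_search(table, candidates)
    ranking.to_csv(outdir / "panel_ranking.csv", index=False)
    resub_scores = panel_predict(best, table)
    labels = grade_labels(table)
    resub_auc = auc_mannwhitney(resub_scores, labels)
    roc = roc_curve(resub_scores, labels)
    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(outdir / "panel_roc.csv", index=False)
    cio.write_json(
        {
            "markers": list(best.marker_names),
            "intercept": best.intercept,
            "coefficients": best.coefficients,
            "means": best.means,
            "sds": best.sds,
            "log_likelihood": best.log_likelihood,
            "aic": best.aic,
            "converged": best.converged,
            "separation_flag": best.separation_flag,
            "resubstitution_auc": resub_auc,
        }
        | stamp,
        outdir / "best_panel.json",
    )

    cv1 = cv_fixed_panel(
        table,
        list(best.marker_names),
        repeats=config.cv1_repeats,
        seed=config.stage_seed("cv1"),
    )
    cv2 = cv_full_procedure(
        table,
        repeats=config.cv2_repeats,
        seed=config.stage_seed("cv2"),
        k_auc=config.k_auc,
        k_roc=config.k_roc,
    )
    for cv, name in ((cv1, "cv_scheme1.json"), (cv2, "cv_scheme2.json")):
        cio.write_json(
            {
                "scheme": cv.scheme,
                "repeats": cv.repeats,
                "mean_auc": cv.mean_auc,
                "sd_auc": cv.sd_auc,
                "n_failed": cv.n_failed,
                "per_repeat_auc": cv.per_repeat_auc,
            }
            | stamp,
            outdir / name,
        )

    boot = bootstrap_panel_ci(
        table,
        list(best.marker_names),
        draws=config.panel_bootstrap_draws,
        level=config.ci_level,
        seed=config.stage_seed("panel_bootstrap"),
    )
    cio.write_json(
        {
            "auc": boot.auc,
            "auc_ci": list(boot.auc_ci),
            "youden": dataclasses.asdict(boot.youden),
            "youden_j_ci": list(boot.youden_j_ci),
            "draws": boot.draws,
            "n_redrawn": boot.n_redrawn,
        }
        | stamp,
        outdir / "panel_bootstrap.json",
    )

    projection = pca_project(standardize_features(table))
    pd.DataFrame(
        {
            ID_COLUMN: table[ID_COLUMN],
            GRADE_COLUMN: labels,
            "pc1": projection.scores[:, 0],
            "pc2": projection.scores[:, 1],
        }
    ).to_csv(outdir / "pca_scores.csv", index=False)
    separation = class_separation(projection)
    if make_plots:
        _scatter_plot(projection, outdir / "pca_scores.png")

    summary = {
        "n_subjects": int(len(table)),
        "n_markers": int(len(table.columns) - 2),
        "candidates": candidates,
        "best_marker": stats[0].name,
        "best_marker_auc": stats[0].auc,
        "panel_markers": list(best.marker_names),
        "panel_aic": best.aic,
        "resubstitution_auc": resub_auc,
        "cv1_mean_auc": cv1.mean_auc,
        "cv1_sd_auc": cv1.sd_auc,
        "cv2_mean_auc": cv2.mean_auc,
        "cv2_sd_auc": cv2.sd_auc,
        "bootstrap_auc_ci": list(boot.auc_ci),
        "pca_class_separation": separation,
        "pca_explained": projection.explained_variance_fractions,
    } | stamp
    cio.write_json(summary, outdir / "summary.json")
    return summary


def _scatter_plot(projection, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for value, label, color in ((1, "HG", "tab:red"), (0, "LG", "tab:blue")):
        sel = projection.labels == value
        ax.scatter(projection.scores[sel, 0], projection.scores[sel, 1], label=label, c=color, s=24)
    frac = projection.explained_variance_fractions
    ax.set_xlabel(f"PC1 ({100 * frac[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * frac[1]:.0f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
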