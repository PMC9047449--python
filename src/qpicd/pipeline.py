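"""End-to-end orchestration: simulate -> segment -> track -> extract ->
fit -> screen/classify -> report.

The pipeline is a pure function of ``(config, seed)``: reruns are
byte-identical (no timestamps are written anywhere).  Cells are processed
one movie at a time so arbitrarily large cohorts stream through constant
memory; raw image stacks are only written to disk on request.
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
import yaml

from . import __version__
from .classify import (
    THREE_CLASS_COLUMNS,
    build_parameter_table,
    lda_project,
    ranksum_screen,
    train_eval_svm,
    two_class_death_classifier,
)
from .dynamics import fit_cohort
from .features import extract_feature_table
from .segment import build_tracks, segment_stack
from .synthetic import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "theoretical_resolution", "run_pipeline", "analyze_stack"]


def theoretical_resolution(wavelength: float, numerical_aperture: float) -> float:
    """Lateral resolution of a coherent imaging system, ``0.82 lambda / NA``.

    Both the wavelength and the returned resolution are in micrometres.
    """
    if not wavelength > 0:
        raise ValueError("wavelength must be positive")
    if not 0 < numerical_aperture <= 1.5:
        raise ValueError("numerical aperture must lie in (0, 1.5]")
    return 0.82 * wavelength / numerical_aperture


@dataclass
class PipelineConfig:
    """All knobs of one reproducible run.

    Physical defaults match the acquisition the package models: 0.48 um
    pixels, 532 nm illumination, one frame every 6 min; analysis defaults
    are a 13-point window, R^2 threshold 0.7 and a 2 h final-fit range.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    window: int = 13
    r2_threshold: float = 0.7
    t_range_h: float = 2.0
    min_area_px: int = 50
    marker_min_distance: int = 10
    n_splits: int = 500
    seed: int = 0
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("window length must be odd and >= 5")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("R^2 threshold must lie in (0, 1]")
        if self.t_range_h < 0 or self.min_area_px < 0:
            raise ValueError("negative analysis parameter")
        for name in ("pixel_size", "wavelength", "interval_min", "duration_h"):
            if getattr(self.cohort, name) <= 0:
                raise ValueError(f"cohort.{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["grid_shape"] = list(self.cohort.grid_shape)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        cohort._normalize()
        return cls(cohort=cohort, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def analyze_stack(
    stack,
    cell_id: int,
    min_area_px: int = 50,
    marker_min_distance: int = 10,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Segment, track and feature-extract one movie.

    Returns the long-format feature table of the complete tracks (border
    touchers excluded by default); the best (largest) complete track is
    relabelled with ``cell_id`` so single-cell movies map one movie to one
    cell.  An empty frame means segmentation found no complete track.
    """
    labels = segment_stack(stack, min_area=min_area_px, marker_min_distance=marker_min_distance)
    tracks = build_tracks(labels)
    candidates = [
        t for t in tracks
        if t.complete(len(stack)) and not (exclude_border and t.touches_border)
    ]
    if not candidates:
        return pd.DataFrame()
    candidates.sort(key=lambda t: -np.mean([a for _, _, a in t.points]))
    best = candidates[0]
    best.track_id = cell_id
    return extract_feature_table(stack, labels, [best])


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the whole analysis and write all artifacts under ``outdir``.

    Layout: ``raw/`` (ground truth, optionally image stacks), ``masks/``
    (optional label maps), ``features/``, ``fits/``, ``reports/`` and a
    ``manifest.json`` recording the config hash, package version and
    per-stage row counts.  Returns the manifest dict.
    """
    out = Path(outdir)
    for sub in ("raw", "masks", "features", "fits", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "qpicd_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
    }
    cfg = config.cohort

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("simulate")
        # draw the cohort recipes; each movie is rendered lazily below so
        # memory stays flat regardless of cohort size
        cells, truth = simulate_cohort(seed=config.seed, config=cfg, render=False)
        truth.to_csv(out / "raw" / "ground_truth.csv", index=False)
        manifest["stages"]["simulate"] = {"n_cells": len(cells)}
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        _stage("segment+track+extract")
        from .synthetic import simulate_cell

        tables = []
        n_lost = 0
        for cell in cells:
            sim = simulate_cell(cell.cell_id, cell.spec, cfg, render=True)
            if config.write_images:
                from .core import write_label_tiff

                sim.stack.write_tiff(out / "raw" / f"cell_{cell.cell_id:04d}.tif")
                write_label_tiff(
                    out / "masks" / f"cell_{cell.cell_id:04d}_truth.tif",
                    [m.astype(np.uint16) for m in sim.cell_masks],
                )
            table = analyze_stack(
                sim.stack,
                cell.cell_id,
                min_area_px=config.min_area_px,
                marker_min_distance=config.marker_min_distance,
            )
            if table.empty:
                n_lost += 1
            else:
                tables.append(table)
        features = (
            pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        )
        features.to_csv(out / "features" / "features.csv", index=False)
        manifest["stages"]["extract"] = {
            "n_rows": int(len(features)),
            "n_cells_analyzed": len(tables),
            "n_cells_lost": n_lost,
        }
        logger.info("extracted %d cells (%d lost)", len(tables), n_lost)
    except Exception as exc:  # noqa: BLE001
        raise StageError("extract", exc) from exc

    try:
        _stage("fit")
        fits, records = fit_cohort(
            features,
            window=config.window,
            threshold=config.r2_threshold,
            t_range=config.t_range_h,
        )
        fits.to_csv(out / "fits" / "fits.csv", index=False)
        summary = {
            str(r.track_id): {
                "transition_time_h": r.transition_time,
                "n_sigmoidal": r.n_sigmoidal,
            }
            for r in records
        }
        (out / "fits" / "cells.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
        n_with_t = sum(r.transitioning for r in records)
        manifest["stages"]["fit"] = {
            "n_cells": len(records),
            "n_with_transition": int(n_with_t),
        }
        logger.info("fitted %d cells, %d with a transition", len(records), n_with_t)
    except Exception as exc:  # noqa: BLE001
        raise StageError("fit", exc) from exc

    try:
        _stage("screen")
        params = build_parameter_table(fits, truth)
        params.to_csv(out / "features" / "parameters.csv", index=False)
        screen = ranksum_screen(params)
        screen.to_csv(out / "reports" / "significance.csv", index=False)
        manifest["stages"]["screen"] = {"n_columns": int(len(screen))}
    except Exception as exc:  # noqa: BLE001
        raise StageError("screen", exc) from exc

    try:
        _stage("classify")
        X = params[list(THREE_CLASS_COLUMNS)].to_numpy(dtype=float)
        y = params["class_label"].to_numpy()
        report3 = train_eval_svm(
            X, y, n_splits=config.n_splits, seed=config.seed,
            columns=list(THREE_CLASS_COLUMNS),
        )
        report2 = two_class_death_classifier(
            params, n_splits=config.n_splits, seed=config.seed
        )
        reports = {
            "three_class": report3.to_dict(),
            "normal_vs_dead_accuracy": report3.collapsed_accuracy(
                {"apoptotic": "dead", "necrotic": "dead"}
            ),
            "two_class_death": report2.to_dict(),
        }
        (out / "reports" / "classification.json").write_text(
            json.dumps(reports, indent=1, sort_keys=True)
        )
        coords, loadings = lda_project(X, y)
        lda_df = pd.DataFrame(
            coords, columns=[f"ld{i+1}" for i in range(coords.shape[1])]
        )
        lda_df.insert(0, "track_id", params["track_id"].to_numpy())
        lda_df["class_label"] = y
        lda_df["svm_error_rate"] = report3.per_cell_error_rate
        lda_df.to_csv(out / "reports" / "lda.csv", index=False)
        manifest["stages"]["classify"] = {
            "three_class_accuracy": report3.overall_accuracy,
            "two_class_accuracy": report2.overall_accuracy,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    _stage("report")
    manifest["stages"]["report"] = {"n_stage_outputs": 6}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
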