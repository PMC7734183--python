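"""End-to-end driver: grid -> layers -> multiplex -> features -> CV -> assessment,
swept over patch scales, all reproducible from one seed."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .assess import AssessmentResult, assess_selection
from .classify import CVConfig, CVSummary, run_cv
from .features import FeatureMatrix, build_feature_matrix, filter_features
from .grid import PatchGrid, make_grid
from .io import LabelVolume
from .network import assemble_multiplex, build_layer

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ScaleResult", "run_single_scale", "run_scale_sweep", "sweep_table"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, with the method's canonical defaults."""

    scales: tuple[int, ...] = defaults.SCALES
    threshold: float = defaults.EDGE_THRESHOLD
    brain_fraction_min: float = defaults.BRAIN_FRACTION_MIN
    corr_filter: float = defaults.CORR_FILTER
    rounds: int = defaults.CV_ROUNDS
    n_trees: int = defaults.N_TREES
    train_fraction: float = defaults.TRAIN_FRACTION
    importance_quantile: float = defaults.IMPORTANCE_QUANTILE
    alpha: float = defaults.ALPHA
    p0: float = defaults.NULL_SELECTION_P0
    region_min_fraction: float = defaults.REGION_MIN_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "threshold": 0 <= self.threshold <= 1,
            "brain_fraction_min": 0 <= self.brain_fraction_min <= 1,
            "corr_filter": 0 < self.corr_filter <= 1,
            "train_fraction": 0 < self.train_fraction < 1,
            "importance_quantile": 0 < self.importance_quantile < 1,
            "alpha": 0 < self.alpha < 1,
            "p0": 0 < self.p0 < 1,
            "region_min_fraction": 0 <= self.region_min_fraction < 1,
            "rounds": self.rounds >= 1,
            "n_trees": self.n_trees >= 1,
            "scales": len(self.scales) > 0 and all(v >= 1 for v in self.scales),
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid config field(s): {', '.join(bad)}")

    def cv_config(self) -> CVConfig:
        return CVConfig(rounds=self.rounds, train_fraction=self.train_fraction,
                        n_trees=self.n_trees, importance_quantile=self.importance_quantile,
                        seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(bad))}")
        if "scales" in d:
            d = {**d, "scales": tuple(int(v) for v in d["scales"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ScaleResult:
    scale: int
    grid: PatchGrid
    features: FeatureMatrix
    cv: CVSummary
    assessment: AssessmentResult


def run_single_scale(volumes: list[np.ndarray], labels: np.ndarray, mask: np.ndarray,
                     scale: int, config: PipelineConfig, subject_ids: list[str] | None = None,
                     label_volume: LabelVolume | None = None) -> ScaleResult:
    """Run the whole method at one patch volume ``scale`` (in voxels)."""
    grid = make_grid(mask.shape, scale, mask, config.brain_fraction_min)
    if grid.n_nodes < 2:
        raise ValueError(f"scale {scale}: fewer than 2 valid patches")
    ids = subject_ids or [f"sub-{i:03d}" for i in range(len(volumes))]
    log.info("scale %d: %d nodes (%d boxes), threshold %.2f", scale, grid.n_nodes, grid.n_boxes, config.threshold)
    layers = [build_layer(v, grid, sid, config.threshold) for v, sid in zip(volumes, ids)]
    multiplex = assemble_multiplex(layers)
    fm = filter_features(build_feature_matrix(multiplex), config.corr_filter)
    cv = run_cv(fm, labels, config.cv_config())
    assessment = assess_selection(cv.selection_counts, config.rounds, grid.n_nodes,
                                  config.alpha, config.p0, grid, label_volume,
                                  config.region_min_fraction)
    return ScaleResult(scale=scale, grid=grid, features=fm, cv=cv, assessment=assessment)


def run_scale_sweep(volumes: list[np.ndarray], labels: np.ndarray, mask: np.ndarray,
                    config: PipelineConfig, subject_ids: list[str] | None = None,
                    label_volume: LabelVolume | None = None) -> dict[int, ScaleResult]:
    """Run every scale in ``config.scales``; unusable scales are skipped with a warning."""
    out: dict[int, ScaleResult] = {}
    for scale in config.scales:
        try:
            out[scale] = run_single_scale(volumes, labels, mask, scale, config, subject_ids, label_volume)
        except ValueError as exc:
            log.warning("scale %d skipped: %s", scale, exc)
    return out


def sweep_table(results: dict[int, ScaleResult]) -> pd.DataFrame:
    """Cross-scale summary: one row per non-skipped scale."""
    rows = []
    for scale, r in sorted(results.items()):
        row = {"scale": scale, "n_nodes": r.grid.n_nodes}
        for m in ("accuracy", "specificity", "sensitivity", "auc"):
            row[f"{m}_mean"] = r.cv.metrics_mean[m]
            row[f"{m}_sd"] = r.cv.metrics_sd[m]
        row["wilson_lo"], row["wilson_hi"] = r.cv.wilson_ci
        row["n_significant_features"] = int(r.assessment.table["significant"].sum())
        rows.append(row)
    return pd.DataFrame(rows)
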