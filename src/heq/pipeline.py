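"""End-to-end orchestration: segment -> quantify -> features -> CV -> stats.

A run is driven by a manifest CSV (patient_id, slice_id, score, image_path,
mask_path) and a serializable :class:`RunConfig`; every numeric artifact in
the run directory is regenerable from manifest + config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .core import ThresholdGrid, quantify_slice
from .features import feature_frame
from .prediction import FeatureCohort, default_config_grid, grid_search
from .segmentation import segment_lungs
from .stats import ContingencyTable, accuracy, weighted_kappa

log = logging.getLogger("heq")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    manifest: str
    out_dir: str
    kind: str = "heq"
    lower_hu: int = -1000
    upper_hu: int = -700
    step_hu: int = 5
    trees: tuple[int, ...] = (10, 100, 1000)
    fractions: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    seed: int = 0
    log_level: str = "INFO"

    def grid(self) -> ThresholdGrid:
        return ThresholdGrid(self.lower_hu, self.upper_hu, self.step_hu)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _load_and_quantify(config: RunConfig):
    manifest = hio.read_manifest(config.manifest)
    base = Path(config.manifest).parent
    curves, scores = [], {}
    for row in manifest.itertuples():
        img_path = base / row.image_path
        if not img_path.exists():
            raise PipelineError(
                f"quantify: slice {row.slice_id}: missing image {img_path}"
            )
        ct = hio.read_slice(
            img_path, patient_id=str(row.patient_id), slice_id=str(row.slice_id)
        )
        try:
            if isinstance(row.mask_path, str) and row.mask_path:
                from .segmentation import load_mask

                mask = load_mask(base / row.mask_path, ct)
            else:
                mask = segment_lungs(ct)
            curves.append(quantify_slice(ct, mask, config.grid()))
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(
                f"quantify: slice {row.slice_id}: {exc}"
            ) from exc
        scores[str(row.slice_id)] = int(row.score)
    return curves, scores


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory.

    Writes curves.csv, features.csv, cv.json, stats.json, config.json and a
    log file; idempotent for a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        (out / "config.json").write_text(config.to_json())

        log.info("quantifying slices from %s", config.manifest)
        curves, scores = _load_and_quantify(config)
        hio.write_curves(curves, out / "curves.csv")

        log.info("building %s features", config.kind)
        df = feature_frame(curves, config.grid(), config.kind, scores)
        df.to_csv(out / "features.csv", index=False)

        log.info("grid-searching %d x %d configs under LOPO CV",
                 len(config.trees), len(config.fractions))
        cohort = FeatureCohort.from_frame(df)
        configs = [
            c
            for c in default_config_grid(config.seed)
            if c.n_trees in config.trees
            and any(np.isclose(c.feature_fraction, f) for f in config.fractions)
        ]
        best, all_results = grid_search(cohort, configs)
        cv_payload = {
            "best": {
                "n_trees": best.config.n_trees,
                "feature_fraction": best.config.feature_fraction,
                "accuracy": best.accuracy,
            },
            "all": [
                {
                    "n_trees": r.config.n_trees,
                    "feature_fraction": r.config.feature_fraction,
                    "accuracy": r.accuracy,
                }
                for r in all_results
            ],
            "predictions": [dataclasses.asdict(r) for r in best.records],
        }
        (out / "cv.json").write_text(json.dumps(cv_payload, indent=2))

        table = ContingencyTable.from_pairs(
            best.true_scores(), best.predicted_scores()
        )
        stats_payload = {
            "accuracy": accuracy(table),
            "weighted_kappa": weighted_kappa(table),
            "contingency": table.counts.tolist(),
        }
        (out / "stats.json").write_text(json.dumps(stats_payload, indent=2))
        log.info("done: accuracy=%.3f", stats_payload["accuracy"])
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def write_cohort(cohort, out_dir) -> Path:
    """Materialize a synthetic cohort to disk with its manifest CSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    rows = []
    for s in cohort.slices:
        img = f"images/{s.ct.slice_id}.nii.gz"
        msk = f"masks/{s.ct.slice_id}.nii.gz"
        hio.write_slice(s.ct, out / img)
        hio.write_mask(s.mask, out / msk)
        rows.append(
            {
                "patient_id": s.ct.patient_id,
                "slice_id": s.ct.slice_id,
                "score": s.score,
                "image_path": img,
                "mask_path": msk,
            }
        )
    manifest = out / "manifest.csv"
    hio.write_manifest(pd.DataFrame(rows), manifest)
    return manifest
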