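"""End-to-end orchestration: simulate -> score -> extract -> select/model -> stats.

``run_all`` executes the full workflow into an output directory with a
JSON manifest recording seeds, parameters and per-stage outputs.  Each
stage writes a ``_complete`` marker; re-running with the same config
skips completed stages (delete a stage directory to recompute from
there) and reproduces all CSV outputs bit-identically.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .cohort import generate_plan, simulate_cohort, synthesize_image
from .features import ExtractionConfig, extract_dosiomics, extract_radiomics
from .metrics import SSIMParams, score_pair, ssim
from .modeling import direction_analysis, scenario_compare
from .preprocess import standardize
from .types import CohortProtocol, MeasurementRecord

__all__ = ["RunConfig", "build_metric_table", "build_feature_table", "run_all"]


@dataclass
class RunConfig:
    """Master configuration for a full reproducible run."""

    protocol: CohortProtocol = field(default_factory=CohortProtocol)
    grid_n: int = 45
    threshold_fraction: float = 0.70
    ssim_params: SSIMParams = field(default_factory=SSIMParams)
    gamma_modes: tuple[str, ...] = ("rd", "ad")
    extraction_spacing_mm: float = 2.0
    dose_bin_width: float = 1.0
    image_bin_width: float = 25.0
    select_k: int = 17
    floor_frac: float = 0.01
    cv_folds: int = 10
    train_fraction: float = 0.70
    seed: int = 0
    compute_gamma: bool = True

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        tag = zlib.crc32(stage.encode()) % (2**31)
        h = np.random.SeedSequence([self.seed, tag])
        return int(h.generate_state(1)[0] % (2**31 - 1))


def _record_rows(records: Sequence[MeasurementRecord]) -> list[dict]:
    rows = []
    for rec in records:
        labels = sorted(rec.rotation.direction_labels)
        rows.append(
            {
                "plan_id": rec.plan_id,
                "stage": rec.stage,
                "pitch_deg": rec.rotation.pitch_deg,
                "roll_deg": rec.rotation.roll_deg,
                "yaw_deg": rec.rotation.yaw_deg,
                "angle_total_deg": rec.rotation.total_deg,
                "n_directions": rec.rotation.n_directions,
                "direction_label": labels[0] if len(labels) == 1 else "+".join(labels),
            }
        )
    return rows


def build_metric_table(
    records: Sequence[MeasurementRecord],
    grid_n: int = 45,
    threshold_fraction: float = 0.70,
    ssim_params: Optional[SSIMParams] = None,
    compute_gamma: bool = True,
    gamma_modes: tuple[str, ...] = ("rd", "ad"),
) -> pd.DataFrame:
    """Standardize every pair and score it; one row per measurement record."""
    rows = _record_rows(records)
    for row, rec in zip(rows, records):
        ref = standardize(rec.reference_plane, n=grid_n, threshold_fraction=threshold_fraction)
        ev = standardize(rec.perturbed_plane, n=grid_n, threshold_fraction=threshold_fraction)
        if compute_gamma:
            mrec = score_pair(
                ref,
                ev,
                ssim_params=ssim_params,
                modes=gamma_modes,
                delta_v100=rec.delta_v100,
                angle_total_deg=rec.rotation.total_deg,
                n_directions=rec.rotation.n_directions,
            )
            row["ssim"] = mrec.ssim
            for k, v in mrec.gamma_pass.items():
                row[f"gamma_{k}"] = v
            for k, v in mrec.dd_pass.items():
                row[f"dd_{k}"] = v
        else:
            row["ssim"] = ssim(ref, ev, ssim_params)[0]
        if rec.delta_v100 is not None:
            row["delta_v100"] = rec.delta_v100
    return pd.DataFrame(rows)


def build_feature_table(
    protocol: CohortProtocol,
    extraction_spacing_mm: float = 2.0,
    dose_bin_width: float = 1.0,
    image_bin_width: float = 25.0,
) -> pd.DataFrame:
    """Per-plan radiomic + dosiomic feature rows (keyed by ``plan_id``).

    Features come from the planned (reference) dose volume and a
    synthetic phantom-image companion; they are constant across a plan's
    rotated measurements, mirroring a planning-time feature workflow.
    """
    master = np.random.default_rng(protocol.seed)
    rows = []
    dose_cfg = ExtractionConfig.for_dose(
        resample_spacing_mm=extraction_spacing_mm, bin_width=dose_bin_width
    )
    img_cfg = ExtractionConfig.for_images(
        resample_spacing_mm=extraction_spacing_mm, bin_width=image_bin_width
    )
    for p in range(protocol.n_plans):
        plan_seed = int(master.integers(2**31 - 1))  # same stream layout as simulate_cohort
        volume, mask = generate_plan(protocol.plan_spec, seed=plan_seed)
        image = synthesize_image(mask, volume.spacing, seed=plan_seed + 7)
        rad = extract_radiomics(image, mask.grid, img_cfg, spacing_mm=float(volume.spacing[0]))
        dos = extract_dosiomics(volume, config=dose_cfg)
        row = {"plan_id": f"plan{p:03d}"}
        row.update(rad.as_dict())
        row.update(dos.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_dir(out: Path, name: str) -> Path:
    d = out / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _done(stage_dir: Path) -> bool:
    return (stage_dir / "_complete").exists()


def _mark(stage_dir: Path) -> None:
    (stage_dir / "_complete").write_text("ok\n")


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline into ``out_dir`` and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_seed": config.seed, "stages": {}, "started": time.time()}

    protocol = config.protocol
    records = None

    # --- simulate + metrics ------------------------------------------------
    d_metrics = _stage_dir(out, "metrics")
    metrics_csv = d_metrics / "metric_table.csv"
    if not _done(d_metrics):
        t0 = time.time()
        records = simulate_cohort(protocol)
        table = build_metric_table(
            records,
            grid_n=config.grid_n,
            threshold_fraction=config.threshold_fraction,
            ssim_params=config.ssim_params,
            compute_gamma=config.compute_gamma,
            gamma_modes=config.gamma_modes,
        )
        table.to_csv(metrics_csv, index=False)
        _mark(d_metrics)
        manifest["stages"]["metrics"] = {"seconds": time.time() - t0, "rows": len(table)}
    table = pd.read_csv(metrics_csv)
    manifest["stages"].setdefault("metrics", {})["path"] = str(metrics_csv)

    # --- features ----------------------------------------------------------
    d_feat = _stage_dir(out, "features")
    feat_csv = d_feat / "feature_table.csv"
    if not _done(d_feat):
        t0 = time.time()
        feats = build_feature_table(
            protocol,
            extraction_spacing_mm=config.extraction_spacing_mm,
            dose_bin_width=config.dose_bin_width,
            image_bin_width=config.image_bin_width,
        )
        rio.write_feature_table(feats, feat_csv)
        _mark(d_feat)
        manifest["stages"]["features"] = {"seconds": time.time() - t0, "columns": feats.shape[1]}
    feats = rio.read_feature_table(feat_csv)
    manifest["stages"].setdefault("features", {})["path"] = str(feat_csv)

    # --- modeling ----------------------------------------------------------
    d_model = _stage_dir(out, "model")
    model_json = d_model / "scenario_reports.json"
    if not _done(d_model):
        t0 = time.time()
        merged = table.merge(feats, on="plan_id", how="left")
        reports = scenario_compare(
            merged,
            k=config.select_k,
            floor_frac=config.floor_frac,
            fraction=config.train_fraction,
            cv_folds=config.cv_folds,
            seed=config.stage_seed("model"),
        )
        payload = {
            name: {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(rep).items()}
            for name, rep in reports.items()
            if not name.startswith("_")
        }
        payload["selected_features"] = reports["_selection"].retained  # type: ignore[union-attr]
        model_json.write_text(json.dumps(payload, indent=1))
        _mark(d_model)
        manifest["stages"]["model"] = {"seconds": time.time() - t0}
    manifest["stages"].setdefault("model", {})["path"] = str(model_json)

    # --- direction statistics ---------------------------------------------
    d_stats = _stage_dir(out, "stats")
    stats_csv = d_stats / "direction_correlations.csv"
    if not _done(d_stats):
        t0 = time.time()
        pass_col = "gamma_rd_2%/2mm" if "gamma_rd_2%/2mm" in table.columns else None
        stats_table = direction_analysis(table, pass_col=pass_col)
        stats_table.to_csv(stats_csv, index=False)
        _mark(d_stats)
        manifest["stages"]["stats"] = {"seconds": time.time() - t0}
    manifest["stages"].setdefault("stats", {})["path"] = str(stats_csv)

    manifest["finished"] = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
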