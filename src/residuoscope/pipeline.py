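"""End-to-end virtual experiment: generation -> calibration -> thresholding
-> classification -> (optional) guided resection -> survival analysis.

Every stage draws its randomness from seeds spawned off the single
experiment seed, so a rerun with the same config is bit-identical. The
summary JSON and every table carry the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionSpec, write_raw_tiff, write_mask_tiff
from .calibration import normalize_by_exposure
from .quantify import (
    DEFAULT_FRACTION,
    DEFAULT_MIN_CLUSTER_PX,
    calibrate_threshold,
    classify_bed,
    full_frame_mask,
)
from .resect import run_guided_resection, score_detection
from .survival import hazard_ratio, km_curve_frame, km_estimator
from .synthetic import ARM_NEGATIVE, ARM_POSITIVE, make_tumor_bed_pair

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]

log = logging.getLogger("residuoscope")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class ExperimentConfig:
    # acquisition
    pixel_pitch_um: float = 6.5
    frame_shape: tuple[int, int] = (96, 128)
    exposure_time_ms: float = 100.0
    read_noise_sd: float = 2.0
    dark_offset: float = 100.0
    # scene
    n_subjects: int = 20
    residual_prevalence: float = 0.5
    tumor_rate: float = 12000.0
    muscle_rate: float = 1000.0
    cluster_rate: float | None = None  # default: tumor_rate
    cluster_diameter_um: float = 40.0
    clusters_per_positive: int = 1
    heterogeneity_cv: float = 0.1
    noise: bool = True
    # classification
    threshold_fraction: float = DEFAULT_FRACTION
    min_cluster_px: int = DEFAULT_MIN_CLUSTER_PX
    # resection
    resect: bool = False
    max_steps: int = 4
    margin_px: int = 2
    # outcome model
    baseline_hazard: float = 0.05  # events/month in truly-negative beds
    true_hazard_ratio: float = 4.0
    followup_max: float = 12.0
    # bookkeeping
    seed: int = 0
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.residual_prevalence <= 1:
            raise ValueError("residual_prevalence must be in [0, 1]")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.true_hazard_ratio <= 0:
            raise ValueError("true_hazard_ratio must be > 0")
        object.__setattr__(self, "frame_shape", tuple(int(v) for v in self.frame_shape))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def acquisition_spec(self) -> AcquisitionSpec:
        return AcquisitionSpec(
            pixel_pitch_um=self.pixel_pitch_um,
            frame_shape=self.frame_shape,
            exposure_time_ms=self.exposure_time_ms,
            read_noise_sd=self.read_noise_sd,
            dark_offset=self.dark_offset,
        )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return ExperimentConfig.from_dict(payload)


def run_experiment(config: ExperimentConfig, out_dir) -> dict[str, Any]:
    """Run the virtual experiment and write its artifacts under ``out_dir``.

    Per subject: a tumor/muscle/bed phantom is generated (residual clusters
    present with the configured prevalence), the 80%-of-tumor-minimum
    threshold is calibrated on the tumor image, the bed is classified and
    optionally resected until clear, and a recurrence time is drawn with a
    hazard elevated by ``true_hazard_ratio`` for subjects whose final bed
    truly harbours residual cells. Arms for the survival analysis follow the
    image-based classification, mirroring an intraoperative diagnosis.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.acquisition_spec()
    cluster_rate = config.cluster_rate if config.cluster_rate is not None else config.tumor_rate
    cfg_hash = config.config_hash()
    ss = np.random.SeedSequence(config.seed)
    subj_seeds = ss.spawn(config.n_subjects)
    fov_um = (spec.frame_shape[0] * spec.pixel_pitch_um, spec.frame_shape[1] * spec.pixel_pitch_um)

    rows = []
    thresholds = []
    for i, sseq in enumerate(subj_seeds):
        subject_id = f"S{i:04d}"
        rng = np.random.default_rng(sseq)
        try:
            has_residual = bool(rng.random() < config.residual_prevalence)
            clusters = []
            if has_residual:
                margin = config.cluster_diameter_um
                for _ in range(config.clusters_per_positive):
                    clusters.append(
                        (
                            float(rng.uniform(margin, fov_um[0] - margin)),
                            float(rng.uniform(margin, fov_um[1] - margin)),
                            config.cluster_diameter_um,
                            cluster_rate,
                        )
                    )
            tumor_raw, muscle_raw, bed_raw, scene = make_tumor_bed_pair(
                spec,
                config.tumor_rate,
                config.muscle_rate,
                clusters,
                heterogeneity_cv=config.heterogeneity_cv,
                noise=config.noise,
                seed=int(rng.integers(2**31)),
            )
            tumor = normalize_by_exposure(tumor_raw)
            bed = normalize_by_exposure(bed_raw)
            model = calibrate_threshold(
                tumor,
                full_frame_mask(tumor, "tumor"),
                fraction=config.threshold_fraction,
                subject_id=subject_id,
            )
            classification = classify_bed(bed, model, min_cluster_px=config.min_cluster_px)
            n_resections = 0
            final_residual_truth = has_residual
            if config.resect and classification.is_positive:
                trace = run_guided_resection(
                    scene, bed, model,
                    margin_px=config.margin_px,
                    max_steps=config.max_steps,
                    min_cluster_px=config.min_cluster_px,
                    rng=rng,
                )
                n_resections = trace.n_resections
                classification = trace.final_classification
                final_residual_truth = trace.residual_truth_pixels > 0
            arm = ARM_POSITIVE if classification.is_positive else ARM_NEGATIVE

            hazard = config.baseline_hazard * (
                config.true_hazard_ratio if final_residual_truth else 1.0
            )
            if hazard > 0:
                t = float(rng.exponential(1.0 / hazard))
            else:
                t = float("inf")
            event = int(t <= config.followup_max)
            t = min(t, config.followup_max)

            rows.append(
                {
                    "subject_id": subject_id,
                    "arm": arm,
                    "time_months": t,
                    "event": event,
                    "true_residual": int(has_residual),
                    "final_residual_truth": int(final_residual_truth),
                    "n_resections": n_resections,
                    "threshold_rate": model.threshold_rate,
                }
            )
            thresholds.append({"subject_id": subject_id, **model.to_dict()})
            if config.write_images:
                img_dir = out / "images" / subject_id
                img_dir.mkdir(parents=True, exist_ok=True)
                write_raw_tiff(img_dir / "tumor.tif", tumor_raw)
                write_raw_tiff(img_dir / "muscle.tif", muscle_raw)
                write_raw_tiff(img_dir / "bed.tif", bed_raw)
                write_mask_tiff(img_dir / "truth_mask.tif", scene.truth_mask)
        except Exception as exc:  # pragma: no cover - abort contract
            raise RuntimeError(f"experiment stage failed for subject {subject_id}: {exc}") from exc
        log.info("subject %s arm=%s resections=%d", subject_id, arm, n_resections)

    cohort = pd.DataFrame(rows)
    cohort_path = out / "cohort.csv"
    cohort[["subject_id", "arm", "time_months", "event"]].to_csv(cohort_path, index=False)
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2))

    neg = cohort[cohort.arm == ARM_NEGATIVE]
    pos = cohort[cohort.arm == ARM_POSITIVE]
    km_tables = {}
    for arm_name, sub in ((ARM_NEGATIVE, neg), (ARM_POSITIVE, pos)):
        if len(sub):
            curve = km_estimator(sub.time_months.to_numpy(), sub.event.to_numpy())
            frame = km_curve_frame(curve)
            frame.to_csv(out / f"km_{arm_name}.csv", index=False)
            km_tables[arm_name] = frame.to_dict(orient="list")

    hr_summary: dict[str, Any]
    if len(neg) and len(pos) and int(cohort.event.sum()) > 0:
        hr = hazard_ratio(
            neg.time_months.to_numpy(), neg.event.to_numpy(),
            pos.time_months.to_numpy(), pos.event.to_numpy(),
        )
        hr_summary = hr.to_dict()
    else:
        hr_summary = {
            "non_estimable": True,
            "reason": "one arm is empty or no events were observed",
        }

    detection = score_detection(
        [bool(r["arm"] == ARM_POSITIVE) for r in rows],
        [bool(r["true_residual"]) for r in rows],
    )
    summary = {
        "config_hash": cfg_hash,
        "config": config.to_dict(),
        "n_subjects": int(len(cohort)),
        "n_positive_arm": int(len(pos)),
        "n_negative_arm": int(len(neg)),
        "n_events": int(cohort.event.sum()),
        "mean_resections": float(cohort.n_resections.mean()),
        "hazard_ratio": hr_summary,
        "detection": detection.to_dict(),
        "km": km_tables,
        "files": {"cohort": cohort_path.name, "thresholds": "thresholds.json"},
    }
    (out / "summary.json").write_text(json.dumps(_round_floats(summary), indent=2, sort_keys=True))
    return summary


def _round_floats(obj, ndigits: int = 10):
    """Stabilize JSON output against last-bit float jitter."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else repr(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    return obj
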