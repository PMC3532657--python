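"""Iterative image-guided resection on phantom beds, plus detection scoring.

Each iteration classifies the current bed against the subject's threshold;
while positive, every supra-threshold component (dilated by a safety margin)
is "resected": its rates drop to the background and its truth pixels are
cleared. A reveal model may then expose the next pre-placed hidden layer of
clusters, emulating beds that stay positive over serial resections. The loop
ends at the first negative classification or at ``max_steps``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .acquisition import EmissionRateImage
from .quantify import (
    DEFAULT_MIN_CLUSTER_PX,
    BedClassification,
    ThresholdModel,
    classify_bed,
)
from .synthetic import PhantomScene, rasterize_disc

__all__ = [
    "ResectionStep",
    "ResectionTrace",
    "DetectionScore",
    "run_guided_resection",
    "score_detection",
]


@dataclass
class ResectionStep:
    index: int  # 1-based
    classification: BedClassification  # the positive call that triggered removal
    removed_mask: np.ndarray
    post_resection_bed: EmissionRateImage
    revealed_clusters: int = 0


@dataclass
class ResectionTrace:
    steps: list[ResectionStep]
    final_classification: BedClassification
    cleared: bool  # negative within max_steps
    residual_truth_pixels: int

    @property
    def n_resections(self) -> int:
        return len(self.steps)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_resections": self.n_resections,
            "cleared": self.cleared,
            "residual_truth_pixels": self.residual_truth_pixels,
            "final_status": self.final_classification.status,
            "steps": [
                {
                    "index": s.index,
                    "status": s.classification.status,
                    "removed_px": int(s.removed_mask.sum()),
                    "revealed_clusters": s.revealed_clusters,
                }
                for s in self.steps
            ],
        }


def run_guided_resection(
    scene: PhantomScene,
    bed_img: EmissionRateImage,
    model: ThresholdModel,
    *,
    margin_px: int = 2,
    reveal_prob: float = 1.0,
    max_steps: int = 6,
    min_cluster_px: int = DEFAULT_MIN_CLUSTER_PX,
    rng: np.random.Generator | None = None,
) -> ResectionTrace:
    """Resect until the bed classifies negative or ``max_steps`` is reached.

    A bed still positive at ``max_steps`` is flagged (``cleared=False``),
    not raised. ``reveal_prob`` is the per-step probability that the next
    hidden layer of clusters surfaces after a removal.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    if rng is None:
        rng = np.random.default_rng()

    rates = bed_img.rates.copy()
    truth = scene.truth_mask.copy()
    hidden = [list(layer) for layer in scene.hidden_layers]
    selem = disk(margin_px) if margin_px > 0 else None
    steps: list[ResectionStep] = []

    def _classify(current_rates: np.ndarray) -> BedClassification:
        img = EmissionRateImage(rates=current_rates, provenance=dict(bed_img.provenance))
        return classify_bed(img, model, min_cluster_px=min_cluster_px,
                            pixel_pitch_um=scene.pixel_pitch_um)

    classification = _classify(rates)
    while classification.is_positive and len(steps) < max_steps:
        removal = classification.supra_threshold_mask
        if selem is not None:
            removal = binary_dilation(removal, structure=selem)
        rates = rates.copy()
        rates[removal] = scene.background_rate
        truth = truth & ~removal

        revealed = 0
        if hidden and float(rng.random()) < reveal_prob:
            layer = hidden.pop(0)
            rates = rates.copy()
            for obj in layer:
                d = rasterize_disc(rates.shape, obj.centroid_um, obj.diameter_um,
                                   scene.pixel_pitch_um)
                rates[d] = obj.rate
                if obj.rate > scene.background_rate:
                    truth |= d
            revealed = len(layer)

        post = EmissionRateImage(rates=rates, provenance=dict(bed_img.provenance))
        steps.append(
            ResectionStep(
                index=len(steps) + 1,
                classification=classification,
                removed_mask=removal,
                post_resection_bed=post,
                revealed_clusters=revealed,
            )
        )
        classification = _classify(rates)

    return ResectionTrace(
        steps=steps,
        final_classification=classification,
        cleared=not classification.is_positive,
        residual_truth_pixels=int(truth.sum()),
    )


@dataclass(frozen=True)
class DetectionScore:
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity_ci95: tuple[float, float]
    specificity_ci95: tuple[float, float]

    def to_dict(self) -> dict[str, Any]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity_ci95": list(self.sensitivity_ci95),
            "specificity_ci95": list(self.specificity_ci95),
        }


def _exact_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return (float(ci.low), float(ci.high))


def score_detection(
    predictions: Sequence[bool | BedClassification],
    truths: Sequence[bool],
) -> DetectionScore:
    """Sensitivity/specificity of bed calls against ground truth, with
    exact (Clopper-Pearson) 95% binomial intervals."""
    if len(predictions) == 0:
        raise ValueError("no classifications to score")
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must be paired lists of equal length")
    pred = np.array(
        [p.is_positive if isinstance(p, BedClassification) else bool(p) for p in predictions]
    )
    true = np.asarray([bool(t) for t in truths])
    tp = int(np.sum(pred & true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return DetectionScore(
        sensitivity=sens,
        specificity=spec,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity_ci95=_exact_ci(tp, tp + fn),
        specificity_ci95=_exact_ci(tn, tn + fp),
    )
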