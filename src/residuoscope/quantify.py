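"""ROI quantification, per-subject thresholding and tumor-bed classification.

The classification rule: the threshold is a fraction (default 0.8) of the
minimum emission rate observed over the excised-tumor ROI; any subsequent
bed image from the same subject is positive when a sufficiently large
connected region sits at or above that threshold. Because both sides of the
comparison are exposure-normalized rates, the call is independent of the
exposure time of the raw frames.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label

from .acquisition import EmissionRateImage

__all__ = [
    "RegionMask",
    "ThresholdModel",
    "BedClassification",
    "mean_region_rate",
    "tumor_to_muscle_ratio",
    "segment_tumor",
    "calibrate_threshold",
    "classify_bed",
    "display_transfer",
    "full_frame_mask",
    "mask_from_polygons",
]

DEFAULT_FRACTION = 0.8
DEFAULT_MIN_CLUSTER_PX = 4


@dataclass
class RegionMask:
    mask: np.ndarray
    label: str = "custom"  # tumor | muscle | bed | custom
    origin: str = "manual"  # manual | otsu | file

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) > 0
        if not self.mask.any():
            raise ValueError("region mask must contain at least one positive pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ThresholdModel:
    """Per-subject residual-fluorescence threshold with provenance."""

    threshold_rate: float
    fraction: float
    tumor_min_rate: float
    min_statistic: str
    subject_id: str | None = None
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if not math.isclose(self.threshold_rate, self.fraction * self.tumor_min_rate,
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("threshold_rate must equal fraction * tumor_min_rate")

    def to_dict(self) -> dict[str, Any]:
        return {
            "threshold_rate": self.threshold_rate,
            "fraction": self.fraction,
            "tumor_min_rate": self.tumor_min_rate,
            "min_statistic": self.min_statistic,
            "subject_id": self.subject_id,
            "frame_shape": list(self.frame_shape) if self.frame_shape else None,
        }


@dataclass
class BedClassification:
    status: str  # "positive" | "negative"
    supra_threshold_mask: np.ndarray
    supra_area_um2: float | None
    max_bed_rate: float
    threshold_rate: float
    min_cluster_px: int
    largest_component_px: int

    @property
    def is_positive(self) -> bool:
        return self.status == "positive"

    def to_dict(self) -> dict[str, Any]:
        return {
            "status": self.status,
            "supra_area_um2": self.supra_area_um2,
            "max_bed_rate": self.max_bed_rate,
            "threshold_rate": self.threshold_rate,
            "min_cluster_px": self.min_cluster_px,
            "largest_component_px": self.largest_component_px,
        }


def _check_roi(img: EmissionRateImage, roi: RegionMask) -> None:
    if roi.mask.shape != img.shape:
        raise ValueError(f"roi shape {roi.mask.shape} does not match image shape {img.shape}")


def mean_region_rate(img: EmissionRateImage, roi: RegionMask) -> float:
    """Arithmetic mean emission rate over the ROI."""
    _check_roi(img, roi)
    return float(img.rates[roi.mask].mean())


def tumor_to_muscle_ratio(
    tumor_img: EmissionRateImage,
    tumor_roi: RegionMask,
    muscle_img: EmissionRateImage,
    muscle_roi: RegionMask,
) -> float:
    """Ratio of mean tumor rate to mean muscle rate."""
    muscle = mean_region_rate(muscle_img, muscle_roi)
    if muscle <= 0:
        raise ValueError("muscle region has zero mean signal; ratio undefined")
    return mean_region_rate(tumor_img, tumor_roi) / muscle


def segment_tumor(img: EmissionRateImage) -> RegionMask:
    """Foreground mask from a global two-class (Otsu) threshold on the
    rates; only the largest 8-connected component is kept."""
    rates = img.rates
    if float(np.ptp(rates)) == 0.0:
        raise ValueError("image is constant; cannot segment a foreground")
    thresh = threshold_otsu(rates)
    fg = rates > thresh
    if not fg.any():
        raise ValueError("no foreground above the Otsu threshold")
    labels = label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = labels == int(sizes.argmax())
    return RegionMask(mask=keep, label="tumor", origin="otsu")


def calibrate_threshold(
    tumor_img: EmissionRateImage,
    tumor_roi: RegionMask,
    *,
    fraction: float = DEFAULT_FRACTION,
    min_statistic: str = "min",
    percentile: float = 1.0,
    median_filter_size: int = 3,
    subject_id: str | None = None,
) -> ThresholdModel:
    """Set the per-subject threshold at ``fraction`` of the tumor minimum.

    ``min_statistic="min"`` takes the literal minimum over the ROI after a
    small median filter (size ``median_filter_size``; 0 disables it) that
    rejects dead/cold pixels; ``"percentile"`` substitutes the given low
    percentile of the unfiltered ROI rates.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    _check_roi(tumor_img, tumor_roi)
    rates = tumor_img.rates
    if min_statistic == "min":
        if median_filter_size and median_filter_size > 1:
            rates = ndimage.median_filter(rates, size=median_filter_size)
        tumor_min = float(rates[tumor_roi.mask].min())
        stat = f"literal-min(median{median_filter_size})" if median_filter_size else "literal-min"
    elif min_statistic == "percentile":
        tumor_min = float(np.percentile(rates[tumor_roi.mask], percentile))
        stat = f"percentile({percentile:g})"
    else:
        raise ValueError("min_statistic must be 'min' or 'percentile'")
    return ThresholdModel(
        threshold_rate=fraction * tumor_min,
        fraction=fraction,
        tumor_min_rate=tumor_min,
        min_statistic=stat,
        subject_id=subject_id,
        frame_shape=tumor_img.shape,
    )


def classify_bed(
    bed_img: EmissionRateImage,
    model: ThresholdModel,
    *,
    min_cluster_px: int = DEFAULT_MIN_CLUSTER_PX,
    pixel_pitch_um: float | None = None,
) -> BedClassification:
    """Classify a tumor-bed image as positive/negative residual fluorescence.

    Positive iff some 8-connected component of ``rates >= threshold`` has at
    least ``min_cluster_px`` pixels.
    """
    if model.frame_shape is not None and tuple(model.frame_shape) != tuple(bed_img.shape):
        raise ValueError(
            f"bed frame {bed_img.shape} does not match the calibration frame "
            f"{tuple(model.frame_shape)}"
        )
    if min_cluster_px < 1:
        raise ValueError("min_cluster_px must be >= 1")
    supra = bed_img.rates >= model.threshold_rate
    largest = 0
    if supra.any():
        labels = label(supra, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        largest = int(sizes.max())
    status = "positive" if largest >= min_cluster_px else "negative"
    pitch = pixel_pitch_um if pixel_pitch_um is not None else bed_img.pixel_pitch_um
    area = float(supra.sum()) * pitch**2 if pitch else None
    return BedClassification(
        status=status,
        supra_threshold_mask=supra,
        supra_area_um2=area,
        max_bed_rate=float(bed_img.rates.max()),
        threshold_rate=model.threshold_rate,
        min_cluster_px=min_cluster_px,
        largest_component_px=largest,
    )


def display_transfer(
    tumor_img: EmissionRateImage,
    images: Sequence[EmissionRateImage] | None = None,
) -> list[np.ndarray]:
    """8-bit display rendering anchored to the tumor histogram.

    The linear map sending [tumor min, tumor max] to [0, 255] (values
    rounded half-to-even, then clipped) is applied identically to every
    image in ``images`` (default: just the tumor itself), so relative
    brightness across a subject's images is preserved.
    """
    tmin = float(tumor_img.rates.min())
    tmax = float(tumor_img.rates.max())
    if tmax <= tmin:
        raise ValueError("tumor image has zero dynamic range; display map undefined")
    if images is None:
        images = [tumor_img]
    scale = 255.0 / (tmax - tmin)
    out = []
    for img in images:
        mapped = np.clip(np.rint((img.rates - tmin) * scale), 0, 255)
        out.append(mapped.astype(np.uint8))
    return out


def full_frame_mask(img: EmissionRateImage, label_name: str = "custom") -> RegionMask:
    return RegionMask(mask=np.ones(img.shape, dtype=bool), label=label_name, origin="manual")


def mask_from_polygons(path, shape: tuple[int, int]) -> RegionMask:
    """Load a polygon-JSON ROI: ``{"label": ..., "polygons": [[[r, c], ...]]}``."""
    with open(path) as fh:
        payload = json.load(fh)
    mask = np.zeros(shape, dtype=bool)
    for poly in payload["polygons"]:
        arr = np.asarray(poly, dtype=float)
        rr, cc = draw_polygon(arr[:, 0], arr[:, 1], shape=shape)
        mask[rr, cc] = True
    return RegionMask(mask=mask, label=payload.get("label", "custom"), origin="file")
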