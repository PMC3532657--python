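"""Exposure normalization and device-linearity fits.

Raw counts are converted to a time-independent emission rate
(counts/second) by subtracting a background estimate and dividing by the
exposure time. Linearity of counts vs exposure and of emission rate vs
nominal source intensity are checked with ordinary least-squares fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max

from .acquisition import EmissionRateImage, RawImage

__all__ = [
    "LinearityFit",
    "normalize_by_exposure",
    "fit_exposure_linearity",
    "fit_intensity_linearity",
    "detect_spheres",
    "sphere_mean_counts",
    "sphere_rate_photometry",
]

SATURATION_FRACTION = 0.98  # of full scale; pixels above are flagged


@dataclass(frozen=True)
class LinearityFit:
    """Least-squares line y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a linearity fit needs at least 3 points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def normalize_by_exposure(
    img: RawImage,
    background: str | float = "auto",
) -> EmissionRateImage:
    """Convert raw counts to counts/second.

    ``background`` selects the background estimate subtracted before
    normalization:

    * ``"auto"`` — the ``dark_offset`` recorded in the image metadata if
      present, else the 1st-percentile fallback;
    * ``"percentile"`` — 1st percentile of the frame;
    * ``"none"`` — no subtraction;
    * a number — that constant, in counts.

    Rates are floored at zero. Pixels at or above 98% of full scale are
    flagged as saturated; if more than 1% of the frame is saturated a
    warning is recorded in the provenance (and emitted).
    """
    if img.exposure_time_ms is None or img.exposure_time_ms <= 0:
        raise ValueError("image has no positive exposure time")
    counts = img.pixels.astype(float)

    if isinstance(background, (int, float)) and not isinstance(background, bool):
        bg_value, bg_method = float(background), "constant"
    elif background == "auto":
        if "dark_offset" in img.metadata:
            bg_value, bg_method = float(img.metadata["dark_offset"]), "metadata-dark-offset"
        else:
            bg_value, bg_method = float(np.percentile(counts, 1)), "percentile-1"
    elif background == "percentile":
        bg_value, bg_method = float(np.percentile(counts, 1)), "percentile-1"
    elif background == "none":
        bg_value, bg_method = 0.0, "none"
    else:
        raise ValueError(f"unknown background method {background!r}")

    t_s = img.exposure_time_ms / 1000.0
    rates = np.clip((counts - bg_value) / t_s, 0.0, None)

    full_scale = 2**img.bit_depth - 1
    saturated = counts >= SATURATION_FRACTION * full_scale
    sat_frac = float(saturated.mean()) if counts.size else 0.0
    provenance = {
        "source": img.metadata.get("kind", "raw"),
        "exposure_time_ms": img.exposure_time_ms,
        "background_method": bg_method,
        "background_counts": bg_value,
        "saturated_fraction": sat_frac,
        "pixel_pitch_um": img.metadata.get("pixel_pitch_um"),
    }
    if sat_frac > 0.01:
        provenance["warning"] = f"{sat_frac:.1%} of pixels saturated"
        warnings.warn(provenance["warning"], stacklevel=2)
    return EmissionRateImage(rates=rates, provenance=provenance, saturated=saturated)


def _fit_line(xy: Sequence[tuple[float, float]], what: str) -> LinearityFit:
    pts = np.asarray([(float(x), float(y)) for x, y in xy], dtype=float)
    if len(pts) < 3:
        raise ValueError(f"need at least 3 {what} points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError(f"all {what} values identical; cannot fit a line")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ssr = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - ssr / sst)
    dof = len(pts) - 2
    return LinearityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(min(r2, 1.0)),
        residual_sd=math.sqrt(ssr / dof) if dof > 0 else 0.0,
        n_points=len(pts),
    )


def fit_exposure_linearity(points: Sequence[tuple[float, float]]) -> LinearityFit:
    """Fit mean sphere counts against exposure time (ms).

    For a linear detector the slope is the sphere flux in counts/ms and the
    intercept recovers the dark offset.
    """
    return _fit_line(points, "exposure")


def fit_intensity_linearity(points: Sequence[tuple[float, float]]) -> LinearityFit:
    """Fit measured emission rate against nominal relative intensity."""
    return _fit_line(points, "intensity")


def detect_spheres(
    img: RawImage | EmissionRateImage,
    n_spheres: int,
    *,
    min_separation_px: float = 6.0,
    smooth_sigma_px: float = 1.0,
) -> np.ndarray:
    """Locate bright spheres as local maxima of a lightly smoothed frame.

    Gaussian smoothing (rather than a median filter) is used so that
    spheres smaller than a pixel survive the pre-filter. Returns an
    ``(n, 2)`` array of (row, col) peak positions.
    """
    values = img.pixels.astype(float) if isinstance(img, RawImage) else img.rates
    smooth = ndimage.gaussian_filter(values, smooth_sigma_px)
    floor = float(np.percentile(smooth, 50))
    peaks = peak_local_max(
        smooth,
        min_distance=max(int(round(min_separation_px)), 1),
        threshold_abs=floor,
        num_peaks=n_spheres,
        exclude_border=False,
    )
    if len(peaks) < n_spheres:
        raise ValueError(f"found only {len(peaks)} of {n_spheres} expected spheres")
    return peaks


def sphere_mean_counts(
    img: RawImage,
    centers_px: np.ndarray,
    radius_px: float,
) -> float:
    """Mean raw counts over discs of ``radius_px + 1`` about each center,
    averaged across spheres (no background subtraction, so a noiseless
    series keeps the dark offset in its intercept)."""
    counts = img.pixels.astype(float)
    vals = []
    r = radius_px + 1.0
    for row, col in centers_px:
        patch, mask = _disc_patch(counts, (float(row), float(col)), r)
        vals.append(float(patch[mask].mean()))
    return float(np.mean(vals))


def sphere_rate_photometry(
    img: EmissionRateImage,
    centers_px: np.ndarray,
    radius_px: float,
) -> float:
    """Aperture photometry estimate of the per-sphere emission rate.

    Sums background-subtracted rates in a window extending 3 px beyond the
    sphere radius and divides by the sphere's area in pixels, which recovers
    the true rate even for sub-pixel spheres (flux conservation).
    """
    rates = img.rates
    # local background from an annulus well outside the aperture
    vals = []
    area = math.pi * max(radius_px, 1e-9) ** 2
    for row, col in centers_px:
        patch, mask = _disc_patch(rates, (float(row), float(col)), radius_px + 3.0)
        ann_patch, ann_mask = _disc_patch(rates, (float(row), float(col)), radius_px + 6.0)
        annulus = ann_patch[ann_mask].sum() - patch[mask].sum()
        n_ann = int(ann_mask.sum() - mask.sum())
        bg = annulus / n_ann if n_ann > 0 else 0.0
        vals.append((float(patch[mask].sum()) - bg * int(mask.sum())) / area)
    return float(np.mean(vals))


def _disc_patch(arr: np.ndarray, center: tuple[float, float], radius: float):
    r0 = max(int(math.floor(center[0] - radius)), 0)
    r1 = min(int(math.ceil(center[0] + radius)) + 1, arr.shape[0])
    c0 = max(int(math.floor(center[1] - radius)), 0)
    c1 = min(int(math.ceil(center[1] + radius)) + 1, arr.shape[1])
    patch = arr[r0:r1, c0:c1]
    rr = np.arange(r0, r1)[:, None] - center[0]
    cc = np.arange(c0, c1)[None, :] - center[1]
    mask = rr**2 + cc**2 <= radius**2
    return patch, mask
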