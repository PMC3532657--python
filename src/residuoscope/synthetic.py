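"""Seeded generators for every input the analysis pipeline consumes.

Four families of synthetic inputs:

* bar-pattern resolution targets (3-bar groups at calibrated spatial
  frequencies, optionally Gaussian-blurred) for contrast-transfer analysis;
* microsphere calibration series spanning exposure times and relative
  intensities, with a ground-truth table;
* tumor / muscle / tumor-bed scene triplets with ground-truth masks for the
  residual clusters stamped into the bed;
* two-arm recurrence cohorts under a proportional-hazards event model with
  administrative censoring.

Everything is deterministic given its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .acquisition import AcquisitionSpec, RawImage, expose

__all__ = [
    "BarGroup",
    "SceneObject",
    "PhantomScene",
    "CohortSpec",
    "ARM_NEGATIVE",
    "ARM_POSITIVE",
    "bar_target_shape",
    "make_bar_target",
    "make_microsphere_series",
    "make_tumor_bed_pair",
    "rasterize_disc",
    "simulate_cohort",
]

ARM_NEGATIVE = "residual_negative"
ARM_POSITIVE = "residual_positive"


# ---------------------------------------------------------------------------
# bar-pattern resolution targets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarGroup:
    """Annotation for one 3-bar group in a rendered resolution target.

    ``start_px`` is the sub-pixel coordinate (along the varying axis, in
    pixel units) of the leading edge of the first bright bar; one cycle is
    ``period_px`` wide with the bright bar in its first half.
    """

    frequency_cpmm: float
    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    period_px: float
    start_px: float
    n_bars: int
    axis: str  # "x": bars vary along columns; "y": along rows

    def to_dict(self) -> dict[str, Any]:
        return {
            "frequency_cpmm": self.frequency_cpmm,
            "bbox": list(self.bbox),
            "period_px": self.period_px,
            "start_px": self.start_px,
            "n_bars": self.n_bars,
            "axis": self.axis,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "BarGroup":
        return cls(
            frequency_cpmm=float(d["frequency_cpmm"]),
            bbox=tuple(int(v) for v in d["bbox"]),  # type: ignore[arg-type]
            period_px=float(d["period_px"]),
            start_px=float(d["start_px"]),
            n_bars=int(d["n_bars"]),
            axis=str(d["axis"]),
        )


def _blurred_bar_profile(
    n_cols: int,
    intervals: Sequence[tuple[float, float]],
    lo: float,
    hi: float,
    sigma_px: float,
) -> np.ndarray:
    """Exact pixel values of bright intervals under Gaussian blur.

    The scene is ``lo`` everywhere plus ``hi - lo`` on each bright interval.
    Convolving a step edge with a Gaussian gives a normal CDF, and the mean
    over a unit pixel has the closed-form antiderivative
    ``int Phi(u) du = u Phi(u) + phi(u)``; with ``sigma_px == 0`` the pixel
    value is the exact geometric coverage fraction. No sub-sampling, so
    rendered contrast carries no edge-quantization error.
    """
    x0 = np.arange(n_cols, dtype=float)
    x1 = x0 + 1.0
    frac = np.zeros(n_cols)
    if sigma_px == 0:
        for a, b in intervals:
            frac += np.clip(np.minimum(x1, b) - np.maximum(x0, a), 0.0, None)
    else:

        def antideriv(x: np.ndarray, edge: float) -> np.ndarray:
            u = (x - edge) / sigma_px
            return sigma_px * (u * norm.cdf(u) + norm.pdf(u))

        for a, b in intervals:
            frac += (antideriv(x1, a) - antideriv(x0, a)) - (antideriv(x1, b) - antideriv(x0, b))
    return lo + (hi - lo) * np.clip(frac, 0.0, 1.0)


def bar_target_shape(
    frequencies_cpmm: Sequence[float],
    pixel_pitch_um: float,
    *,
    band_px: int = 16,
    margin_px: int = 16,
) -> tuple[int, int]:
    """Frame shape large enough to hold one 3-bar group per frequency,
    stacked vertically with margins."""
    widest = max(3.0 * 1000.0 / (f * pixel_pitch_um) for f in frequencies_cpmm)
    rows = len(frequencies_cpmm) * (band_px + margin_px) + margin_px
    cols = int(math.ceil(widest)) + 2 * margin_px
    return (rows, cols)


def make_bar_target(
    spec: AcquisitionSpec,
    frequencies_cpmm: Sequence[float],
    *,
    blur_sigma_um: float = 0.0,
    contrast: float = 1.0,
    base_rate: float = 2000.0,
    orientation: str = "x",
    band_px: int = 16,
    margin_px: int = 16,
    noise: bool = False,
    seed: int | None = 0,
) -> tuple[RawImage, list[BarGroup]]:
    """Render a bar-pattern resolution target.

    Each requested spatial frequency becomes one group of 3 bright bars
    (square wave, bright bar = half the cycle). ``contrast`` sets the
    unblurred modulation: bright/dark emission rates are
    ``base_rate * (1 +/- contrast)``. The scene is blurred with a Gaussian of
    ``blur_sigma_um`` and integrated exactly over each pixel.
    """
    if not 0 < contrast <= 1:
        raise ValueError("contrast must be in (0, 1]")
    if blur_sigma_um < 0:
        raise ValueError("blur_sigma_um must be >= 0")
    frequencies = [float(f) for f in frequencies_cpmm]
    if not frequencies:
        raise ValueError("at least one frequency is required")
    nyquist = 1000.0 / (2.0 * spec.pixel_pitch_um)
    for f in frequencies:
        if f <= 0:
            raise ValueError("frequencies must be > 0")
        if f > nyquist:
            raise ValueError(
                f"frequency {f:g} cycles/mm exceeds the Nyquist limit "
                f"{nyquist:g} cycles/mm for a {spec.pixel_pitch_um:g} um pixel pitch"
            )

    rows, cols = spec.frame_shape
    if orientation == "y":
        rows, cols = cols, rows
    elif orientation != "x":
        raise ValueError("orientation must be 'x' or 'y'")
    need = bar_target_shape(frequencies, spec.pixel_pitch_um, band_px=band_px, margin_px=margin_px)
    if rows < need[0] or cols < need[1]:
        raise ValueError(
            f"frame {(rows, cols)} too small for these groups; needs at least {need}"
        )

    lo = base_rate * (1.0 - contrast)
    hi = base_rate * (1.0 + contrast)
    sigma_px = blur_sigma_um / spec.pixel_pitch_um
    rate = np.full((rows, cols), lo, dtype=float)
    groups: list[BarGroup] = []
    row0 = margin_px
    for f in frequencies:
        period_px = 1000.0 / (f * spec.pixel_pitch_um)
        start_px = float(margin_px)
        intervals = [
            (start_px + k * period_px, start_px + k * period_px + period_px / 2)
            for k in range(3)
        ]
        profile = _blurred_bar_profile(cols, intervals, lo, hi, sigma_px)
        rate[row0 : row0 + band_px, :] = profile[np.newaxis, :]
        c0 = int(math.floor(start_px))
        c1 = int(math.ceil(start_px + 3 * period_px))
        groups.append(
            BarGroup(
                frequency_cpmm=f,
                bbox=(row0, row0 + band_px, c0, c1),
                period_px=period_px,
                start_px=start_px,
                n_bars=3,
                axis="x",
            )
        )
        row0 += band_px + margin_px

    if orientation == "y":
        rate = rate.T
        groups = [
            BarGroup(
                frequency_cpmm=g.frequency_cpmm,
                bbox=(g.bbox[2], g.bbox[3], g.bbox[0], g.bbox[1]),
                period_px=g.period_px,
                start_px=g.start_px,
                n_bars=g.n_bars,
                axis="y",
            )
            for g in groups
        ]

    rng = np.random.default_rng(seed)
    img = expose(
        rate,
        spec,
        noise=noise,
        rng=rng,
        metadata={"kind": "bar_target", "seed": seed, "contrast": contrast,
                  "blur_sigma_um": blur_sigma_um, "base_rate": base_rate},
    )
    return img, groups


# ---------------------------------------------------------------------------
# microsphere calibration series
# ---------------------------------------------------------------------------


def _coverage_disc(shape: tuple[int, int], center_px: tuple[float, float], radius_px: float,
                   subsamples: int = 16) -> np.ndarray:
    """Anti-aliased disc: per-pixel fraction covered, estimated on a
    ``subsamples x subsamples`` sub-grid. Flux-conserving to within the
    sub-grid resolution."""
    r0 = max(int(math.floor(center_px[0] - radius_px - 1)), 0)
    r1 = min(int(math.ceil(center_px[0] + radius_px + 1)) + 1, shape[0])
    c0 = max(int(math.floor(center_px[1] - radius_px - 1)), 0)
    c1 = min(int(math.ceil(center_px[1] + radius_px + 1)) + 1, shape[1])
    cov = np.zeros(shape, dtype=float)
    if r1 <= r0 or c1 <= c0:
        return cov
    sub = (np.arange(subsamples) + 0.5) / subsamples
    rr = r0 + np.add.outer(np.arange(r1 - r0), sub).ravel()
    cc = c0 + np.add.outer(np.arange(c1 - c0), sub).ravel()
    d2 = (rr[:, None] - center_px[0]) ** 2 + (cc[None, :] - center_px[1]) ** 2
    inside = (d2 <= radius_px**2).reshape(r1 - r0, subsamples, c1 - c0, subsamples)
    cov[r0:r1, c0:c1] = inside.mean(axis=(1, 3))
    return cov


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    min_separation_px: float,
    margin_px: float,
) -> np.ndarray:
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * n
    lo_r, hi_r = margin_px, shape[0] - margin_px
    lo_c, hi_c = margin_px, shape[1] - margin_px
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("frame too small for the requested sphere margin")
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} non-overlapping spheres in a "
                f"{shape[0]}x{shape[1]} frame at minimum separation "
                f"{min_separation_px:.1f} px; reduce the density"
            )
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_separation_px**2
               for r, c in centers):
            centers.append(cand)
    return np.array(centers)


def make_microsphere_series(
    spec: AcquisitionSpec,
    nominal_fractions: Sequence[float],
    exposure_times_ms: Sequence[float],
    *,
    sphere_diameter_um: float = 6.0,
    n_spheres: int = 20,
    brightest_rate: float = 2.0e4,
    noise: bool = True,
    seed: int = 0,
) -> tuple[list[RawImage], pd.DataFrame]:
    """Simulate a fluorescent-microsphere calibration series.

    One frame per (nominal fraction, exposure time) pair. Sphere emission
    rate is ``fraction * brightest_rate``, clamped so that the expected peak
    signal never exceeds the full-well ceiling at that exposure. The sphere
    layout is drawn once per fraction and reused across exposures, as for
    beads held in a flow channel.

    Returns the frame list and a truth table with one row per sphere per
    frame (frame index, fraction, exposure, centroid, true emission rate,
    saturation flag).
    """
    fractions = [float(v) for v in nominal_fractions]
    exposures = [float(v) for v in exposure_times_ms]
    if any(not 0 < v <= 1 for v in fractions):
        raise ValueError("nominal fractions must be in (0, 1]")
    if any(v <= 0 for v in exposures):
        raise ValueError("exposure times must be > 0")
    if n_spheres < 15:
        raise ValueError("need at least 15 spheres per frame")
    radius_px = sphere_diameter_um / (2.0 * spec.pixel_pitch_um)
    sep = 2 * radius_px + 8.0
    ss = np.random.SeedSequence(seed)
    layout_rngs = [np.random.default_rng(s) for s in ss.spawn(len(fractions))]
    noise_rng = np.random.default_rng(ss.spawn(1)[0])

    frames: list[RawImage] = []
    rows: list[dict[str, Any]] = []
    frame_idx = 0
    for fi, frac in enumerate(fractions):
        centers = _place_centers(layout_rngs[fi], spec.frame_shape, n_spheres, sep, radius_px + 4)
        base = np.zeros(spec.frame_shape, dtype=float)
        for r, c in centers:
            base += _coverage_disc(spec.frame_shape, (r, c), radius_px)
        for t_ms in exposures:
            # saturation guard: truth rate never exceeds what the well can hold
            ceiling = (spec.full_well - spec.dark_offset) / (t_ms / 1000.0)
            rate_val = frac * brightest_rate
            saturated = rate_val > ceiling
            true_rate = min(rate_val, ceiling)
            frames.append(
                expose(
                    base * true_rate,
                    spec,
                    exposure_time_ms=t_ms,
                    noise=noise,
                    rng=noise_rng,
                    metadata={
                        "kind": "microsphere",
                        "nominal_fraction": frac,
                        "sphere_diameter_um": sphere_diameter_um,
                        "seed": seed,
                    },
                )
            )
            for r, c in centers:
                rows.append(
                    {
                        "frame": frame_idx,
                        "nominal_fraction": frac,
                        "exposure_time_ms": t_ms,
                        "row_px": r,
                        "col_px": c,
                        "true_rate": true_rate,
                        "saturated": saturated,
                    }
                )
            frame_idx += 1
    return frames, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tumor / muscle / tumor-bed phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneObject:
    """A disc-shaped emitter: centroid in micrometres (row, col)."""

    centroid_um: tuple[float, float]
    diameter_um: float
    rate: float
    shape: str = "disc"

    def to_dict(self) -> dict[str, Any]:
        return {
            "centroid_um": list(self.centroid_um),
            "diameter_um": self.diameter_um,
            "rate": self.rate,
            "shape": self.shape,
        }


@dataclass
class PhantomScene:
    """Ground truth for a tumor-bed phantom.

    ``truth_mask`` marks pixels containing tumor cells among the *visible*
    objects; ``hidden_layers`` hold clusters only revealed by successive
    resections (a simulation device for serially positive beds, not a claim
    about the underlying biology).
    """

    background_rate: float
    objects: list[SceneObject]
    truth_mask: np.ndarray
    hidden_layers: list[list[SceneObject]] = field(default_factory=list)
    pixel_pitch_um: float = 6.5


def rasterize_disc(
    frame_shape: tuple[int, int],
    centroid_um: tuple[float, float],
    diameter_um: float,
    pixel_pitch_um: float,
) -> np.ndarray:
    """Binary disc mask by pixel-center inclusion.

    Pixel (r, c) spans ``[r, r+1) x [c, c+1)`` pixel units; its center sits at
    ``(r + 0.5, c + 0.5) * pitch`` micrometres. A pixel is inside the disc
    iff its center is within ``diameter/2`` of the centroid.
    """
    if diameter_um <= 0:
        raise ValueError("diameter_um must be > 0")
    rr = (np.arange(frame_shape[0]) + 0.5) * pixel_pitch_um
    cc = (np.arange(frame_shape[1]) + 0.5) * pixel_pitch_um
    d2 = (rr[:, None] - centroid_um[0]) ** 2 + (cc[None, :] - centroid_um[1]) ** 2
    return d2 <= (diameter_um / 2.0) ** 2


def _lognormal_field(rng: np.random.Generator, shape: tuple[int, int], cv: float) -> np.ndarray:
    """Multiplicative heterogeneity with mean 1 and the requested CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


def make_tumor_bed_pair(
    spec: AcquisitionSpec,
    tumor_rate: float,
    muscle_rate: float,
    residual_clusters: Sequence[tuple[float, float, float, float]] = (),
    *,
    heterogeneity_cv: float = 0.0,
    hidden_layers: Sequence[Sequence[tuple[float, float, float, float]]] = (),
    noise: bool = True,
    seed: int = 0,
) -> tuple[RawImage, RawImage, RawImage, PhantomScene]:
    """Generate a (tumor, muscle, bed) image triplet with ground truth.

    ``residual_clusters`` is a sequence of ``(row_um, col_um, diameter_um,
    rate)`` discs stamped into the bed on top of a muscle-rate background.
    ``hidden_layers`` follow the same format; they are recorded in the scene
    but not rendered (the guided-resection loop reveals them).

    Pixel-wise multiplicative lognormal heterogeneity (mean 1, given CV) is
    applied to the tissue rates before detector noise.
    """
    if not tumor_rate > muscle_rate > 0:
        raise ValueError("require tumor_rate > muscle_rate > 0")
    if heterogeneity_cv < 0:
        raise ValueError("heterogeneity_cv must be >= 0")
    fov_um = (spec.frame_shape[0] * spec.pixel_pitch_um, spec.frame_shape[1] * spec.pixel_pitch_um)
    objects: list[SceneObject] = []
    for row_um, col_um, diam, rate_val in residual_clusters:
        if diam <= 0:
            raise ValueError("cluster diameters must be > 0")
        if not (0 <= row_um <= fov_um[0] and 0 <= col_um <= fov_um[1]):
            raise ValueError(
                f"cluster at ({row_um}, {col_um}) um lies outside the "
                f"{fov_um[0]:g} x {fov_um[1]:g} um field"
            )
        objects.append(SceneObject(centroid_um=(row_um, col_um), diameter_um=diam, rate=rate_val))
    hidden = [
        [SceneObject(centroid_um=(r, c), diameter_um=d, rate=v) for r, c, d, v in layer]
        for layer in hidden_layers
    ]

    ss = np.random.SeedSequence(seed)
    het_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    tumor_map = tumor_rate * _lognormal_field(het_rng, spec.frame_shape, heterogeneity_cv)
    muscle_map = muscle_rate * _lognormal_field(het_rng, spec.frame_shape, heterogeneity_cv)
    bed_map = muscle_rate * _lognormal_field(het_rng, spec.frame_shape, heterogeneity_cv)

    truth = np.zeros(spec.frame_shape, dtype=bool)
    for obj in objects:
        disc = rasterize_disc(spec.frame_shape, obj.centroid_um, obj.diameter_um,
                              spec.pixel_pitch_um)
        bed_map[disc] = obj.rate
        if obj.rate > muscle_rate:
            truth |= disc

    common = {"seed": seed, "tumor_rate": tumor_rate, "muscle_rate": muscle_rate}
    tumor_img = expose(tumor_map, spec, noise=noise, rng=noise_rng,
                       metadata={"kind": "tumor", **common})
    muscle_img = expose(muscle_map, spec, noise=noise, rng=noise_rng,
                        metadata={"kind": "muscle", **common})
    bed_img = expose(bed_map, spec, noise=noise, rng=noise_rng,
                     metadata={"kind": "bed", **common})
    scene = PhantomScene(
        background_rate=muscle_rate,
        objects=objects,
        truth_mask=truth,
        hidden_layers=hidden,
        pixel_pitch_um=spec.pixel_pitch_um,
    )
    return tumor_img, muscle_img, bed_img, scene


# ---------------------------------------------------------------------------
# recurrence cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm recurrence cohort under proportional hazards.

    Event times are exponential with rate ``baseline_hazard`` in the
    residual-negative arm and ``baseline_hazard * true_hazard_ratio`` in the
    residual-positive arm; follow-up is administratively censored at
    ``followup_max`` months. ``weibull_shape != 1`` switches to a Weibull
    event-time model with the same scale interpretation (for robustness
    experiments only).
    """

    n_per_arm: int
    baseline_hazard: float
    true_hazard_ratio: float
    followup_max: float = 12.0
    seed: int = 0
    weibull_shape: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")
        if self.true_hazard_ratio <= 0:
            raise ValueError("true_hazard_ratio must be > 0")
        if self.followup_max <= 0:
            raise ValueError("followup_max must be > 0")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort; returns ``subject_id, arm, time_months, event``."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for arm, mult in ((ARM_NEGATIVE, 1.0), (ARM_POSITIVE, spec.true_hazard_ratio)):
        hazard = spec.baseline_hazard * mult
        if hazard > 0:
            u = rng.uniform(size=spec.n_per_arm)
            t = (-np.log(u) / hazard) ** (1.0 / spec.weibull_shape)
        else:
            t = np.full(spec.n_per_arm, np.inf)
        event = t <= spec.followup_max
        t = np.minimum(t, spec.followup_max)
        for i in range(spec.n_per_arm):
            rows.append(
                {
                    "subject_id": f"{arm}_{i:04d}",
                    "arm": arm,
                    "time_months": float(t[i]),
                    "event": int(event[i]),
                }
            )
    return pd.DataFrame(rows)
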