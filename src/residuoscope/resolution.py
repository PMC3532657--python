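"""Contrast-transfer-function measurement on bar-pattern targets.

For each bar group the profile perpendicular to the bars is reduced to a
peak intensity ``i_max`` (mean of the per-cycle maxima over the bright
bars) and a trough intensity ``i_min`` (mean of the minima between
consecutive bright bars). The contrast-transfer modulus at that group's
spatial frequency is ``(i_max - i_min) / (i_max + i_min)``.

The resolution limit of a measured curve is the spatial frequency at which
the modulus first drops through a configurable cutoff (default 0.1); one
full line cycle at that frequency, ``1000 / f`` micrometres, is reported as
the spatial resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .acquisition import EmissionRateImage
from .synthetic import BarGroup

__all__ = [
    "BarGroupMeasurement",
    "CTFCurve",
    "measure_bar_contrast",
    "ctf_modulus",
    "compute_ctf_curve",
    "resolution_limit",
    "frequency_to_resolution",
    "resolution_to_frequency",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 0.1


@dataclass(frozen=True)
class BarGroupMeasurement:
    frequency_cpmm: float
    i_max: float
    i_min: float

    def __post_init__(self) -> None:
        if self.frequency_cpmm <= 0:
            raise ValueError("frequency must be > 0")
        if not self.i_max >= self.i_min >= 0:
            raise ValueError("require i_max >= i_min >= 0")


@dataclass(frozen=True)
class CTFCurve:
    """Contrast moduli per spatial frequency along one axis."""

    points: tuple[tuple[float, float], ...]  # (cycles/mm, modulus), ascending f
    axis: str = "horizontal"
    resolution_limit_cpmm: float | None = None
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        freqs = [p[0] for p in self.points]
        if freqs != sorted(freqs):
            raise ValueError("curve points must be sorted by frequency")
        for _, m in self.points:
            if not -1e-9 <= m <= 1 + 1e-9:
                raise ValueError("ctf modulus must lie in [0, 1]")

    @property
    def resolution_um(self) -> float | None:
        if self.resolution_limit_cpmm is None:
            return None
        return frequency_to_resolution(self.resolution_limit_cpmm)


def measure_bar_contrast(img: EmissionRateImage, group: BarGroup) -> BarGroupMeasurement:
    """Measure peak/trough intensities for one annotated bar group.

    The 2-D box is averaged along the bars to a 1-D profile; per-cycle
    windows derived from the annotation's period and phase supply the
    maxima (one per bright bar) and the minima (one per gap between
    consecutive bright bars).
    """
    r0, r1, c0, c1 = group.bbox
    rows, cols = img.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"group bbox {group.bbox} does not lie inside the {img.shape} frame")
    window = img.rates[r0:r1, c0:c1]
    if group.axis == "y":
        window = window.T
        lo, hi = r0, r1
    else:
        lo, hi = c0, c1
    if (hi - lo) < 2 * group.period_px:
        raise ValueError(
            f"annotation spans {(hi - lo)} px, less than two cycles "
            f"({2 * group.period_px:.1f} px) at {group.frequency_cpmm:g} cycles/mm"
        )
    profile = window.mean(axis=0)
    x = lo + np.arange(profile.size) + 0.5  # pixel-center coordinates

    T = group.period_px
    x0 = group.start_px
    maxima = []
    for k in range(group.n_bars):
        sel = (x >= x0 + k * T) & (x < x0 + (k + 1) * T)
        if not sel.any():
            raise ValueError("bar cycle contains no pixel sample; frequency too high")
        maxima.append(float(profile[sel].max()))
    minima = []
    for k in range(group.n_bars - 1):
        sel = (x >= x0 + k * T + T / 2) & (x < x0 + (k + 1) * T)
        if not sel.any():
            raise ValueError("gap between bars contains no pixel sample; frequency too high")
        minima.append(float(profile[sel].min()))
    i_max = float(np.mean(maxima))
    i_min = float(np.mean(minima))
    if i_min > i_max:  # degenerate flat fields can invert by float noise
        i_min = i_max
    return BarGroupMeasurement(frequency_cpmm=group.frequency_cpmm, i_max=i_max, i_min=max(i_min, 0.0))


def ctf_modulus(m: BarGroupMeasurement) -> float:
    """Square-wave contrast modulus ``(i_max - i_min)/(i_max + i_min)``."""
    denom = m.i_max + m.i_min
    if denom <= 0:
        raise ValueError("contrast undefined: i_max and i_min are both zero")
    return (m.i_max - m.i_min) / denom


def compute_ctf_curve(
    img: EmissionRateImage,
    groups: Sequence[BarGroup],
    *,
    axis: str = "horizontal",
    cutoff: float = DEFAULT_CUTOFF,
    require_limit: bool = False,
) -> CTFCurve:
    """Measure every group, assemble the sorted curve and, when the curve
    crosses the cutoff, its resolution limit."""
    measurements = [measure_bar_contrast(img, g) for g in groups]
    pts = sorted((m.frequency_cpmm, min(max(ctf_modulus(m), 0.0), 1.0)) for m in measurements)
    limit: float | None
    try:
        limit = resolution_limit(pts, cutoff)
    except ValueError:
        if require_limit:
            raise
        limit = None
    return CTFCurve(points=tuple(pts), axis=axis, resolution_limit_cpmm=limit, cutoff=cutoff)


def resolution_limit(points: Sequence[tuple[float, float]], cutoff: float = DEFAULT_CUTOFF) -> float:
    """Frequency of the first downward crossing of ``ctf = cutoff``,
    linearly interpolated between the neighbouring measured groups."""
    pts = sorted((float(f), float(m)) for f, m in points)
    if len(pts) < 2:
        raise ValueError("need at least 2 curve points")
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    for (f0, m0), (f1, m1) in zip(pts, pts[1:]):
        if m0 >= cutoff >= m1 and m0 > m1:
            return f0 + (m0 - cutoff) / (m0 - m1) * (f1 - f0)
        if m0 <= cutoff and pts[0][1] <= cutoff:
            # curve starts below the cutoff: no downward crossing exists
            break
    lo, hi = pts[0][0], pts[-1][0]
    raise ValueError(
        f"CTF curve never crosses {cutoff:g} from above between "
        f"{lo:g} and {hi:g} cycles/mm"
    )


def frequency_to_resolution(frequency_cpmm: float) -> float:
    """Spatial resolution in micrometres: the length of one full line cycle
    at the given frequency, ``1000 / f``."""
    if frequency_cpmm <= 0:
        raise ValueError("frequency must be > 0")
    return 1000.0 / frequency_cpmm


def resolution_to_frequency(resolution_um: float) -> float:
    if resolution_um <= 0:
        raise ValueError("resolution must be > 0")
    return 1000.0 / resolution_um
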