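"""Acquisition geometry, image containers, sensor model and TIFF I/O.

The two image containers used throughout the package are :class:`RawImage`
(integer pixel counts straight off the detector, tagged with the exposure
time used to acquire them) and :class:`EmissionRateImage` (exposure-
normalized counts/second, the time-independent intensity every downstream
measurement is defined on).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import tifffile

__all__ = [
    "AcquisitionSpec",
    "RawImage",
    "EmissionRateImage",
    "expose",
    "write_raw_tiff",
    "read_raw_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera + optics geometry for a 1:1 magnification wide-field system.

    Parameters
    ----------
    pixel_pitch_um:
        Physical size of one pixel at the specimen plane (micrometres).
        The default of 6.5 um puts a ~1385 x 1015 pixel sensor across a
        9.0 x 6.6 mm field of view.
    frame_shape:
        (rows, cols) of the sensor.
    exposure_time_ms:
        Default exposure used when a frame is synthesized.
    bit_depth:
        ADC bit depth; counts are clipped to ``2**bit_depth - 1``.
    read_noise_sd:
        Gaussian read-noise standard deviation in counts.
    dark_offset:
        Constant dark level added to every pixel, in counts.
    full_well:
        Saturation ceiling in counts. Defaults to ``2**bit_depth - 1``.
    """

    pixel_pitch_um: float = 6.5
    frame_shape: tuple[int, int] = (1015, 1385)
    exposure_time_ms: float = 100.0
    bit_depth: int = 16
    read_noise_sd: float = 2.0
    dark_offset: float = 100.0
    full_well: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")
        if self.exposure_time_ms <= 0:
            raise ValueError("exposure_time_ms must be > 0")
        if self.dark_offset < 0:
            raise ValueError("dark_offset must be >= 0")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 1:
            raise ValueError("frame_shape must be two positive integers")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        if self.full_well is None:
            object.__setattr__(self, "full_well", self.max_count)
        object.__setattr__(self, "frame_shape", tuple(int(n) for n in self.frame_shape))

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def field_of_view_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the imaged field in millimetres."""
        r, c = self.frame_shape
        return (r * self.pixel_pitch_um / 1000.0, c * self.pixel_pitch_um / 1000.0)

    def with_exposure(self, exposure_time_ms: float) -> "AcquisitionSpec":
        return replace(self, exposure_time_ms=exposure_time_ms)

    def to_dict(self) -> dict[str, Any]:
        return {
            "pixel_pitch_um": self.pixel_pitch_um,
            "frame_shape": list(self.frame_shape),
            "exposure_time_ms": self.exposure_time_ms,
            "bit_depth": self.bit_depth,
            "read_noise_sd": self.read_noise_sd,
            "dark_offset": self.dark_offset,
            "full_well": self.full_well,
        }


@dataclass
class RawImage:
    """Integer pixel counts plus the metadata needed to normalize them."""

    pixels: np.ndarray
    exposure_time_ms: float
    bit_depth: int = 16
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.exposure_time_ms is None or self.exposure_time_ms <= 0:
            raise ValueError("exposure_time_ms must be > 0")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("RawImage pixels must be integer counts")
        if self.pixels.min(initial=0) < 0:
            raise ValueError("RawImage pixels must be non-negative")
        if self.pixels.size and int(self.pixels.max()) > 2**self.bit_depth - 1:
            raise ValueError("pixel counts exceed the stated bit depth")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class EmissionRateImage:
    """Exposure-normalized pixel map in counts/second."""

    rates: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("emission rates must be finite")
        if self.rates.size and self.rates.min() < 0:
            raise ValueError("emission rates must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rates.shape  # type: ignore[return-value]

    @property
    def pixel_pitch_um(self) -> float | None:
        return self.provenance.get("pixel_pitch_um")


def expose(
    rate_map: np.ndarray,
    spec: AcquisitionSpec,
    *,
    exposure_time_ms: float | None = None,
    noise: bool = True,
    rng: np.random.Generator | None = None,
    metadata: dict[str, Any] | None = None,
) -> RawImage:
    """Turn a counts/second map into detector counts.

    Sensor model: ``counts ~ Poisson(rate * t) + N(0, read_noise_sd) +
    dark_offset``, rounded and clipped to ``[0, min(full_well, 2**bits - 1)]``.
    With ``noise=False`` the Poisson and Gaussian terms are replaced by their
    means, so a noiseless frame is exactly ``rint(rate * t) + dark_offset``.
    """
    rate_map = np.asarray(rate_map, dtype=float)
    if rate_map.min(initial=0.0) < 0:
        raise ValueError("rate map must be non-negative")
    t_ms = spec.exposure_time_ms if exposure_time_ms is None else exposure_time_ms
    if t_ms <= 0:
        raise ValueError("exposure time must be > 0")
    expected = rate_map * (t_ms / 1000.0)
    if noise:
        if rng is None:
            rng = np.random.default_rng()
        counts = rng.poisson(expected).astype(float)
        if spec.read_noise_sd > 0:
            counts += rng.normal(0.0, spec.read_noise_sd, size=counts.shape)
    else:
        counts = expected.copy()
    counts += spec.dark_offset
    ceiling = min(int(spec.full_well), spec.max_count)
    counts = np.clip(np.rint(counts), 0, ceiling)
    dtype = np.uint16 if spec.bit_depth <= 16 else np.uint32
    meta = {
        "pixel_pitch_um": spec.pixel_pitch_um,
        "dark_offset": spec.dark_offset,
        "read_noise_sd": spec.read_noise_sd,
        "full_well": int(spec.full_well),
        "noise": bool(noise),
    }
    if metadata:
        meta.update(metadata)
    return RawImage(
        pixels=counts.astype(dtype),
        exposure_time_ms=float(t_ms),
        bit_depth=spec.bit_depth,
        metadata=meta,
    )


def write_raw_tiff(path, img: RawImage) -> None:
    """Write a 16-bit grayscale TIFF with acquisition metadata in the
    description tag as JSON."""
    desc = {
        "exposure_time_ms": img.exposure_time_ms,
        "bit_depth": img.bit_depth,
        "metadata": _json_safe(img.metadata),
    }
    tifffile.imwrite(str(path), img.pixels, description=json.dumps(desc))


def read_raw_tiff(path, *, exposure_time_ms: float | None = None) -> RawImage:
    """Read a TIFF written by :func:`write_raw_tiff`, or any plain grayscale
    TIFF if the exposure time is supplied explicitly."""
    with tifffile.TiffFile(str(path)) as tif:
        pixels = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict[str, Any] = {}
    bit_depth = 16
    t_ms = exposure_time_ms
    if desc:
        try:
            payload = json.loads(desc)
            if t_ms is None:
                t_ms = payload.get("exposure_time_ms")
            bit_depth = int(payload.get("bit_depth", bit_depth))
            meta = payload.get("metadata", {}) or {}
        except (ValueError, TypeError, AttributeError):
            pass
    if t_ms is None:
        raise ValueError(
            f"{path}: no exposure time in the TIFF description; pass exposure_time_ms"
        )
    return RawImage(
        pixels=np.asarray(pixels), exposure_time_ms=float(t_ms), bit_depth=bit_depth, metadata=meta
    )


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path))) > 0


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
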