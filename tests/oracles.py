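"""Independent brute-force oracles used to freeze expected values.

Deliberately naive implementations (explicit loops, np.convolve on fine
grids) that share no code with the package paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def bar_contrast_oracle(
    frequency_cpmm: float,
    pixel_pitch_um: float,
    blur_sigma_um: float,
    contrast: float,
    *,
    base_rate: float = 2000.0,
    start_px: float = 16.0,
    n_bars: int = 3,
    n_cols: int = 400,
    oversample: int = 128,
) -> float:
    """Contrast of a Gaussian-blurred, pixel-integrated 3-bar pattern by
    direct 1-D numerical convolution on a fine grid.

    Mirrors the rendering geometry (bright bar = first half of each cycle,
    pattern starting at ``start_px``) but builds the profile with a
    hand-rolled discrete Gaussian kernel and np.convolve, bins by
    averaging, and scans cycle windows with plain Python loops.
    """
    lo = base_rate * (1.0 - contrast)
    hi = base_rate * (1.0 + contrast)
    period_px = 1000.0 / (frequency_cpmm * pixel_pitch_um)
    dx = 1.0 / oversample
    xs = (np.arange(n_cols * oversample) + 0.5) * dx
    phase = xs - start_px
    wave = np.where(
        (phase >= 0) & (phase < n_bars * period_px) & (np.mod(phase, period_px) < period_px / 2),
        hi,
        lo,
    )
    sigma_px = blur_sigma_um / pixel_pitch_um
    if sigma_px > 0:
        half = int(math.ceil(6 * sigma_px / dx))
        k = np.arange(-half, half + 1) * dx
        kernel = np.exp(-0.5 * (k / sigma_px) ** 2)
        kernel /= kernel.sum()
        padded = np.concatenate([np.full(half, lo), wave, np.full(half, lo)])
        wave = np.convolve(padded, kernel, mode="valid")
    pixels = wave.reshape(n_cols, oversample).mean(axis=1)
    centers = np.arange(n_cols) + 0.5

    maxima = []
    for k in range(n_bars):
        window = [
            pixels[i]
            for i in range(n_cols)
            if start_px + k * period_px <= centers[i] < start_px + (k + 1) * period_px
        ]
        maxima.append(max(window))
    minima = []
    for k in range(n_bars - 1):
        window = [
            pixels[i]
            for i in range(n_cols)
            if start_px + k * period_px + period_px / 2
            <= centers[i]
            < start_px + (k + 1) * period_px
        ]
        minima.append(min(window))
    i_max = sum(maxima) / len(maxima)
    i_min = sum(minima) / len(minima)
    return (i_max - i_min) / (i_max + i_min)


def km_oracle(times, events):
    """Product-limit estimate by explicit risk-set enumeration.

    Returns (event_times, survival, greenwood_variance) as plain lists.
    """
    records = sorted(zip(times, events))
    event_times = sorted({t for t, e in records if e == 1})
    surv = 1.0
    cum = 0.0
    out_t, out_s, out_v = [], [], []
    for u in event_times:
        at_risk = sum(1 for t, _ in records if t >= u)
        deaths = sum(1 for t, e in records if t == u and e == 1)
        surv *= 1.0 - deaths / at_risk
        if at_risk > deaths:
            cum += deaths / (at_risk * (at_risk - deaths))
            var = surv**2 * cum
        else:
            var = 0.0
        out_t.append(u)
        out_s.append(surv)
        out_v.append(var)
    return out_t, out_s, out_v


def logrank_oracle(times_a, events_a, times_b, events_b):
    """O-E / V log-rank computation by direct per-time enumeration."""
    pooled = sorted(
        {t for t, e in zip(list(times_a) + list(times_b), list(events_a) + list(events_b)) if e == 1}
    )
    o_minus_e = 0.0
    var = 0.0
    for u in pooled:
        n_a = sum(1 for t in times_a if t >= u)
        n_b = sum(1 for t in times_b if t >= u)
        d_a = sum(1 for t, e in zip(times_a, events_a) if t == u and e == 1)
        d_b = sum(1 for t, e in zip(times_b, events_b) if t == u and e == 1)
        n = n_a + n_b
        d = d_a + d_b
        o_minus_e += d_b - d * n_b / n
        if n > 1:
            var += d * (n_b / n) * (n_a / n) * (n - d) / (n - 1)
    stat = 0.0 if var == 0 else o_minus_e**2 / var
    return stat, o_minus_e, var


def disc_pixel_count_oracle(
    frame_shape, centroid_um, diameter_um, pixel_pitch_um
) -> int:
    """Count pixels whose centers fall inside the disc, by double loop."""
    n = 0
    for r in range(frame_shape[0]):
        for c in range(frame_shape[1]):
            cy = (r + 0.5) * pixel_pitch_um
            cx = (c + 0.5) * pixel_pitch_um
            if (cy - centroid_um[0]) ** 2 + (cx - centroid_um[1]) ** 2 <= (diameter_um / 2) ** 2:
                n += 1
    return n
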