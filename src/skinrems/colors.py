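"""Colour-space conversion and per-ROI statistical descriptors.

The hue/saturation/value construction implemented here is the arccos-based
one used by the acquisition method::

    theta = arccos[ ((R-G) + (R-B)) / (2 * sqrt((R-G)^2 + (R-B)(G-B))) ]
    H = theta          if B <= G
    H = 360 - theta    if B >  G            (degrees, in [0, 360))
    S = 1 - 3 * min(R, G, B) / (R + G + B)  (unitless, in [0, 1])
    V = max(R, G, B)                        (intensity units)

This is deliberately the HSI-style hue/saturation — not the standard
hexcone HSV — and is implemented verbatim. Degenerate conventions: for
achromatic pixels (R = G = B) the hue denominator vanishes and H is defined
as 0; for black pixels (R + G + B = 0) S is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from .errors import InputError

CHANNELS = ("R", "G", "B", "H", "S", "V")
STATISTICS = ("mean", "median", "mode", "min", "max", "range")


def rgb_to_hsv(r, g, b):
    """Convert 8-bit RGB intensities to (H degrees, S unitless, V intensity).

    Accepts scalars or arrays (broadcast together). Vectorised; the identity
    (R-G)^2 + (R-B)(G-B) = (a - b/2)^2 + 3b^2/4 >= 0 with a = R-G, b = R-B
    guarantees the radicand is non-negative, vanishing iff R = G = B.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)

    num = 0.5 * ((r - g) + (r - b))
    radicand = (r - g) ** 2 + (r - b) * (g - b)
    den = np.sqrt(np.maximum(radicand, 0.0))
    achromatic = den == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(achromatic, 1.0, num / np.where(achromatic, 1.0, den))
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    h = np.where(b <= g, theta, 360.0 - theta)
    h = np.where(achromatic, 0.0, h)

    total = r + g + b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / np.where(total > 0, total, 1.0), 0.0)
    v = np.maximum(np.maximum(r, g), b)
    if h.ndim == 0:
        return float(h), float(s), float(v)
    return h, s, v


def _mode(values: np.ndarray, channel: str) -> float:
    """Mode on an integer-binned histogram; ties resolved to the smallest bin.

    R/G/B/V are already 0-255 integers; H is binned to whole degrees; S (in
    [0, 1]) is quantised to 1/255 steps so its mode lives on the same grid
    as the 8-bit channels it derives from.
    """
    if channel == "S":
        scaled = np.rint(np.asarray(values, dtype=float) * 255.0).astype(np.int64)
        counts = np.bincount(scaled, minlength=256)
        return float(np.argmax(counts) / 255.0)
    scaled = np.rint(np.asarray(values, dtype=float)).astype(np.int64)
    counts = np.bincount(scaled)
    return float(np.argmax(counts))


@dataclass
class ColorDescriptor:
    """Six order/location statistics per colour channel for one ROI."""

    stats: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __getitem__(self, key: Tuple[str, str]) -> float:
        return self.stats[key]

    def channels(self):
        return sorted({c for c, _ in self.stats})


def descriptor_stats(pixels: Mapping[str, np.ndarray]) -> ColorDescriptor:
    """Compute mean/median/mode/min/max/range per channel of an ROI.

    ``pixels`` maps channel letters to 1-D arrays of per-pixel values (the
    multiset of intensities inside one mask). Order of pixels is irrelevant.
    """
    out: Dict[Tuple[str, str], float] = {}
    for channel, values in pixels.items():
        values = np.asarray(values, dtype=float).ravel()
        if values.size == 0:
            raise InputError(f"empty ROI for channel {channel!r}")
        lo, hi = float(values.min()), float(values.max())
        # constant ROI: mean/median are the value itself, exactly (avoids
        # accumulation error that would break the zero-response null case)
        out[(channel, "mean")] = lo if lo == hi else float(values.mean())
        out[(channel, "median")] = lo if lo == hi else float(np.median(values))
        out[(channel, "mode")] = _mode(values, channel)
        out[(channel, "min")] = lo
        out[(channel, "max")] = hi
        out[(channel, "range")] = hi - lo
    return ColorDescriptor(out)


def roi_channel_values(rgb_pixels: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-channel value arrays (R, G, B, H, S, V) for an (n, 3) pixel set."""
    rgb_pixels = np.asarray(rgb_pixels, dtype=float)
    if rgb_pixels.ndim != 2 or rgb_pixels.shape[1] != 3:
        raise InputError("expected an (n, 3) array of RGB pixels")
    r, g, b = rgb_pixels[:, 0], rgb_pixels[:, 1], rgb_pixels[:, 2]
    h, s, v = rgb_to_hsv(r, g, b)
    return {"R": r, "G": g, "B": b, "H": h, "S": s, "V": v}


def differential_features(
    patch: ColorDescriptor, control: ColorDescriptor
) -> Dict[Tuple[str, str], float]:
    """Patch-minus-control difference for every (channel, statistic).

    Both descriptors must come from the same frame; the subtraction removes
    the subject's baseline skin tone and residual illumination. Differences
    may be negative. Hue is differenced as plain degrees (no circular
    statistics) — adequate for skin tones far from the 0/360 wrap.
    """
    if set(patch.stats) != set(control.stats):
        raise InputError("patch and control descriptors cover different keys")
    return {k: patch.stats[k] - control.stats[k] for k in patch.stats}
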