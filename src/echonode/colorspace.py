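"""HSV color machinery on the 8-bit scanner-overlay convention.

All color rules in this package (Doppler flow detection, elastography
stiffness bands) are expressed in the HSV convention used by 8-bit image
pipelines: hue in half-degrees 0-179 (so the full color circle fits a
byte), saturation and value 0-255.  Gray pixels (R = G = B) have
saturation 0, which is what separates B-mode speckle from genuine color
overlay regardless of brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidMeasureError, ModalityError

__all__ = ["HSVRange", "rgb_to_hsv_bytes", "hsv_bytes_to_rgb", "in_hsv_range"]


@dataclass(frozen=True)
class HSVRange:
    """Inclusive hue/saturation/value box.

    Hue is on the 0-180 half-degree scale; an upper hue bound of 180 means
    "up to the top of the scale" (stored hues are 0-179).
    """

    hue_lo: int = 0
    hue_hi: int = 180
    sat_lo: int = 0
    sat_hi: int = 255
    val_lo: int = 0
    val_hi: int = 255

    def __post_init__(self) -> None:
        for lo, hi, top, name in (
            (self.hue_lo, self.hue_hi, 180, "hue"),
            (self.sat_lo, self.sat_hi, 255, "sat"),
            (self.val_lo, self.val_hi, 255, "val"),
        ):
            if not (0 <= lo <= hi <= top):
                raise InvalidMeasureError(
                    f"invalid {name} range [{lo}, {hi}] (bounds 0..{top})"
                )

    @classmethod
    def from_bounds(cls, lower: tuple[int, int, int], upper: tuple[int, int, int]) -> "HSVRange":
        return cls(lower[0], upper[0], lower[1], upper[1], lower[2], upper[2])


#: any pixel that carries color at all: saturation >= 1 and value >= 1
ANY_COLOR = HSVRange(0, 180, 1, 255, 1, 255)


def rgb_to_hsv_bytes(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) uint8 RGB image to byte HSV.

    Returns an (H, W, 3) uint8 array with hue 0-179 (half-degrees),
    saturation and value 0-255; the rounding follows the usual 8-bit
    pipeline convention so integer thresholds behave as practitioners
    expect.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ModalityError("HSV conversion needs a 3-channel color image")
    rgb = arr.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = rgb.max(axis=-1)
    delta = v - rgb.min(axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, 255.0 * delta / v, 0.0)
        hue = np.zeros_like(v)
        nz = delta > 0
        rmax = nz & (r == v)
        gmax = nz & ~rmax & (g == v)
        bmax = nz & ~rmax & ~gmax
        hue[rmax] = 60.0 * ((g - b)[rmax] / delta[rmax])
        hue[gmax] = 120.0 + 60.0 * ((b - r)[gmax] / delta[gmax])
        hue[bmax] = 240.0 + 60.0 * ((r - g)[bmax] / delta[bmax])
    hue = np.mod(hue, 360.0)

    out = np.empty(arr.shape, dtype=np.uint8)
    out[..., 0] = np.mod(np.round(hue / 2.0), 180).astype(np.uint8)
    out[..., 1] = np.round(s).astype(np.uint8)
    out[..., 2] = np.round(v).astype(np.uint8)
    return out


def hsv_bytes_to_rgb(hue: int, sat: int, val: int) -> tuple[int, int, int]:
    """Inverse transform for a single color (used by the phantom painter)."""
    h = (hue * 2.0) / 60.0  # sector in [0, 6)
    s = sat / 255.0
    v = float(val)
    i = int(np.floor(h)) % 6
    f = h - np.floor(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return tuple(int(round(c)) for c in rgb)  # type: ignore[return-value]


def in_hsv_range(image: np.ndarray, rng: HSVRange) -> np.ndarray:
    """Boolean mask of pixels whose byte HSV falls inside ``rng``.

    A ``hue_hi`` of 180 is treated as the top of the scale (hue values
    themselves never exceed 179).
    """
    hsv = rgb_to_hsv_bytes(image)
    h, s, v = hsv[..., 0].astype(int), hsv[..., 1].astype(int), hsv[..., 2].astype(int)
    return (
        (h >= rng.hue_lo)
        & (h <= rng.hue_hi)
        & (s >= rng.sat_lo)
        & (s <= rng.sat_hi)
        & (v >= rng.val_lo)
        & (v <= rng.val_hi)
    )
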