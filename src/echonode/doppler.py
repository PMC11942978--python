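"""Doppler vascularity scoring.

Color-Doppler frames overlay flow information as colored (nonzero
saturation) pixels on a gray B-mode background.  Two indicators are
computed inside the node mask:

* ``vascularity_percentage`` — colored pixels / mask pixels x 100.
  Metastatic nodes are typically poorly vascularized; below 25% leans
  malignant.
* ``vascularity_position`` — mean distance of colored pixels from the
  node centroid, normalized by the mean centroid distance of the contour
  pixels.  Peripheral (neo-)vascularization pushes the value up; above
  0.5 leans malignant.  For a uniformly vascularized convex node the
  value sits near 2/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .colorspace import ANY_COLOR, HSVRange, in_hsv_range
from .core import mask_to_contour, polygon_to_mask
from .errors import EmptyMaskError, ModalityError, UndefinedPositionError

__all__ = [
    "DopplerMetrics",
    "colored_pixel_mask",
    "vascularity_percentage",
    "vascularity_position",
    "doppler_flags",
    "analyze_doppler",
]

LOW_VASCULARITY_PCT = 25.0
PERIPHERAL_POSITION = 0.5


@dataclass(frozen=True)
class DopplerMetrics:
    vascularity_percentage: float
    vascularity_position: Optional[float]  # None when no colored pixel in mask
    colored_pixel_count: int
    mask_pixel_count: int
    low_vascularity_flag: bool
    peripheral_vascularity_flag: Optional[bool]

    def to_dict(self) -> dict:
        out = {
            "vascularity_percentage": self.vascularity_percentage,
            "colored_pixel_count": self.colored_pixel_count,
            "mask_pixel_count": self.mask_pixel_count,
        }
        if self.vascularity_position is not None:
            out["vascularity_position"] = self.vascularity_position
        return out


def colored_pixel_mask(image: np.ndarray, rng: HSVRange = ANY_COLOR) -> np.ndarray:
    """Pixels whose byte HSV falls in ``rng``; the default range selects
    every pixel carrying any color at all (saturation and value >= 1)."""
    arr = np.asarray(image)
    if arr.ndim != 3:
        raise ModalityError("Doppler analysis needs a 3-channel color image")
    return in_hsv_range(arr, rng)


def vascularity_percentage(
    image: np.ndarray, ln_mask: np.ndarray, rng: HSVRange = ANY_COLOR
) -> float:
    """Percentage of node pixels that carry color (flow signal)."""
    mask = np.asarray(ln_mask, dtype=bool)
    total = int(mask.sum())
    if total == 0:
        raise EmptyMaskError("node mask is empty")
    colored = colored_pixel_mask(image, rng)
    return 100.0 * int((colored & mask).sum()) / total


def vascularity_position(
    image: np.ndarray,
    ln_contour: np.ndarray,
    ln_mask: np.ndarray,
    rng: HSVRange = ANY_COLOR,
) -> float:
    """Centroid-normalized radial position of the flow signal.

    The centroid is the area centroid of the filled mask; the numerator
    averages colored in-mask pixel distances to it and the denominator
    averages rasterized-contour pixel distances, so 0 means flow at the
    hilum/center and values near (or slightly above) 1 mean flow hugging
    the capsule.
    """
    mask = np.asarray(ln_mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("node mask is empty")
    colored = colored_pixel_mask(image, rng) & mask
    if not colored.any():
        raise UndefinedPositionError("no colored pixel inside the node mask")

    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()

    cr, cc = np.nonzero(colored)
    num = np.hypot(cc - cx, cr - cy).mean()

    boundary = mask_to_contour(polygon_to_mask(ln_contour, *mask.shape))
    den = np.hypot(boundary[:, 0] - cx, boundary[:, 1] - cy).mean()
    return float(num / den)


def doppler_flags(
    percentage: float,
    position: Optional[float],
    low_threshold: float = LOW_VASCULARITY_PCT,
    position_threshold: float = PERIPHERAL_POSITION,
) -> tuple[bool, Optional[bool]]:
    """Malignancy-indicator flags: percentage strictly below 25% and
    position strictly above 0.5 (both boundaries exclusive)."""
    low = percentage < low_threshold
    peripheral = None if position is None else position > position_threshold
    return low, peripheral


def analyze_doppler(
    image: np.ndarray,
    ln_contour: np.ndarray,
    ln_mask: np.ndarray,
    rng: HSVRange = ANY_COLOR,
    low_threshold: float = LOW_VASCULARITY_PCT,
    position_threshold: float = PERIPHERAL_POSITION,
) -> DopplerMetrics:
    """Full Doppler record for one node."""
    mask = np.asarray(ln_mask, dtype=bool)
    total = int(mask.sum())
    if total == 0:
        raise EmptyMaskError("node mask is empty")
    colored = colored_pixel_mask(image, rng) & mask
    count = int(colored.sum())
    pct = 100.0 * count / total
    try:
        pos: Optional[float] = vascularity_position(image, ln_contour, mask, rng)
    except UndefinedPositionError:
        pos = None
    low, peripheral = doppler_flags(pct, pos, low_threshold, position_threshold)
    return DopplerMetrics(
        vascularity_percentage=pct,
        vascularity_position=pos,
        colored_pixel_count=count,
        mask_pixel_count=total,
        low_vascularity_flag=low,
        peripheral_vascularity_flag=peripheral,
    )
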