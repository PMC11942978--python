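"""Elastography stiffness quantification on duplex frames.

Strain elastography is usually exported as a duplex frame: a plain B-mode
panel and an elastogram panel side by side, the elastogram carrying a
semi-transparent color map (here blue = hard, red = soft; the map is
configurable for other vendors).  The node contour is detected on the
B-mode panel and must be translated horizontally by half the width of the
ultrasound content region onto the elastogram before color quantification.

The color classes are hue bands on the byte HSV scale (saturation and
value >= 1):

========  ==================
class     hue band
========  ==================
red       0-39 and 136-180
green     40-79
blue      80-135
========  ==================

The malignancy indicator fires when the hard fraction (green + blue under
the default map) strictly exceeds 40% of the node pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import disk, opening

from .colorspace import HSVRange, in_hsv_range, rgb_to_hsv_bytes
from .core import as_contour
from .errors import (
    DetectionFailureError,
    EmptyMaskError,
    ModalityError,
    NoElastogramError,
    SideTieError,
    TranslationOutOfBoundsError,
)

logger = logging.getLogger("echonode")

__all__ = [
    "ElastoMetrics",
    "PanelLayout",
    "RED_RANGES",
    "GREEN_RANGE",
    "BLUE_RANGE",
    "detect_ultrasound_region",
    "detect_colored_side",
    "remove_color_scale",
    "translate_contour",
    "color_region_percentages",
    "stiffness_flag",
]

#: hue bands (byte scale); red wraps around the top of the hue circle
RED_RANGES = (HSVRange(0, 39, 1, 255, 1, 255), HSVRange(136, 180, 1, 255, 1, 255))
GREEN_RANGE = HSVRange(40, 79, 1, 255, 1, 255)
BLUE_RANGE = HSVRange(80, 135, 1, 255, 1, 255)

#: loose "any visible color" box used for panel-side detection
_SIDE_RANGE = HSVRange(0, 180, 10, 255, 10, 255)

HARD_THRESHOLD_PCT = 40.0


@dataclass(frozen=True)
class ElastoMetrics:
    red_pct: float
    green_pct: float
    blue_pct: float
    hard_fraction_pct: float
    stiffness_flag: bool

    def to_dict(self) -> dict:
        return {
            "red_pct": self.red_pct,
            "green_pct": self.green_pct,
            "blue_pct": self.blue_pct,
            "hard_fraction_pct": self.hard_fraction_pct,
        }


@dataclass(frozen=True)
class PanelLayout:
    """Detected duplex geometry: the ultrasound content rectangle
    (x, y, w, h), which side carries the elastogram, and the implied
    panel width (half the content width)."""

    us_region: tuple[int, int, int, int]
    colored_side: str  # "left" | "right"

    @property
    def panel_width(self) -> float:
        return self.us_region[2] / 2.0


def _intensity(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim == 3:
        return arr.max(axis=-1).astype(np.uint8)  # HSV value channel
    return arr.astype(np.uint8)


def detect_ultrasound_region(
    image: np.ndarray,
    min_area_fraction: float = 0.10,
    smooth_sigma: float = 1.0,
    opening_radius: int = 2,
) -> tuple[int, int, int, int]:
    """Bounding rectangle (x, y, w, h) of the ultrasound content.

    Smoothing, a small morphological opening and Otsu binarization
    separate the bright scan content from the dark margins and UI chrome;
    the largest connected component wins.  Fails when that component
    covers less than ``min_area_fraction`` of the frame.
    """
    inten = _intensity(image).astype(np.float64)
    if inten.max() < 10:
        raise DetectionFailureError("frame is uniformly dark; no content found")
    smooth = ndi.gaussian_filter(inten, smooth_sigma)
    opened = opening(smooth, disk(opening_radius))
    thr = threshold_otsu(opened)
    binary = opened > thr
    labels, n = _cc_label(binary, connectivity=2, return_num=True)
    if n == 0:
        raise DetectionFailureError("no connected component above threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    if counts[biggest] < min_area_fraction * inten.size:
        raise DetectionFailureError(
            f"largest component covers {counts[biggest] / inten.size:.1%} "
            f"of the frame (< {min_area_fraction:.0%})"
        )
    rows, cols = np.nonzero(labels == biggest)
    x, y = int(cols.min()), int(rows.min())
    return (x, y, int(cols.max() - x + 1), int(rows.max() - y + 1))


def detect_colored_side(image: np.ndarray, rng: HSVRange = _SIDE_RANGE) -> str:
    """Which half of the frame carries the elastogram overlay.

    Counts visibly colored pixels (saturation and value >= 10) left and
    right of the vertical midline.  Raises when neither half has any, or
    on an exact tie.
    """
    arr = np.asarray(image)
    if arr.ndim != 3:
        raise ModalityError("colored-side detection needs a color image")
    colored = in_hsv_range(arr, rng)
    half = arr.shape[1] // 2
    left = int(colored[:, :half].sum())
    right = int(colored[:, half:].sum())
    if left == 0 and right == 0:
        raise NoElastogramError("no colored pixels in either half of the frame")
    if left == right:
        raise SideTieError(f"equal colored counts left/right ({left})")
    return "left" if left > right else "right"


def remove_color_scale(
    image: np.ndarray,
    max_width_fraction: float = 0.05,
    min_aspect: float = 4.0,
    edge_fraction: float = 0.10,
) -> np.ndarray:
    """Blank any color-scale legend bar near a vertical frame edge.

    Scanners often burn a tall, narrow rainbow legend next to the
    elastogram; left in place it can flip the colored-side vote.  Any
    high-saturation connected component that is at least ``min_aspect``
    times taller than wide, no wider than ``max_width_fraction`` of the
    frame and entirely within ``edge_fraction`` of the left or right edge
    is blacked out.  Best-effort: when nothing matches, the image is
    returned unchanged.
    """
    arr = np.asarray(image)
    if arr.ndim != 3:
        return arr
    h, w = arr.shape[:2]
    colored = in_hsv_range(arr, _SIDE_RANGE)
    edge = int(np.ceil(edge_fraction * w))
    in_edge = np.zeros_like(colored)
    in_edge[:, :edge] = True
    in_edge[:, w - edge:] = True
    candidates = colored & in_edge
    if not candidates.any():
        return arr
    out = arr.copy()
    labels, n = _cc_label(candidates, connectivity=2, return_num=True)
    removed = 0
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        bw = cols.max() - cols.min() + 1
        bh = rows.max() - rows.min() + 1
        if bh / bw >= min_aspect and bw <= max_width_fraction * w:
            out[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1] = 0
            removed += 1
    if removed:
        logger.debug("removed %d color-scale candidate bar(s)", removed)
    return out


def translate_contour(
    contour: np.ndarray,
    layout: PanelLayout,
    frame_shape: tuple[int, ...],
    paper_literal: bool = False,
) -> np.ndarray:
    """Shift a B-mode-panel contour horizontally onto the elastogram panel.

    The shift is half the ultrasound-region width, toward the colored
    side; y-coordinates are untouched.  ``paper_literal`` selects the
    opposite sign convention (add when the colored side is left) for
    compatibility with pipelines that define the shift that way.
    """
    pts = as_contour(contour).copy()
    shift = layout.panel_width
    toward_left = layout.colored_side == "left"
    if paper_literal:
        toward_left = not toward_left
    pts[:, 0] += -shift if toward_left else shift
    h, w = frame_shape[0], frame_shape[1]
    if pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1:
        raise TranslationOutOfBoundsError(
            f"translated contour leaves the frame (x in "
            f"[{pts[:, 0].min():.0f}, {pts[:, 0].max():.0f}], width {w})"
        )
    return pts


def class_masks(image: np.ndarray) -> dict[str, np.ndarray]:
    """Per-class boolean masks for the red/green/blue hue bands."""
    arr = np.asarray(image)
    red = in_hsv_range(arr, RED_RANGES[0]) | in_hsv_range(arr, RED_RANGES[1])
    return {
        "red": red,
        "green": in_hsv_range(arr, GREEN_RANGE),
        "blue": in_hsv_range(arr, BLUE_RANGE),
    }


def color_region_percentages(
    image: np.ndarray,
    elasto_mask: np.ndarray,
    hard_classes: tuple[str, ...] = ("green", "blue"),
    hard_threshold_pct: float = HARD_THRESHOLD_PCT,
) -> ElastoMetrics:
    """Red/green/blue area percentages inside the (translated) node mask,
    plus the hard-tissue fraction and its malignancy flag.

    Percentages are taken over all mask pixels, so uncolored (saturation
    0) pixels dilute every class and the three classes plus the
    uncolored remainder always partition the mask.
    """
    mask = np.asarray(elasto_mask, dtype=bool)
    total = int(mask.sum())
    if total == 0:
        raise EmptyMaskError("elastogram mask is empty")
    masks = class_masks(image)
    pct = {k: 100.0 * int((m & mask).sum()) / total for k, m in masks.items()}
    hard = sum(pct[c] for c in hard_classes)
    return ElastoMetrics(
        red_pct=pct["red"],
        green_pct=pct["green"],
        blue_pct=pct["blue"],
        hard_fraction_pct=hard,
        stiffness_flag=stiffness_flag(hard, hard_threshold_pct),
    )


def stiffness_flag(hard_fraction_pct: float, threshold_pct: float = HARD_THRESHOLD_PCT) -> bool:
    """True when the hard-tissue fraction strictly exceeds the threshold
    (40% by default)."""
    return hard_fraction_pct > threshold_pct


def analyze_elasto(
    image: np.ndarray,
    bmode_contour: np.ndarray,
    hard_classes: tuple[str, ...] = ("green", "blue"),
    hard_threshold_pct: float = HARD_THRESHOLD_PCT,
    paper_literal_translation: bool = False,
    strip_color_scale: bool = True,
    layout: Optional[PanelLayout] = None,
) -> tuple[ElastoMetrics, PanelLayout, np.ndarray]:
    """Full duplex pipeline: scale-bar removal, content-region and
    colored-side detection, contour translation, color quantification.

    Returns the metrics, the detected layout and the translated contour.
    """
    from .core import polygon_to_mask  # local import to avoid cycle noise

    arr = np.asarray(image)
    if arr.ndim != 3:
        raise ModalityError("elastography analysis needs a color duplex frame")
    clean = remove_color_scale(arr) if strip_color_scale else arr
    if layout is None:
        region = detect_ultrasound_region(clean)
        side = detect_colored_side(clean)
        layout = PanelLayout(us_region=region, colored_side=side)
    translated = translate_contour(
        bmode_contour, layout, arr.shape, paper_literal=paper_literal_translation
    )
    mask = polygon_to_mask(translated, arr.shape[0], arr.shape[1])
    metrics = color_region_percentages(clean, mask, hard_classes, hard_threshold_pct)
    return metrics, layout, translated
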