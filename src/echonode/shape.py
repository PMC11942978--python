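"""Lymph-node shape morphology.

A metastatic node tends to become rounder (short/long axis ratio rising
toward 1), thicker (short diameter >= 10 mm), and more irregular in
outline.  This module measures:

* the long and short axes of the minimum-area rotated rectangle enclosing
  the contour, in pixels and millimetres;
* the Solbiati index (long/short); >= 2 leans benign, <= 1.5 leans
  malignant, the band in between is indeterminate;
* a shape-variability score: the Hu-moment distance between the contour
  and its own least-squares fitted ellipse, so a smooth oval scores near
  zero and a lobulated outline scores high.  Hu invariants are computed
  analytically from the polygon (Green's theorem), making the score
  independent of rasterization and invariant to translation, rotation and
  uniform scale.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from shapely.geometry import MultiPoint, Polygon
from skimage.measure import EllipseModel

from .core import Calibration, as_contour, validate_contour
from .errors import (
    DegenerateShapeError,
    FitFailureError,
    InvalidMeasureError,
    TooFewPointsError,
)

__all__ = [
    "ShapeMetrics",
    "min_area_axes",
    "shape_metrics",
    "solbiati_class",
    "thickness_flag",
    "fit_ellipse",
    "shape_variability",
    "polygon_hu_moments",
]

SOLBIATI_BENIGN = 2.0
SOLBIATI_MALIGNANT = 1.5
THICKNESS_MM = 10.0


@dataclass(frozen=True)
class ShapeMetrics:
    long_axis_px: float
    short_axis_px: float
    long_axis_mm: float
    short_axis_mm: float
    axis_ratio: float          # short/long, in (0, 1]
    solbiati_index: float      # long/short, >= 1
    shape_variability: float   # Hu-moment distance to the fitted ellipse
    area_px: float
    orientation_deg: float     # long-axis direction from the x-axis, [0, 180)

    def to_dict(self) -> dict:
        return asdict(self)


def min_area_axes(contour: np.ndarray) -> tuple[float, float, float]:
    """Side lengths and orientation of the minimum-area enclosing rectangle.

    Returns ``(long_px, short_px, orientation_deg)`` with the orientation
    of the long axis measured from the x-axis in [0, 180).  Collinear
    input raises :class:`DegenerateShapeError`.
    """
    pts = validate_contour(contour)
    rect = MultiPoint([tuple(p) for p in pts]).minimum_rotated_rectangle
    if not isinstance(rect, Polygon):
        raise DegenerateShapeError("contour points are collinear")
    corners = np.asarray(rect.exterior.coords[:-1], dtype=np.float64)
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = float(np.hypot(*e1)), float(np.hypot(*e2))
    if min(l1, l2) <= 1e-12:
        raise DegenerateShapeError("contour points are collinear")
    if l1 >= l2:
        long_px, short_px, axis = l1, l2, e1
    else:
        long_px, short_px, axis = l2, l1, e2
    angle = float(np.degrees(np.arctan2(axis[1], axis[0]))) % 180.0
    return long_px, short_px, angle


def solbiati_class(solbiati_index: float) -> str:
    """Classify the long/short ratio against the Solbiati cut-offs:
    >= 2 benign-leaning, <= 1.5 malignant-leaning, otherwise
    indeterminate."""
    if solbiati_index < 1:
        raise InvalidMeasureError(
            f"Solbiati index is long/short and cannot be < 1, got {solbiati_index}"
        )
    if solbiati_index >= SOLBIATI_BENIGN:
        return "benign_leaning"
    if solbiati_index <= SOLBIATI_MALIGNANT:
        return "malignant_leaning"
    return "indeterminate"


def thickness_flag(short_axis_mm: float, threshold_mm: float = THICKNESS_MM) -> bool:
    """True when the short diameter reaches the metastasis marker
    (>= 10 mm by default)."""
    if not short_axis_mm > 0:
        raise InvalidMeasureError(f"short axis must be > 0 mm, got {short_axis_mm}")
    return short_axis_mm >= threshold_mm


# ---------------------------------------------------------------------------
# Hu-moment shape variability
# ---------------------------------------------------------------------------

def _polygon_raw_moments(pts: np.ndarray) -> dict[tuple[int, int], float]:
    """Area moments m_pq of a closed polygon up to order 3 via Green's
    theorem (exact; no rasterization).  Vertices are normalized to
    counter-clockwise orientation first so the area is positive."""
    x = pts[:, 0]
    y = pts[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        pts = pts[::-1]
        x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    a = x * y1 - x1 * y  # per-edge cross product

    m = {}
    m[0, 0] = np.sum(a) / 2.0
    m[1, 0] = np.sum(a * (x + x1)) / 6.0
    m[0, 1] = np.sum(a * (y + y1)) / 6.0
    m[2, 0] = np.sum(a * (x * x + x * x1 + x1 * x1)) / 12.0
    m[1, 1] = np.sum(a * (2 * x * y + x * y1 + x1 * y + 2 * x1 * y1)) / 24.0
    m[0, 2] = np.sum(a * (y * y + y * y1 + y1 * y1)) / 12.0
    m[3, 0] = np.sum(a * (x**3 + x * x * x1 + x * x1 * x1 + x1**3)) / 20.0
    m[0, 3] = np.sum(a * (y**3 + y * y * y1 + y * y1 * y1 + y1**3)) / 20.0
    m[2, 1] = np.sum(
        a * (3 * x * x * y + 2 * x * x1 * y + x1 * x1 * y
             + x * x * y1 + 2 * x * x1 * y1 + 3 * x1 * x1 * y1)
    ) / 60.0
    m[1, 2] = np.sum(
        a * (3 * y * y * x + 2 * y * y1 * x + y1 * y1 * x
             + y * y * x1 + 2 * y * y1 * x1 + 3 * y1 * y1 * x1)
    ) / 60.0
    return {k: float(v) for k, v in m.items()}


def polygon_hu_moments(contour: np.ndarray) -> np.ndarray:
    """The seven Hu invariants of a polygon's interior region.

    Central moments are obtained by re-evaluating the Green's-theorem
    sums on centroid-translated vertices; normalized moments
    eta_pq = mu_pq / mu00^((p+q)/2 + 1) then feed the classical Hu
    combinations, invariant to translation, rotation and uniform scale.
    """
    pts = as_contour(contour)
    m = _polygon_raw_moments(pts)
    if abs(m[0, 0]) < 1e-12:
        raise DegenerateShapeError("polygon has zero area")
    cx, cy = m[1, 0] / m[0, 0], m[0, 1] / m[0, 0]
    mu = _polygon_raw_moments(pts - [cx, cy])

    a = mu[0, 0]
    eta = {pq: mu[pq] / a ** ((pq[0] + pq[1]) / 2.0 + 1.0) for pq in mu}
    n20, n02, n11 = eta[2, 0], eta[0, 2], eta[1, 1]
    n30, n03, n21, n12 = eta[3, 0], eta[0, 3], eta[2, 1], eta[1, 2]

    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    h7 = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return np.array([h1, h2, h3, h4, h5, h6, h7])


#: invariants below this magnitude are treated as exactly zero: genuine
#: Hu values of visibly asymmetric shapes sit at 1e-7 or above, while
#: symmetric shapes produce pure floating-point noise around 1e-30
_HU_ZERO = 1e-12


def _hu_distance(hu_a: np.ndarray, hu_b: np.ndarray) -> float:
    """Reciprocal-log Hu distance: sum_i |1/m_i(A) - 1/m_i(B)| with
    m_i = sign(h_i) * log10 |h_i|; terms with a zero invariant on either
    shape are skipped."""
    total = 0.0
    for ha, hb in zip(hu_a, hu_b):
        if abs(ha) < _HU_ZERO or abs(hb) < _HU_ZERO:
            continue
        ma = np.sign(ha) * np.log10(abs(ha))
        mb = np.sign(hb) * np.log10(abs(hb))
        if ma == 0 or mb == 0:
            continue
        total += abs(1.0 / ma - 1.0 / mb)
    return float(total)


def fit_ellipse(contour: np.ndarray, n_samples: int = 360) -> np.ndarray:
    """Direct least-squares ellipse fit to the contour points, returned as
    an ``n_samples``-point polygon.  Needs >= 5 points."""
    pts = as_contour(contour)
    if len(pts) < 5:
        raise TooFewPointsError(
            f"ellipse fitting needs >= 5 points, got {len(pts)}"
        )
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise FitFailureError(f"direct ellipse fit failed: {model}")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise FitFailureError("direct ellipse fit returned non-finite parameters")
    if a <= 0 or b <= 0:
        raise FitFailureError("degenerate fitted ellipse")
    t = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    xs = xc + a * np.cos(t) * ct - b * np.sin(t) * st
    ys = yc + a * np.cos(t) * st + b * np.sin(t) * ct
    return np.column_stack([xs, ys])


def shape_variability(contour: np.ndarray, n_samples: int = 360) -> float:
    """Hu-moment distance between the contour and its fitted ellipse.

    Zero for a perfectly elliptical outline; grows with lobulation and
    boundary irregularity.
    """
    pts = as_contour(contour)
    ellipse = fit_ellipse(pts, n_samples=n_samples)
    return _hu_distance(polygon_hu_moments(pts), polygon_hu_moments(ellipse))


def shape_metrics(contour: np.ndarray, calibration: Calibration) -> ShapeMetrics:
    """Full shape record: rectangle axes (px and mm), axis ratio, Solbiati
    index, area, and Hu shape variability when the contour supports an
    ellipse fit."""
    pts = validate_contour(contour)
    long_px, short_px, angle = min_area_axes(pts)
    try:
        variability = shape_variability(pts)
    except (TooFewPointsError, FitFailureError):
        variability = float("nan")
    area = abs(
        0.5 * float(np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1]))
    )
    return ShapeMetrics(
        long_axis_px=long_px,
        short_axis_px=short_px,
        long_axis_mm=calibration.to_mm(long_px),
        short_axis_mm=calibration.to_mm(short_px),
        axis_ratio=short_px / long_px,
        solbiati_index=long_px / short_px,
        shape_variability=variability,
        area_px=area,
        orientation_deg=angle,
    )
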