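"""Core image/mask/contour plumbing shared by every analysis module.

Conventions (used everywhere in the package):

* Images are numpy ``uint8`` arrays, shape ``(H, W)`` for grayscale or
  ``(H, W, 3)`` for RGB color.
* Binary masks are boolean arrays of shape ``(H, W)``.
* Contours are ``(N, 2)`` float arrays of ``(x, y)`` pixel coordinates,
  ``x`` = column, ``y`` = row, 0-based, origin at the top-left corner.
  The polygon is implicitly closed (last point connects to the first).
* Polygon fill is even-odd and boundary-inclusive: a pixel whose center
  lies exactly on a polygon edge counts as foreground, matching the
  semantics of an annotator tracing the lymph-node capsule.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
from PIL import Image, ImageDraw
from skimage.measure import label as _cc_label

from .errors import (
    AnnotationError,
    EmptyMaskError,
    InvalidContourError,
    InvalidMeasureError,
)

logger = logging.getLogger("echonode")

__all__ = [
    "Calibration",
    "AnalysisReport",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "validate_contour",
    "polygon_to_mask",
    "mask_to_contour",
    "largest_component",
    "read_annotations",
    "render_overlay",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale of one acquired frame.

    Ultrasound scanners burn a depth ruler into each frame; the ratio is
    therefore frame-specific and must be supplied per image.
    """

    px_per_mm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.px_per_mm) or self.px_per_mm <= 0:
            raise InvalidMeasureError(
                f"px_per_mm must be finite and > 0, got {self.px_per_mm!r}"
            )

    def to_mm(self, px: float) -> float:
        return px / self.px_per_mm


@dataclass
class AnalysisReport:
    """Per-lymph-node record of all computed metrics and indicator flags.

    Metric groups are optional by modality (a B-mode frame has no Doppler
    metrics); a flag is present only when its underlying metric is.
    Serializes losslessly to JSON.
    """

    image_id: str = ""
    modality: str = ""
    shape: Optional[dict] = None
    contour: Optional[dict] = None
    doppler: Optional[dict] = None
    elasto: Optional[dict] = None
    flags: Optional[dict] = None
    config: Optional[dict] = None

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"image_id": self.image_id, "modality": self.modality}
        for key in ("shape", "contour", "doppler", "elasto", "flags", "config"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisReport":
        return cls(
            image_id=data.get("image_id", ""),
            modality=data.get("modality", ""),
            **{k: data.get(k) for k in ("shape", "contour", "doppler", "elasto", "flags", "config")},
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# image / mask file IO
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/JPEG/TIFF image as a grayscale or RGB array."""
    with Image.open(path) as img:
        if img.mode in ("L", "I;16", "I"):
            arr = np.asarray(img.convert("L"))
        else:
            arr = np.asarray(img.convert("RGB"))
    return arr.astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask PNG; any nonzero pixel is foreground."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255))).save(path)


# ---------------------------------------------------------------------------
# contours and masks
# ---------------------------------------------------------------------------

def as_contour(points: Any) -> np.ndarray:
    """Coerce a point sequence to an (N, 2) float64 contour array."""
    arr = np.asarray(points, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidContourError(f"contour must be (N, 2), got shape {arr.shape}")
    return arr


def validate_contour(
    contour: np.ndarray, height: int | None = None, width: int | None = None
) -> np.ndarray:
    """Validate the contour invariants: >= 3 points, no consecutive
    duplicates, all points inside the frame when a frame size is given."""
    arr = as_contour(contour)
    if len(arr) < 3:
        raise InvalidContourError(f"contour needs >= 3 points, got {len(arr)}")
    closed = np.vstack([arr, arr[:1]])
    if np.any(np.all(np.diff(closed, axis=0) == 0, axis=1)):
        raise InvalidContourError("contour has consecutive duplicate points")
    if height is not None and width is not None:
        x, y = arr[:, 0], arr[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() > width - 1 or y.max() > height - 1:
            raise InvalidContourError(
                f"contour exceeds frame bounds {width}x{height}: "
                f"x in [{x.min()}, {x.max()}], y in [{y.min()}, {y.max()}]"
            )
    return arr


def _polygon_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_to_mask(contour: np.ndarray, height: int, width: int) -> np.ndarray:
    """Rasterize a polygon to a boolean mask, even-odd fill, boundary
    inclusive (pixel centers exactly on an edge are foreground).

    Raises :class:`InvalidContourError` for polygons with fewer than 3
    points or with zero area (collinear vertices).
    """
    poly = validate_contour(contour, height, width)
    if abs(_polygon_area(poly)) < 1e-12:
        raise InvalidContourError("degenerate polygon: vertices are collinear")

    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())), width - 1)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())), height - 1)

    xs, ys = np.meshgrid(
        np.arange(x0, x1 + 1, dtype=np.float64),
        np.arange(y0, y1 + 1, dtype=np.float64),
    )
    inside = np.zeros(xs.shape, dtype=bool)
    on_edge = np.zeros(xs.shape, dtype=bool)

    closed = np.vstack([poly, poly[:1]])
    eps = 1e-9
    for (xa, ya), (xb, yb) in zip(closed[:-1], closed[1:]):
        # even-odd crossing number: edge crosses the horizontal ray at y
        crosses = (ya > ys) != (yb > ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = xa + (ys - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (xs < x_at)

        # boundary-inclusive: pixel center on the closed segment
        dx, dy = xb - xa, yb - ya
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            on_edge |= (np.abs(xs - xa) < eps) & (np.abs(ys - ya) < eps)
            continue
        t = ((xs - xa) * dx + (ys - ya) * dy) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        d2 = (xs - (xa + t * dx)) ** 2 + (ys - (ya + t * dy)) ** 2
        on_edge |= d2 < eps

    mask = np.zeros((height, width), dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside | on_edge
    return mask


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Multiple components indicate either detector noise or a second node in
    frame; the analysis is per-node, so extras are dropped with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask has no foreground pixel")
    labels, n = _cc_label(mask, connectivity=2, return_num=True)
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    warnings.warn(
        f"mask has {n} foreground components; keeping the largest "
        f"({counts[keep]} px) and ignoring the rest",
        stacklevel=2,
    )
    return labels == keep


_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
# (dr, dc) in clockwise order starting east


def mask_to_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the largest 8-connected component.

    Moore-neighbor tracing with Jacob's stopping criterion; the returned
    boundary pixel chain is oriented so its shoelace signed area (in x/y
    with y pointing down the rows) is non-negative.  A single-pixel
    component yields a 1-point contour (rejected downstream by operations
    that need a polygon).
    """
    comp = largest_component(mask)
    rows, cols = np.nonzero(comp)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost

    h, w = comp.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(comp[r, c])

    # no foreground neighbor -> single-pixel component
    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return np.array([[start[1], start[0]]], dtype=np.float64)

    boundary: list[tuple[int, int]] = [start]
    # backtrack: we conceptually arrived at start from the west
    cur = start
    back = 4  # index of west in _MOORE
    first_move: tuple[tuple[int, int], int] | None = None
    limit = 4 * (len(rows) + 2)

    for _ in range(limit):
        found = None
        for k in range(1, 9):
            d = (back + k) % 8
            dr, dc = _MOORE[d]
            if fg(cur[0] + dr, cur[1] + dc):
                found = d
                break
        assert found is not None
        nxt = (cur[0] + _MOORE[found][0], cur[1] + _MOORE[found][1])
        if first_move is None:
            first_move = (nxt, found)
        elif cur == start and (nxt, found) == first_move:
            break  # Jacob's criterion: repeating the initial move
        boundary.append(nxt)
        # new backtrack points at the previous pixel
        back = (found + 4) % 8
        # skip candidates before the one just after the previous pixel:
        # restart clockwise scan from the neighbor after the backtrack
        cur = nxt

    if boundary[-1] == start:
        boundary.pop()
    contour = np.array([[c, r] for r, c in boundary], dtype=np.float64)
    if len(contour) >= 3 and _polygon_area(contour) < 0:
        contour = contour[::-1]
    return contour


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read COCO-style polygon annotations.

    Returns one ``(image_id, contour)`` record per annotation.  Polygon
    segmentations are flat ``[x1, y1, x2, y2, ...]`` lists; RLE
    segmentations are deliberately unsupported, and out-of-bounds points
    raise a validation error naming the offending annotation.
    """
    with open(path) as fh:
        doc = json.load(fh)
    try:
        images = {img["id"]: img for img in doc["images"]}
        annotations = doc["annotations"]
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"not a COCO-style annotation file: {path}") from exc

    records: list[tuple[str, np.ndarray]] = []
    for ann in annotations:
        ann_id = ann.get("id", "?")
        img_id = ann.get("image_id")
        if img_id not in images:
            raise AnnotationError(
                f"annotation {ann_id} references missing image id {img_id!r}"
            )
        seg = ann.get("segmentation")
        if isinstance(seg, dict) or (
            isinstance(seg, list) and seg and isinstance(seg[0], dict)
        ):
            raise AnnotationError(
                f"annotation {ann_id}: RLE segmentation is unsupported"
            )
        if not isinstance(seg, list) or not seg:
            raise AnnotationError(f"annotation {ann_id}: missing polygon segmentation")
        flat = seg[0] if isinstance(seg[0], (list, tuple)) else seg
        if len(flat) < 6 or len(flat) % 2 != 0:
            raise AnnotationError(
                f"annotation {ann_id}: polygon needs >= 3 (x, y) pairs"
            )
        contour = np.asarray(flat, dtype=np.float64).reshape(-1, 2)
        img = images[img_id]
        try:
            contour = validate_contour(contour, img["height"], img["width"])
        except InvalidContourError as exc:
            raise AnnotationError(f"annotation {ann_id}: {exc}") from exc
        records.append((str(img_id), contour))
    return records


# ---------------------------------------------------------------------------
# overlay rendering
# ---------------------------------------------------------------------------

def _report_lines(report: AnalysisReport) -> list[str]:
    lines = []
    if report.shape:
        lines.append(f"Long axis: {report.shape['long_axis_mm']:.1f} mm")
        lines.append(f"Short axis: {report.shape['short_axis_mm']:.1f} mm")
        lines.append(f"Solbiati: {report.shape['solbiati_index']:.2f}")
        if "shape_variability" in report.shape:
            lines.append(f"Variability: {report.shape['shape_variability']:.3f}")
    if report.contour:
        lines.append(f"Sharpness: {report.contour['sharpness']:.3f}")
    if report.doppler:
        lines.append(f"Color: {report.doppler['vascularity_percentage']:.1f}%")
        if "vascularity_position" in report.doppler:
            lines.append(f"Position: {report.doppler['vascularity_position']:.2f}")
    if report.elasto:
        lines.append(f"Red: {report.elasto['red_pct']:.1f}%")
        lines.append(f"Green: {report.elasto['green_pct']:.1f}%")
        lines.append(f"Blue: {report.elasto['blue_pct']:.1f}%")
    return lines


def render_overlay(
    image: np.ndarray,
    predicted: np.ndarray,
    report: AnalysisReport,
    reference: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Render the reference contour (red), predicted contour (green) and a
    metric text block on the left margin.  The input image is not modified."""
    arr = np.asarray(image, dtype=np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    canvas = Image.fromarray(arr.copy())
    draw = ImageDraw.Draw(canvas)
    if reference is not None:
        pts = [tuple(p) for p in as_contour(reference)]
        draw.polygon(pts, outline=(255, 0, 0))
    pts = [tuple(p) for p in as_contour(predicted)]
    draw.polygon(pts, outline=(0, 255, 0))
    for i, line in enumerate(_report_lines(report)):
        draw.text((4, 4 + 12 * i), line, fill=(0, 255, 0))
    return np.asarray(canvas)
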