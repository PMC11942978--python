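"""Synthetic multimodal ultrasound phantoms.

The clinical frames the analysis modules were designed for cannot ship
with the package, so this module generates stand-ins with exactly known
ground truth:

* **B-mode**: a speckled bright background with a darker elliptical (or
  star-shaped) node whose boundary blur is controlled by ``blur_sigma``.
  Speckle is multiplicative noise on a smooth base — visually adequate
  for edge and color logic, with no acoustic simulation attempted.
* **Doppler**: the B-mode base as a gray RGB frame plus fully saturated
  color blobs inside the node.  The painted pixel count is budgeted
  exactly (``round(fraction * area)`` pixels), and blob placement is
  controlled by ``blob_offset`` (0 = node centroid, 1 = boundary).
* **Elastography duplex**: two equal-width panels inside a dark margin;
  the B-mode panel carries the node, the elastogram panel a
  semi-transparent overlay with exact red/green/blue area budgets inside
  the mirrored node region, plus an optional edge color-scale bar.

Default frame size is 760 x 574 (the smallest common scanner export
size), and every generator is deterministic in its seed.  Ground truth is
returned as a :class:`PhantomTruth` so tests never re-derive truth from
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .colorspace import hsv_bytes_to_rgb
from .core import polygon_to_mask
from .errors import InvalidParamsError

__all__ = [
    "PhantomTruth",
    "ellipse_contour",
    "star_contour",
    "make_bmode_phantom",
    "make_doppler_phantom",
    "make_elasto_duplex",
    "FRAME_SHAPE",
]

FRAME_SHAPE = (574, 760)  # rows, cols

#: default node intensities: strongly hypoechoic node on bright tissue,
#: so a zero-blur boundary is a near-maximal intensity step
LN_INTENSITY = 5.0
BG_INTENSITY = 245.0

#: byte-scale hues at the center of each stiffness class
CLASS_HUES = {"red": 0, "green": 60, "blue": 120}


@dataclass
class PhantomTruth:
    """Exact generator parameters, recorded as used."""

    contour: np.ndarray
    mask: np.ndarray
    modality: str
    seed: int
    blur_sigma: float = 0.0
    noise_level: float = 0.0
    vascularity_fraction: Optional[float] = None
    blob_offset: Optional[float] = None
    colored_count: Optional[int] = None
    color_fractions: Optional[tuple[float, float, float]] = None
    color_counts: Optional[dict] = None
    colored_side: Optional[str] = None
    scale_bar: bool = False
    us_region: Optional[tuple[int, int, int, int]] = None
    panel_width: Optional[int] = None
    elasto_contour: Optional[np.ndarray] = field(default=None)

    @property
    def mask_area(self) -> int:
        return int(self.mask.sum())


def ellipse_contour(
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation_deg: float = 0.0,
    n_points: int = 360,
) -> np.ndarray:
    """Ellipse polygon: center (x, y), semi-axes (a, b), rotation in
    degrees."""
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    a, b = axes
    th = np.radians(rotation_deg)
    x = center[0] + a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
    y = center[1] + a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
    return np.column_stack([x, y])


def star_contour(
    center: tuple[float, float],
    radius: float,
    n_arms: int = 5,
    amplitude: float = 0.3,
    n_points: int = 360,
) -> np.ndarray:
    """Lobulated outline: radius modulated by ``1 + amplitude*cos(k*t)``."""
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    r = radius * (1.0 + amplitude * np.cos(n_arms * t))
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def _check_in_frame(contour: np.ndarray, shape: tuple[int, int]) -> None:
    h, w = shape
    if (
        contour[:, 0].min() < 0
        or contour[:, 0].max() > w - 1
        or contour[:, 1].min() < 0
        or contour[:, 1].max() > h - 1
    ):
        raise InvalidParamsError("node shape exceeds the frame")


def _speckle(base: np.ndarray, noise_level: float, rng: np.random.Generator) -> np.ndarray:
    noisy = base * (1.0 + noise_level * rng.standard_normal(base.shape))
    return np.clip(noisy, 0, 255).astype(np.uint8)


def make_bmode_phantom(
    shape_params: Optional[dict] = None,
    blur_sigma: float = 0.0,
    noise_level: float = 0.05,
    seed: int = 0,
    frame_shape: tuple[int, int] = FRAME_SHAPE,
    ln_intensity: float = LN_INTENSITY,
    bg_intensity: float = BG_INTENSITY,
) -> tuple[np.ndarray, PhantomTruth]:
    """Grayscale B-mode frame with a dark node on speckled bright tissue.

    ``shape_params`` selects the node outline: ``{"kind": "ellipse",
    "center": (x, y), "axes": (a, b), "rotation": deg}`` or
    ``{"kind": "star", "center": ..., "radius": ..., "n_arms": ...,
    "amplitude": ...}``.  ``blur_sigma`` Gaussian-blurs the ideal edge
    before speckle is applied.
    """
    h, w = frame_shape
    params = dict(shape_params or {})
    kind = params.pop("kind", "ellipse")
    if kind == "ellipse":
        params.setdefault("center", (w / 2, h / 2))
        params.setdefault("axes", (110.0, 70.0))
        contour = ellipse_contour(
            params["center"], params["axes"], params.get("rotation", 0.0)
        )
    elif kind == "star":
        params.setdefault("center", (w / 2, h / 2))
        params.setdefault("radius", 90.0)
        contour = star_contour(
            params["center"],
            params["radius"],
            params.get("n_arms", 5),
            params.get("amplitude", 0.3),
        )
    else:
        raise InvalidParamsError(f"unknown shape kind {kind!r}")
    _check_in_frame(contour, (h, w))

    mask = polygon_to_mask(contour, h, w)
    ideal = np.full((h, w), bg_intensity, dtype=np.float64)
    ideal[mask] = ln_intensity
    if blur_sigma > 0:
        ideal = ndi.gaussian_filter(ideal, blur_sigma)
    rng = np.random.default_rng(seed)
    image = _speckle(ideal, noise_level, rng)
    truth = PhantomTruth(
        contour=contour,
        mask=mask,
        modality="bmode",
        seed=seed,
        blur_sigma=blur_sigma,
        noise_level=noise_level,
    )
    return image, truth


def make_doppler_phantom(
    vascularity_fraction: float,
    blob_offset: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int] = FRAME_SHAPE,
    shape_params: Optional[dict] = None,
    hue: Optional[int] = None,
) -> tuple[np.ndarray, PhantomTruth]:
    """Color-Doppler frame: gray B-mode base plus a saturated flow blob.

    Exactly ``round(fraction * node_area)`` node pixels are painted: the
    pixels nearest to a target point placed ``blob_offset`` of the way
    from the node centroid toward the boundary, so offset 0 yields a
    central (hilar-like) blob and offsets near 1 a peripheral one.
    ``hue`` fixes the painted byte-scale hue; by default it is drawn from
    the seed (color identity is irrelevant to the analysis).
    """
    if not 0.0 <= vascularity_fraction <= 1.0:
        raise InvalidParamsError(f"fraction must be in [0, 1], got {vascularity_fraction}")
    if not 0.0 <= blob_offset <= 1.0:
        raise InvalidParamsError(f"blob_offset must be in [0, 1], got {blob_offset}")

    base, truth = make_bmode_phantom(
        shape_params=shape_params, blur_sigma=1.0, seed=seed, frame_shape=frame_shape
    )
    image = np.stack([base] * 3, axis=-1)  # exactly gray: saturation 0
    mask = truth.mask
    area = int(mask.sum())
    n_paint = int(round(vascularity_fraction * area))
    if n_paint > area:
        raise InvalidParamsError("requested fraction exceeds the node area")

    rng = np.random.default_rng(seed)
    if n_paint > 0:
        rows, cols = np.nonzero(mask)
        cy, cx = rows.mean(), cols.mean()
        # aim the blob along a seed-chosen direction, offset of the way
        # from centroid to the boundary point in that direction
        angle = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(angle), np.sin(angle)])
        radial = (cols - cx) * direction[0] + (rows - cy) * direction[1]
        reach = radial.max()  # distance to boundary along the direction
        target = np.array([cx, cy]) + blob_offset * reach * direction
        d2 = (cols - target[0]) ** 2 + (rows - target[1]) ** 2
        chosen = np.argsort(d2, kind="stable")[:n_paint]
        paint_hue = int(hue) if hue is not None else int(rng.integers(0, 180))
        rgb = hsv_bytes_to_rgb(paint_hue, 255, 255)
        image[rows[chosen], cols[chosen]] = rgb

    truth.modality = "doppler"
    truth.vascularity_fraction = vascularity_fraction
    truth.blob_offset = blob_offset
    truth.colored_count = n_paint
    return image, truth


def make_elasto_duplex(
    color_fractions: tuple[float, float, float] = (0.2, 0.2, 0.2),
    colored_side: str = "right",
    scale_bar: bool = False,
    seed: int = 0,
    frame_shape: tuple[int, int] = FRAME_SHAPE,
    overlay_alpha: float = 0.6,
) -> tuple[np.ndarray, PhantomTruth]:
    """Two-panel elastography duplex frame with exact color budgets.

    ``color_fractions`` are the (red, green, blue) area fractions of the
    node region on the elastogram panel; exactly ``round(f * area)``
    pixels per class are overlaid (band-ordered top to bottom) at the
    class-center hues 0/60/120, alpha-blended over the gray base so hue
    is preserved while saturation drops.  The B-mode panel holds the node
    contour recorded in the truth; ``truth.elasto_contour`` is the same
    contour shifted by exactly one panel width.
    """
    if colored_side not in ("left", "right"):
        raise InvalidParamsError(f"colored_side must be left/right, got {colored_side!r}")
    fr, fg, fb = color_fractions
    if min(fr, fg, fb) < 0 or fr + fg + fb > 1.0 + 1e-12:
        raise InvalidParamsError(
            f"color fractions must be non-negative and sum <= 1, got {color_fractions}"
        )

    h, w = frame_shape
    margin_x, margin_y = 40, 30
    region_w = w - 2 * margin_x
    region_w -= region_w % 2  # equal-width panels need an even split
    region_h = h - 2 * margin_y
    panel_w = region_w // 2
    us_region = (margin_x, margin_y, region_w, region_h)

    rng = np.random.default_rng(seed)
    frame = np.zeros((h, w), dtype=np.float64)
    content = np.full((region_h, region_w), 200.0)

    # node in each panel at the same panel-local position
    bmode_is_left = colored_side == "right"
    panel_cx_local = panel_w / 2.0
    cx_bmode = margin_x + (0 if bmode_is_left else panel_w) + panel_cx_local
    cy = margin_y + region_h / 2.0
    axes = (min(110.0, panel_w / 2.0 - 20), 70.0)
    contour = ellipse_contour((cx_bmode, cy), axes)
    shift = panel_w if bmode_is_left else -panel_w
    elasto_contour = contour + [shift, 0.0]

    mask_bmode = polygon_to_mask(contour, h, w)
    mask_elasto = polygon_to_mask(elasto_contour, h, w)
    ln = np.zeros((h, w), dtype=bool)
    ln |= mask_bmode | mask_elasto

    frame[margin_y : margin_y + region_h, margin_x : margin_x + region_w] = content
    frame[ln] = LN_INTENSITY
    gray = _speckle(frame, 0.05, rng)
    image = np.stack([gray] * 3, axis=-1)

    # exact per-class pixel budgets inside the elastogram-panel node,
    # assigned in row-major bands so classes form contiguous regions
    rows, cols = np.nonzero(mask_elasto)
    area = len(rows)
    counts = {
        "red": int(round(fr * area)),
        "green": int(round(fg * area)),
        "blue": int(round(fb * area)),
    }
    if sum(counts.values()) > area:
        counts["blue"] = area - counts["red"] - counts["green"]
    start = 0
    for cls in ("red", "green", "blue"):
        n = counts[cls]
        sel = slice(start, start + n)
        start += n
        color = np.array(hsv_bytes_to_rgb(CLASS_HUES[cls], 255, 255), dtype=np.float64)
        base_px = image[rows[sel], cols[sel]].astype(np.float64)
        blended = overlay_alpha * color + (1 - overlay_alpha) * base_px
        image[rows[sel], cols[sel]] = np.round(blended).astype(np.uint8)

    if scale_bar:
        bar_x = 6 if colored_side == "left" else w - 18
        bar_h = 200
        y0 = (h - bar_h) // 2
        hues = np.linspace(0, 130, bar_h).astype(int)
        for i, hu in enumerate(hues):
            image[y0 + i, bar_x : bar_x + 12] = hsv_bytes_to_rgb(int(hu), 255, 255)

    truth = PhantomTruth(
        contour=contour,
        mask=mask_bmode,
        modality="elasto",
        seed=seed,
        color_fractions=(fr, fg, fb),
        color_counts={**counts, "area": area},
        colored_side=colored_side,
        scale_bar=scale_bar,
        us_region=us_region,
        panel_width=panel_w,
        elasto_contour=elasto_contour,
    )
    return image, truth
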