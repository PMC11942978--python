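"""Modality-dispatched analysis orchestration.

``analyze_arrays`` is the library entry point: image + node contour/mask
+ config in, :class:`AnalysisReport` out.  B-mode frames get shape and
contour-sharpness metrics; Doppler frames add vascularity metrics;
elastography duplex frames get shape metrics on the B-mode panel, the
panel translation, and the stiffness quantification.  ``analyze`` wraps
it with file IO for the CLI.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np

from .colorspace import HSVRange, rgb_to_hsv_bytes
from .config import RunConfig
from .core import (
    AnalysisReport,
    Calibration,
    mask_to_contour,
    polygon_to_mask,
    read_annotations,
    read_image,
    read_mask,
    render_overlay,
    write_image,
)
from .doppler import analyze_doppler
from .elastography import analyze_elasto, detect_colored_side, remove_color_scale
from .errors import EchoNodeError, ModalityError, NoElastogramError, SideTieError
from .shape import shape_metrics, solbiati_class, thickness_flag
from .sharpness import contour_sharpness

logger = logging.getLogger("echonode")

__all__ = ["analyze", "analyze_arrays", "modality_autodetect"]


def _luma(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        return image
    return np.round(
        0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
    ).astype(np.uint8)


def modality_autodetect(image: np.ndarray) -> str:
    """Heuristic modality detection.

    Frames with no saturated pixel are B-mode; frames whose color is
    confined to one half (after color-scale removal) are elastography
    duplex frames; anything else is Doppler.  Falls back to B-mode with a
    warning when the heuristics cannot decide.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return "bmode"
    hsv = rgb_to_hsv_bytes(arr)
    colored = (hsv[..., 1] >= 1) & (hsv[..., 2] >= 1)
    if not colored.any():
        return "bmode"
    try:
        clean = remove_color_scale(arr)
        detect_colored_side(clean)  # raises if colorless
        hsv2 = rgb_to_hsv_bytes(clean)
        colored2 = (hsv2[..., 1] >= 10) & (hsv2[..., 2] >= 10)
        half = arr.shape[1] // 2
        left, right = int(colored2[:, :half].sum()), int(colored2[:, half:].sum())
        total = left + right
        if total and max(left, right) / total > 0.98:
            return "elasto"
        return "doppler"
    except (NoElastogramError, SideTieError):
        logger.warning("modality autodetect inconclusive; falling back to bmode")
        return "bmode"


def _stage(name: str, t0: float) -> None:
    logger.debug("stage %-12s %.1f ms", name, 1000 * (time.perf_counter() - t0))


def analyze_arrays(
    image: np.ndarray,
    contour: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    config: Optional[RunConfig] = None,
    image_id: str = "",
) -> AnalysisReport:
    """Analyze one frame given its node contour and/or mask.

    Exactly one of ``contour``/``mask`` may be omitted; the other is
    derived.  For elastography the contour must lie on the B-mode panel.
    """
    cfg = config or RunConfig()
    arr = np.asarray(image)
    if contour is None and mask is None:
        raise EchoNodeError("either a contour or a mask is required")
    if contour is None:
        contour = mask_to_contour(mask)
    modality = cfg.modality
    if modality == "auto":
        modality = modality_autodetect(arr)
        logger.info("autodetected modality: %s", modality)
    if modality in ("doppler", "elasto") and arr.ndim != 3:
        raise ModalityError(f"{modality} analysis needs a color image")
    if mask is None and modality != "elasto":
        mask = polygon_to_mask(contour, arr.shape[0], arr.shape[1])

    report = AnalysisReport(image_id=image_id, modality=modality, config=cfg.snapshot())
    flags: dict = {}

    t0 = time.perf_counter()
    sm = shape_metrics(contour, Calibration(cfg.px_per_mm))
    report.shape = sm.to_dict()
    flags["solbiati_class"] = solbiati_class(sm.solbiati_index)
    flags["thickness_flag"] = thickness_flag(sm.short_axis_mm, cfg.shape.thickness_mm)
    _stage("shape", t0)

    if modality in ("bmode", "doppler"):
        t0 = time.perf_counter()
        sharp = contour_sharpness(
            _luma(arr),
            contour,
            step=cfg.contour.step,
            probe_half_length=cfg.contour.probe_half_length,
            band_half_width=cfg.contour.band_half_width,
        )
        report.contour = sharp.to_dict()
        _stage("sharpness", t0)

    if modality == "doppler":
        t0 = time.perf_counter()
        rng = HSVRange.from_bounds(cfg.doppler.hsv_lower, cfg.doppler.hsv_upper)
        dm = analyze_doppler(
            arr,
            contour,
            mask,
            rng,
            low_threshold=cfg.doppler.low_vasc_threshold,
            position_threshold=cfg.doppler.position_threshold,
        )
        report.doppler = dm.to_dict()
        flags["low_vascularity_flag"] = dm.low_vascularity_flag
        if dm.peripheral_vascularity_flag is not None:
            flags["peripheral_vascularity_flag"] = dm.peripheral_vascularity_flag
        _stage("doppler", t0)

    if modality == "elasto":
        t0 = time.perf_counter()
        em, layout, _ = analyze_elasto(
            arr,
            contour,
            hard_classes=cfg.elasto.hard_classes,
            hard_threshold_pct=cfg.elasto.hard_threshold,
            paper_literal_translation=cfg.elasto.paper_literal_translation,
            strip_color_scale=cfg.elasto.strip_color_scale,
        )
        report.elasto = em.to_dict()
        report.elasto["colored_side"] = layout.colored_side
        flags["stiffness_flag"] = em.stiffness_flag
        _stage("elasto", t0)

    report.flags = flags
    return report


def analyze(
    image_path: str | Path,
    mask_path: Optional[str | Path] = None,
    annotations_path: Optional[str | Path] = None,
    config: Optional[RunConfig] = None,
    out_path: Optional[str | Path] = None,
    overlay_path: Optional[str | Path] = None,
) -> AnalysisReport:
    """File-level entry point used by the CLI."""
    if (mask_path is None) == (annotations_path is None):
        raise EchoNodeError("provide exactly one of mask_path / annotations_path")
    image = read_image(image_path)
    contour = None
    mask = None
    if mask_path is not None:
        mask = read_mask(mask_path)
    else:
        records = read_annotations(annotations_path)
        if not records:
            raise EchoNodeError(f"no annotations in {annotations_path}")
        contour = records[0][1]

    report = analyze_arrays(
        image, contour=contour, mask=mask, config=config, image_id=str(image_path)
    )
    if out_path is not None:
        Path(out_path).write_text(report.to_json())
    if overlay_path is not None:
        if contour is None:
            contour = mask_to_contour(mask)
        write_image(overlay_path, render_overlay(image, contour, report))
    return report
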