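"""Duplex-panel geometry, color-scale removal, contour translation and
stiffness color quantification."""

import numpy as np
import pytest

from echonode.colorspace import hsv_bytes_to_rgb
from echonode.core import polygon_to_mask
from echonode.elastography import (
    PanelLayout,
    analyze_elasto,
    color_region_percentages,
    detect_colored_side,
    detect_ultrasound_region,
    remove_color_scale,
    stiffness_flag,
    translate_contour,
)
from echonode.errors import (
    DetectionFailureError,
    EmptyMaskError,
    NoElastogramError,
    SideTieError,
    TranslationOutOfBoundsError,
)
from echonode.phantoms import make_elasto_duplex

from conftest import disk_mask


def _frame_with_block(frame_shape=(500, 600), block=(120, 50, 360, 400), level=200):
    x, y, w, h = block
    img = np.zeros(frame_shape, np.uint8)
    img[y : y + h, x : x + w] = level
    return img


class TestDetectUltrasoundRegion:
    def test_centered_block_located(self):
        img = _frame_with_block()
        x, y, w, h = detect_ultrasound_region(img)
        assert abs(x - 120) <= 3 and abs(y - 50) <= 3
        assert abs(w - 360) <= 3 and abs(h - 400) <= 3

    def test_all_black_frame_fails(self):
        with pytest.raises(DetectionFailureError):
            detect_ultrasound_region(np.zeros((200, 200), np.uint8))

    def test_block_touching_edge_clipped(self):
        img = _frame_with_block(block=(0, 0, 300, 250))
        x, y, w, h = detect_ultrasound_region(img)
        assert x >= 0 and y >= 0
        assert x + w <= 600 and y + h <= 500
        assert abs(w - 300) <= 3 and abs(h - 250) <= 3

    def test_tiny_component_fails(self):
        img = np.zeros((200, 200), np.uint8)
        img[10:30, 10:30] = 200  # 1% of the frame
        with pytest.raises(DetectionFailureError):
            detect_ultrasound_region(img)


class TestDetectColoredSide:
    def _frame(self):
        return np.full((100, 200, 3), 80, np.uint8)

    def test_left_only(self):
        img = self._frame()
        img[40:60, 20:40] = (255, 0, 0)
        assert detect_colored_side(img) == "left"

    def test_right_only(self):
        img = self._frame()
        img[40:60, 150:170] = (0, 0, 255)
        assert detect_colored_side(img) == "right"

    def test_majority_vote(self):
        img = self._frame()
        img[0:20, 0:20] = (255, 0, 0)      # 400 px left
        img[0:15, 150:170] = (0, 255, 0)   # 300 px right
        assert detect_colored_side(img) == "left"

    def test_gray_frame_has_no_elastogram(self):
        with pytest.raises(NoElastogramError):
            detect_colored_side(self._frame())

    def test_exact_tie_raises(self):
        img = self._frame()
        img[0:10, 0:10] = (255, 0, 0)
        img[0:10, 190:200] = (255, 0, 0)
        with pytest.raises(SideTieError):
            detect_colored_side(img)


class TestRemoveColorScale:
    def _bar_frame(self, bar_x=5):
        img = np.full((300, 400, 3), 60, np.uint8)
        for i, hue in enumerate(np.linspace(0, 130, 200).astype(int)):
            img[50 + i, bar_x : bar_x + 12] = hsv_bytes_to_rgb(int(hue), 255, 255)
        return img

    def test_edge_bar_blanked(self):
        img = self._bar_frame()
        out = remove_color_scale(img)
        assert (out[50:250, 5:17] == 0).all()
        with pytest.raises(NoElastogramError):
            detect_colored_side(out)  # nothing colored left

    def test_frame_without_bar_unchanged(self):
        img = np.full((300, 400, 3), 60, np.uint8)
        img[100:150, 150:250] = (0, 0, 255)  # wide central overlay, not a bar
        assert np.array_equal(remove_color_scale(img), img)

    def test_bar_beside_elastogram_does_not_flip_side(self):
        image, truth = make_elasto_duplex(
            (0.1, 0.2, 0.2), colored_side="left", scale_bar=True, seed=2
        )
        assert detect_colored_side(remove_color_scale(image)) == "left"


class TestTranslateContour:
    LAYOUT_R = PanelLayout(us_region=(0, 0, 400, 300), colored_side="right")
    LAYOUT_L = PanelLayout(us_region=(0, 0, 400, 300), colored_side="left")

    def _contour(self):
        return np.array([[50, 30], [100, 30], [100, 80], [50, 80]], float)

    def test_shift_toward_right_panel(self):
        out = translate_contour(self._contour(), self.LAYOUT_R, (300, 600))
        assert out[:, 0].min() == 250 and out[:, 0].max() == 300

    def test_shift_toward_left_panel(self):
        contour = self._contour() + [250, 0]  # sits on the right panel
        out = translate_contour(contour, self.LAYOUT_L, (300, 600))
        assert out[:, 0].min() == 100 and out[:, 0].max() == 150

    def test_y_unchanged(self):
        contour = self._contour()
        out = translate_contour(contour, self.LAYOUT_R, (300, 600))
        np.testing.assert_array_equal(out[:, 1], contour[:, 1])

    def test_round_trip_is_exact(self):
        contour = self._contour() + 0.25  # non-integer coordinates
        there = translate_contour(contour, self.LAYOUT_R, (300, 600))
        back = translate_contour(there, self.LAYOUT_L, (300, 600))
        np.testing.assert_array_equal(back, contour)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(TranslationOutOfBoundsError):
            translate_contour(self._contour(), self.LAYOUT_R, (300, 290))

    def test_paper_literal_flips_direction(self):
        contour = self._contour() + [250, 0]
        out = translate_contour(contour, self.LAYOUT_L, (300, 600), paper_literal=True)
        assert out[:, 0].min() == 500  # shifted away from the colored side


class TestColorRegionPercentages:
    def test_pure_blue_mask(self):
        img = np.zeros((100, 100, 3), np.uint8)
        img[..., 2] = 255  # hue 120 = blue class
        mask = disk_mask((100, 100), (50, 50), 30)
        em = color_region_percentages(img, mask)
        assert em.blue_pct == 100.0 and em.red_pct == 0.0 and em.green_pct == 0.0
        assert em.hard_fraction_pct == 100.0 and em.stiffness_flag

    @pytest.mark.parametrize("hue,cls", [(39, "red"), (40, "green"), (79, "green"), (80, "blue"), (135, "blue"), (136, "red")])
    def test_hue_band_boundaries(self, hue, cls):
        img = np.full((20, 20, 3), hsv_bytes_to_rgb(hue, 255, 255), np.uint8)
        mask = np.ones((20, 20), bool)
        em = color_region_percentages(img, mask)
        assert getattr(em, f"{cls}_pct") == 100.0

    def test_phantom_fractions_recovered(self):
        image, truth = make_elasto_duplex((0.3, 0.3, 0.3), colored_side="right", seed=5)
        mask = polygon_to_mask(truth.elasto_contour, *image.shape[:2])
        em = color_region_percentages(image, mask)
        area = truth.color_counts["area"]
        for cls in ("red", "green", "blue"):
            expected = 100 * truth.color_counts[cls] / area
            assert getattr(em, f"{cls}_pct") == pytest.approx(expected, abs=0.5)

    def test_partition_property(self):
        image, truth = make_elasto_duplex((0.25, 0.25, 0.2), colored_side="left", seed=8)
        mask = polygon_to_mask(truth.elasto_contour, *image.shape[:2])
        em = color_region_percentages(image, mask)
        from echonode.colorspace import HSVRange, in_hsv_range

        uncolored = 100.0 * (
            (~in_hsv_range(image, HSVRange(0, 180, 1, 255, 1, 255)) & mask).sum() / mask.sum()
        )
        assert em.red_pct + em.green_pct + em.blue_pct + uncolored == pytest.approx(
            100.0, abs=1e-9
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            color_region_percentages(np.zeros((10, 10, 3), np.uint8), np.zeros((10, 10), bool))


class TestStiffnessFlag:
    @pytest.mark.parametrize("hard,expected", [(41.0, True), (40.0, False), (0.0, False), (40.01, True)])
    def test_strict_threshold(self, hard, expected):
        assert stiffness_flag(hard) is expected


class TestEndToEnd:
    @pytest.mark.parametrize("side", ["left", "right"])
    @pytest.mark.parametrize("bar", [False, True])
    def test_full_pipeline_recovers_hard_fraction(self, side, bar):
        for seed in range(3):
            image, truth = make_elasto_duplex(
                (0.2, 0.25, 0.25), colored_side=side, scale_bar=bar, seed=seed
            )
            em, layout, _ = analyze_elasto(image, truth.contour)
            assert layout.colored_side == side
            expected = 100 * (
                truth.color_counts["green"] + truth.color_counts["blue"]
            ) / truth.color_counts["area"]
            assert em.hard_fraction_pct == pytest.approx(expected, abs=1.0)
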