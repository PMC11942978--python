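"""Contour/mask conversion, annotation IO, and overlay rendering."""

import json

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from echonode.core import (
    AnalysisReport,
    Calibration,
    _report_lines,
    largest_component,
    mask_to_contour,
    polygon_to_mask,
    read_annotations,
    render_overlay,
    validate_contour,
)
from echonode.errors import (
    AnnotationError,
    EmptyMaskError,
    InvalidContourError,
    InvalidMeasureError,
)
from echonode.phantoms import ellipse_contour, star_contour

SQUARE = np.array([[10, 10], [20, 10], [20, 20], [10, 20]], float)


class TestPolygonToMask:
    def test_square_boundary_inclusive(self):
        mask = polygon_to_mask(SQUARE, 100, 100)
        assert mask.sum() == 121  # 11 x 11, boundary pixels included
        assert mask[10, 10] and mask[20, 20] and not mask[9, 10]

    @pytest.mark.parametrize(
        "contour",
        [
            SQUARE,
            np.array([[5.5, 3.2], [42.8, 11.1], [30.0, 44.9], [8.3, 35.0]]),
            ellipse_contour((50, 40), (30, 18), rotation_deg=25.0, n_points=90),
        ],
        ids=["square", "quad", "ellipse"],
    )
    def test_matches_point_in_polygon_oracle(self, contour):
        """Brute-force oracle: shapely point-in-polygon (boundary counts
        as inside) over every pixel of the bounding box."""
        mask = polygon_to_mask(contour, 100, 100)
        poly = Polygon(contour)
        for y in range(int(contour[:, 1].min()) - 1, int(contour[:, 1].max()) + 2):
            for x in range(int(contour[:, 0].min()) - 1, int(contour[:, 0].max()) + 2):
                expected = poly.intersects(Point(x, y))  # inside or on boundary
                assert mask[y, x] == expected, (x, y)

    def test_collinear_triangle_rejected(self):
        bad = np.array([[0, 0], [5, 5], [10, 10]], float)
        with pytest.raises(InvalidContourError):
            polygon_to_mask(bad, 50, 50)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidContourError):
            polygon_to_mask(np.array([[0, 0], [5, 5]], float), 50, 50)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(InvalidContourError):
            polygon_to_mask(SQUARE + 95, 100, 100)


class TestMaskToContour:
    def test_square_boundary_ring(self):
        mask = np.zeros((100, 100), bool)
        mask[10:21, 10:21] = True
        contour = mask_to_contour(mask)
        assert len(contour) == 40  # 4*11 - 4 boundary pixels
        assert len(np.unique(contour, axis=0)) == 40

    def test_single_pixel(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 7] = True
        contour = mask_to_contour(mask)
        assert contour.shape == (1, 2)
        assert tuple(contour[0]) == (7.0, 4.0)

    def test_largest_component_wins(self):
        mask = np.zeros((50, 50), bool)
        mask[5:15, 5:15] = True  # area 100
        mask[30:31, 30:35] = True  # area 5
        with pytest.warns(UserWarning, match="2 foreground components"):
            contour = mask_to_contour(mask)
        assert contour[:, 0].max() <= 14 and contour[:, 1].max() <= 14

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            mask_to_contour(np.zeros((10, 10), bool))

    @pytest.mark.parametrize(
        "contour",
        [
            ellipse_contour((60, 50), (35, 22), rotation_deg=15.0),
            star_contour((60, 60), 40, n_arms=5, amplitude=0.25),
        ],
        ids=["ellipse", "star"],
    )
    def test_round_trip_preserves_pixel_set(self, contour):
        """Filling the traced boundary reproduces the original mask."""
        mask = polygon_to_mask(contour, 120, 120)
        recovered = polygon_to_mask(mask_to_contour(mask), 120, 120)
        assert np.array_equal(mask, recovered)


class TestLargestComponent:
    def test_single_component_untouched(self):
        mask = np.zeros((20, 20), bool)
        mask[3:8, 3:8] = True
        assert np.array_equal(largest_component(mask), mask)


class TestValidateContour:
    def test_consecutive_duplicates_rejected(self):
        bad = np.array([[0, 0], [5, 0], [5, 0], [5, 5]], float)
        with pytest.raises(InvalidContourError):
            validate_contour(bad)

    def test_closing_duplicate_rejected(self):
        bad = np.array([[0, 0], [5, 0], [5, 5], [0, 0]], float)
        with pytest.raises(InvalidContourError):
            validate_contour(bad)


class TestCalibration:
    def test_converts_px_to_mm(self):
        assert Calibration(px_per_mm=2.0).to_mm(40.0) == 20.0

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(InvalidMeasureError):
            Calibration(px_per_mm=bad)


class TestReadAnnotations:
    @staticmethod
    def _write(tmp_path, doc):
        path = tmp_path / "ann.json"
        path.write_text(json.dumps(doc))
        return path

    def _doc(self):
        return {
            "images": [
                {"id": 1, "width": 100, "height": 80, "file_name": "a.png"},
                {"id": 2, "width": 50, "height": 50, "file_name": "b.png"},
            ],
            "annotations": [
                {"id": 10, "image_id": 1, "segmentation": [[10, 10, 30, 10, 30, 30, 10, 30]]},
                {"id": 11, "image_id": 1, "segmentation": [[5, 5, 20, 5, 12, 25]]},
                {"id": 12, "image_id": 2, "segmentation": [[1, 1, 10, 1, 10, 10]]},
            ],
            "categories": [{"id": 1, "name": "lymph_node"}],
        }

    def test_counts_and_shapes(self, tmp_path):
        records = read_annotations(self._write(tmp_path, self._doc()))
        assert len(records) == 3
        ids = [r[0] for r in records]
        assert ids == ["1", "1", "2"]
        # flat [x1,y1,...] list of length 8 -> 4-point contour
        assert records[0][1].shape == (4, 2)
        assert records[1][1].shape == (3, 2)

    def test_missing_image_id(self, tmp_path):
        doc = self._doc()
        doc["annotations"][0]["image_id"] = 99
        with pytest.raises(AnnotationError, match="missing image id"):
            read_annotations(self._write(tmp_path, doc))

    def test_rle_unsupported(self, tmp_path):
        doc = self._doc()
        doc["annotations"][0]["segmentation"] = {"counts": "abc", "size": [80, 100]}
        with pytest.raises(AnnotationError, match="RLE"):
            read_annotations(self._write(tmp_path, doc))

    def test_out_of_bounds_names_annotation(self, tmp_path):
        doc = self._doc()
        doc["annotations"][2]["segmentation"] = [[1, 1, 60, 1, 60, 60]]
        with pytest.raises(AnnotationError, match="12"):
            read_annotations(self._write(tmp_path, doc))


class TestRenderOverlay:
    def test_draws_green_contour_and_preserves_input(self):
        image = np.full((60, 60), 100, np.uint8)
        before = image.copy()
        out = render_overlay(image, SQUARE, AnalysisReport())
        assert np.array_equal(image, before)
        assert np.array_equal(out[10, 15], [0, 255, 0])

    def test_reference_drawn_red(self):
        image = np.full((60, 60, 3), 100, np.uint8)
        out = render_overlay(image, SQUARE, AnalysisReport(), reference=SQUARE + 20)
        assert np.array_equal(out[30, 35], [255, 0, 0])

    def test_text_block_includes_vascularity_line(self):
        report = AnalysisReport(doppler={"vascularity_percentage": 31.4})
        lines = _report_lines(report)
        assert any("Color: 31.4%" in line for line in lines)


class TestAnalysisReport:
    def test_json_round_trip_is_lossless(self):
        report = AnalysisReport(
            image_id="img1",
            modality="doppler",
            shape={"long_axis_mm": 20.0},
            doppler={"vascularity_percentage": 30.0},
            flags={"low_vascularity_flag": False},
        )
        again = AnalysisReport.from_json(report.to_json())
        assert again == report
        assert again.to_json() == report.to_json()
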