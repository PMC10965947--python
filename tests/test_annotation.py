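"""Stain separation, stand-in nucleus detection, polygon labeling, boxes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdl1bench import (
    CellClass,
    CellPoint,
    DetectorParams,
    GroundTruthROI,
    LabeledPolygon,
    boxes_to_points,
    detect_nuclei,
    label_points_by_polygons,
    points_to_boxes,
    render_ihc_image,
    separate_stains,
)
from pdl1bench.annotation import PolygonOverlapError, StainMatrixError
from pdl1bench.synthetic import HEMATOXYLIN_OD
from oracle_utils import even_odd_inside


def sparse_roi(seed=0, n=50, size=400.0, spacing=0.5):
    """A rendered ROI with n well-separated nuclei (min 14 um apart)."""
    rng = np.random.default_rng(seed)
    placed = []
    while len(placed) < n:
        x, y = rng.uniform(10, size - 10, 2)
        if all((x - px) ** 2 + (y - py) ** 2 >= 14.0**2 for px, py in placed):
            placed.append((x, y))
    cells = [CellPoint(x, y, CellClass.NEG_TUMOR) for x, y in placed]
    roi = GroundTruthROI(width_um=size, height_um=size, spacing_um_per_px=spacing,
                         cells=cells, seed=seed, roi_id="sparse")
    roi.image = render_ihc_image(roi)
    return roi


class TestSeparateStains:
    def test_pure_white_image_has_zero_density(self):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        maps = separate_stains(img)
        assert np.allclose(maps["hematoxylin"], 0.0, atol=1e-4)
        assert np.allclose(maps["dab"], 0.0, atol=1e-4)

    def test_render_then_unmix_recovers_nucleus_signal(self):
        # Unmixing must be a left inverse of rendering: the recovered
        # hematoxylin map correlates > 0.99 with the optical-density field
        # the nuclei were drawn with (same profile, computed independently).
        roi = sparse_roi(seed=1, n=30)
        maps = separate_stains(roi.image)
        ref = np.zeros(roi.image.shape[:2])
        s = roi.spacing_um_per_px
        r_nuc = 2.8
        ii, jj = np.mgrid[0 : ref.shape[0], 0 : ref.shape[1]]
        for c in roi.cells:
            r = np.hypot((ii + 0.5) * s - c.y_um, (jj + 0.5) * s - c.x_um)
            od = 0.9 * np.exp(-0.5 * (np.maximum(r - 0.5 * r_nuc, 0.0) / (0.45 * r_nuc)) ** 2)
            ref = np.maximum(ref, od)
        corr = np.corrcoef(maps["hematoxylin"].ravel(), ref.ravel())[0, 1]
        assert corr > 0.99

    def test_single_stain_disk_does_not_leak_into_dab(self):
        # A pure-hematoxylin disk: DAB map stays < 5% of hematoxylin peak.
        h, w = 64, 64
        od = np.zeros((h, w))
        yy, xx = np.mgrid[0:h, 0:w]
        od[(yy - 32) ** 2 + (xx - 32) ** 2 < 12**2] = 0.8
        rgb = np.power(10.0, -od[..., None] * HEMATOXYLIN_OD)
        img = np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)
        maps = separate_stains(img)
        assert maps["dab"].max() < 0.05 * maps["hematoxylin"].max()

    def test_parallel_stain_vectors_rejected(self):
        img = np.full((8, 8, 3), 200, dtype=np.uint8)
        m = np.vstack([HEMATOXYLIN_OD, HEMATOXYLIN_OD * 1.0000001])
        with pytest.raises(StainMatrixError):
            separate_stains(img, stain_matrix=m)

    def test_output_shapes_match_input_raster(self):
        img = np.full((17, 23, 3), 240, dtype=np.uint8)
        maps = separate_stains(img)
        assert maps["hematoxylin"].shape == (17, 23)


class TestDetectNuclei:
    def test_blank_image_yields_no_detections(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert detect_nuclei(img, 0.5) == []

    def test_recovers_well_separated_nuclei(self):
        roi = sparse_roi(seed=2, n=50)
        points = detect_nuclei(roi.image, roi.spacing_um_per_px)
        truth = [(c.x_um, c.y_um) for c in roi.cells]
        hits = 0
        for tx, ty in truth:
            d = min(math.hypot(p.x_um - tx, p.y_um - ty) for p in points)
            if d <= 3.0:
                hits += 1
        spurious = sum(
            1 for p in points
            if min(math.hypot(p.x_um - tx, p.y_um - ty) for tx, ty in truth) > 3.0
        )
        assert hits >= 48
        assert spurious <= 2

    def test_prominence_above_global_max_suppresses_everything(self):
        roi = sparse_roi(seed=3, n=20)
        params = DetectorParams(min_prominence=1e6)
        assert detect_nuclei(roi.image, roi.spacing_um_per_px, params=params) == []

    def test_translation_equivariance(self):
        roi = sparse_roi(seed=4, n=15, size=200.0)
        shift_px = 8
        shifted = np.full_like(roi.image, 255)
        shifted[shift_px:, shift_px:] = roi.image[:-shift_px, :-shift_px]
        base = detect_nuclei(roi.image, roi.spacing_um_per_px)
        moved = detect_nuclei(shifted, roi.spacing_um_per_px)
        d_um = shift_px * roi.spacing_um_per_px
        window = lambda x, y: 10 < x < 190 and 10 < y < 190  # same frame for both
        base_in = sorted(
            (p.x_um + d_um, p.y_um + d_um)
            for p in base
            if window(p.x_um + d_um, p.y_um + d_um)
        )
        moved_in = sorted((p.x_um, p.y_um) for p in moved if window(p.x_um, p.y_um))
        assert len(base_in) == len(moved_in)
        for (xa, ya), (xb, yb) in zip(base_in, moved_in):
            assert math.hypot(xa - xb, ya - yb) < 1e-6

    def test_detections_are_class_agnostic(self):
        roi = sparse_roi(seed=5, n=10)
        points = detect_nuclei(roi.image, roi.spacing_um_per_px)
        assert all(p.label is None for p in points)


class TestLabelPointsByPolygons:
    RECT = lambda self, x0, y0, x1, y1, cls: LabeledPolygon(
        ((x0, y0), (x1, y0), (x1, y1), (x0, y1)), cls
    )

    def test_point_at_centroid_gets_polygon_class(self):
        poly = self.RECT(0, 0, 10, 10, CellClass.POS_TUMOR)
        out = label_points_by_polygons([CellPoint(5, 5)], [poly])
        assert len(out.points) == 1
        assert out.points[0].label is CellClass.POS_TUMOR

    def test_point_outside_all_polygons_discarded(self):
        poly = self.RECT(0, 0, 10, 10, CellClass.OTHER)
        out = label_points_by_polygons([CellPoint(50, 50)], [poly])
        assert out.points == []

    def test_outside_other_mode_keeps_points(self):
        poly = self.RECT(0, 0, 10, 10, CellClass.POS_TUMOR)
        out = label_points_by_polygons([CellPoint(50, 50)], [poly], outside="other")
        assert out.points[0].label is CellClass.OTHER

    def test_boundary_points_count_as_inside(self):
        poly = self.RECT(0, 0, 10, 10, CellClass.NEG_TUMOR)
        out = label_points_by_polygons([CellPoint(10.0, 5.0)], [poly])
        assert len(out.points) == 1

    def test_matches_even_odd_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        rects = [
            ((5, 5), (20, 5), (20, 20), (5, 20)),
            ((30, 0), (45, 0), (45, 18), (30, 18)),
            ((0, 30), (25, 30), (25, 45), (0, 45)),
        ]
        classes = [CellClass.NEG_TUMOR, CellClass.POS_TUMOR, CellClass.OTHER]
        polys = [LabeledPolygon(r, c) for r, c in zip(rects, classes)]
        pts = [CellPoint(x, y) for x, y in rng.uniform(0, 50, size=(10, 2))]
        out = label_points_by_polygons(pts, polys)
        got = {(p.x_um, p.y_um): p.label for p in out.points}
        for p in pts:
            inside = [c for r, c in zip(rects, classes) if even_odd_inside(p.x_um, p.y_um, r)]
            if inside:
                assert got[(p.x_um, p.y_um)] is inside[0]
            else:
                assert (p.x_um, p.y_um) not in got

    def test_smallest_area_polygon_wins_overlap(self):
        big = self.RECT(0, 0, 100, 100, CellClass.OTHER)
        small = self.RECT(40, 40, 60, 60, CellClass.POS_TUMOR)
        out = label_points_by_polygons([CellPoint(50, 50)], [big, small])
        assert out.points[0].label is CellClass.POS_TUMOR

    def test_strict_mode_raises_listing_offenders(self):
        big = self.RECT(0, 0, 100, 100, CellClass.OTHER)
        small = self.RECT(40, 40, 60, 60, CellClass.POS_TUMOR)
        with pytest.raises(PolygonOverlapError) as err:
            label_points_by_polygons([CellPoint(50, 50)], [big, small], tie_rule="strict")
        assert len(err.value.offending) == 1

    def test_never_invents_points_and_sorted_output(self):
        rng = np.random.default_rng(14)
        poly = self.RECT(0, 0, 50, 50, CellClass.NEG_TUMOR)
        pts = [CellPoint(x, y) for x, y in rng.uniform(0, 60, size=(20, 2))]
        out = label_points_by_polygons(pts, [poly])
        in_coords = {(p.x_um, p.y_um) for p in pts}
        assert all((p.x_um, p.y_um) in in_coords for p in out.points)
        keys = [(p.y_um, p.x_um) for p in out.points]
        assert keys == sorted(keys)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = LabeledPolygon(((0, 0), (10, 10), (10, 0), (0, 10)), CellClass.OTHER)
        with pytest.raises(ValueError, match="invalid polygon"):
            label_points_by_polygons([CellPoint(5, 5)], [bowtie])


class TestBoxConversions:
    def test_paper_box_size_arithmetic(self):
        boxes = points_to_boxes([CellPoint(30.0, 40.0, CellClass.OTHER)], side_um=20.0)
        assert boxes[0].bounds == (20.0, 40.0, 30.0, 50.0)

    def test_small_side_scaling(self):
        boxes = points_to_boxes([CellPoint(30.0, 40.0)], side_um=0.5)
        assert boxes[0].bounds == (29.75, 30.25, 39.75, 40.25)

    @given(
        x=st.floats(-1e4, 1e4, allow_nan=False),
        y=st.floats(-1e4, 1e4, allow_nan=False),
        side=st.floats(0.1, 100.0, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_is_identity_on_centers(self, x, y, side):
        pt = CellPoint(x, y, CellClass.POS_TUMOR, confidence=0.5)
        (back,) = boxes_to_points(points_to_boxes([pt], side_um=side))
        assert back.x_um == x and back.y_um == y
        assert back.label is pt.label and back.confidence == pt.confidence

    def test_nonpositive_side_rejected(self):
        with pytest.raises(ValueError):
            points_to_boxes([CellPoint(0, 0)], side_um=0.0)
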