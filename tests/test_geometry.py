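import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from insertfactors import (
    InvalidShapeError,
    Polygon2D,
    circle_polygon,
    ellipse_polygon,
    largest_inscribed_circle,
    parameterize_shape,
    polygon_area,
    read_polygon_file,
    rectangle_polygon,
    write_polygon_file,
)
from insertfactors.geometry import DEFAULT_TOL, ellipse_perimeter

from conftest import grid_inscribed_diameter, random_convex_polygon


class TestPolygonConstruction:
    def test_trailing_duplicate_of_first_vertex_dropped(self):
        poly = Polygon2D([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert len(poly) == 4

    def test_consecutive_duplicates_merged(self):
        poly = Polygon2D([(0, 0), (1, 0), (1, 0), (1, 1), (0, 1)])
        assert len(poly) == 4

    @pytest.mark.parametrize(
        "vertices",
        [
            [(0, 0), (1, 0)],                               # too few
            [(0, 0), (1, 1), (2, 2)],                       # collinear, zero area
            [(0, 0), (1, 1), (1, 0), (0, 1)],               # bowtie self-intersection
        ],
        ids=["two-vertices", "collinear", "self-intersecting"],
    )
    def test_degenerate_polygons_rejected(self, vertices):
        with pytest.raises(InvalidShapeError):
            Polygon2D(vertices)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(Polygon2D([(0, 0), (1, 0), (1, 1), (0, 1)])) == pytest.approx(1.0)

    def test_square_4x4(self):
        assert polygon_area(rectangle_polygon(4, 4)) == pytest.approx(16.0)

    def test_regular_128gon_matches_closed_form(self):
        # regular n-gon inscribed in a circle of radius R: area = n R² sin(2π/n)/2
        n, r = 128, 4.0
        area = polygon_area(circle_polygon(2 * r, n_vertices=n))
        closed_form = 0.5 * n * r**2 * math.sin(2 * math.pi / n)
        assert area == pytest.approx(closed_form, rel=1e-12)
        assert area == pytest.approx(math.pi * r**2, rel=1e-3)

    def test_orientation_independent(self):
        cw = Polygon2D([(0, 0), (0, 4), (4, 4), (4, 0)])
        ccw = Polygon2D([(0, 0), (4, 0), (4, 4), (0, 4)])
        assert polygon_area(cw) == polygon_area(ccw) == pytest.approx(16.0)


class TestLargestInscribedCircle:
    def test_circle_is_its_own_inscribed_circle(self):
        _, d = largest_inscribed_circle(circle_polygon(6.0, n_vertices=512))
        # discretization of the 512-gon shrinks the radius by ~(1 - cos(π/n))
        assert d == pytest.approx(6.0, abs=DEFAULT_TOL + 6.0 * (1 - math.cos(math.pi / 512)))

    def test_rectangle_inscribed_circle_is_short_side(self):
        (cx, _), d = largest_inscribed_circle(rectangle_polygon(5, 17))
        assert d == pytest.approx(5.0, abs=2 * DEFAULT_TOL)
        assert cx == pytest.approx(0.0, abs=2 * DEFAULT_TOL)

    def test_ellipse_inscribed_circle_matches_grid_oracle(self):
        poly = ellipse_polygon(5.0, 10.0, n_vertices=360)
        _, d = largest_inscribed_circle(poly)
        oracle = grid_inscribed_diameter(poly, pitch=0.01)
        assert d == pytest.approx(5.0, abs=0.01)
        assert d == pytest.approx(oracle, abs=2 * DEFAULT_TOL + 0.01)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            largest_inscribed_circle(rectangle_polygon(2, 3), tol=0.0)

    def test_random_convex_polygons_agree_with_grid_oracle(self):
        rng = np.random.default_rng(2024)
        pitch = 0.05
        for _ in range(10):
            poly = random_convex_polygon(rng)
            _, d = largest_inscribed_circle(poly)
            oracle = grid_inscribed_diameter(poly, pitch=pitch)
            assert d == pytest.approx(oracle, abs=2 * DEFAULT_TOL + pitch)


class TestParameterizeShape:
    def test_circle_maps_to_itself(self):
        e = parameterize_shape(circle_polygon(8.0, n_vertices=512))
        assert e.width_cm == pytest.approx(8.0, rel=0.005)
        assert e.length_cm == pytest.approx(8.0, rel=0.005)

    def test_square_4x4(self):
        e = parameterize_shape(rectangle_polygon(4, 4))
        assert e.width_cm == pytest.approx(4.0, abs=2 * DEFAULT_TOL)
        assert e.length_cm == pytest.approx(16.0 / math.pi, rel=1e-3)
        assert e.area_cm2 == pytest.approx(16.0)

    def test_ellipse_maps_to_itself(self):
        e = parameterize_shape(ellipse_polygon(5.0, 10.0, n_vertices=360))
        assert e.width_cm == pytest.approx(5.0, rel=0.005)
        assert e.length_cm == pytest.approx(10.0, rel=0.005)

    def test_length_never_below_width_and_area_equivalence(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            poly = random_convex_polygon(rng)
            e = parameterize_shape(poly)
            assert e.length_cm >= e.width_cm * (1 - 1e-12)
            ellipse_area = math.pi * (e.width_cm / 2) * (e.length_cm / 2)
            assert ellipse_area == pytest.approx(e.area_cm2, rel=1e-9)
            assert e.area_cm2 == pytest.approx(polygon_area(poly), rel=1e-12)

    @given(
        dx=st.floats(-15, 15),
        dy=st.floats(-15, 15),
        angle=st.floats(0, 2 * math.pi),
    )
    def test_translation_and_rotation_invariance(self, dx, dy, angle):
        poly = ellipse_polygon(4.0, 9.0, n_vertices=90)
        base = parameterize_shape(poly)
        moved = parameterize_shape(poly.translated(dx, dy).rotated(angle))
        assert moved.width_cm == pytest.approx(base.width_cm, abs=2 * DEFAULT_TOL)
        assert moved.length_cm == pytest.approx(base.length_cm, abs=2 * DEFAULT_TOL)
        assert moved.area_cm2 == pytest.approx(base.area_cm2, rel=1e-9)

    def test_ramanujan_perimeter_circle_limit(self):
        # for equal axes the approximation is exact: P = π d
        assert ellipse_perimeter(6.0, 6.0) == pytest.approx(math.pi * 6.0, rel=1e-12)


class TestPolygonFiles:
    def test_round_trip_with_comments(self, tmp_path):
        poly = ellipse_polygon(3.5, 8.0, n_vertices=64)
        path = tmp_path / "cutout.txt"
        write_polygon_file(poly, path, comment="3.5 x 8 ellipse")
        back = read_polygon_file(path)
        assert np.allclose(back.vertices, poly.vertices, atol=1e-5)

    def test_malformed_line_reports_location(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0,0\n1,0\nnot-a-pair\n")
        with pytest.raises(InvalidShapeError, match="bad.txt:3"):
            read_polygon_file(path)
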