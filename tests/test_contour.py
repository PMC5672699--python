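"""Border model, polygon geometry and radial featurization."""

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from lvvol.contour import (
    LVBorder,
    border_center,
    long_axis_length,
    polygon_area,
    radial_distances,
    resample_border,
)
from lvvol.errors import BorderValidationError, GeometryError, LandmarkError

from conftest import (
    circle_border,
    densify,
    ellipse_border,
    random_star_polygon,
    shoelace_reference,
)


def square_border(side=1.0, origin=(0.0, 0.0), clockwise=False) -> LVBorder:
    x0, y0 = origin
    corners = np.array([
        [x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]
    ])
    if clockwise:
        corners = corners[::-1]
    return LVBorder(points=densify(corners, 4), apex_index=0,
                    mitral_indices=(6, 10))


class TestPolygonArea:
    @pytest.mark.parametrize("clockwise", [False, True])
    def test_unit_square(self, clockwise):
        assert polygon_area(square_border(clockwise=clockwise)) == pytest.approx(1.0)

    def test_dense_ellipse_matches_pi_ab(self):
        b = ellipse_border(10.0, 5.0, n=512)
        assert polygon_area(b) == pytest.approx(np.pi * 50.0, rel=1e-4)

    def test_matches_triangulation_oracle_on_random_polygons(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pts = random_star_polygon(rng)
            b = LVBorder(points=pts, apex_index=0, mitral_indices=(20, 40))
            assert polygon_area(b) == pytest.approx(
                shoelace_reference(pts), rel=1e-9
            )


class TestBorderCenter:
    def test_unit_square(self):
        assert border_center(square_border()) == pytest.approx((0.5, 0.5))

    def test_triangle_centroid(self):
        tri = densify(np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]]), 6)
        b = LVBorder(points=tri, apex_index=0, mitral_indices=(6, 12))
        assert border_center(b) == pytest.approx((1.0, 1.0))

    def test_circle_center_by_symmetry(self):
        b = circle_border(7.0, center=(2.0, -1.0), n=256)
        assert border_center(b) == pytest.approx((2.0, -1.0), abs=1e-6)

    def test_matches_shapely_centroid(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            pts = random_star_polygon(rng)
            b = LVBorder(points=pts, apex_index=0, mitral_indices=(20, 40))
            c = Polygon(pts).centroid
            assert border_center(b) == pytest.approx((c.x, c.y), abs=1e-9)


class TestLongAxis:
    def test_apex_above_symmetric_chord(self):
        pts = densify(np.array([[0.0, 10.0], [-3.0, 0.0], [3.0, 0.0]]), 8)
        b = LVBorder(points=pts, apex_index=0, mitral_indices=(8, 16))
        assert long_axis_length(b) == pytest.approx(10.0)

    def test_vertical_chord_midpoint(self):
        pts = densify(np.array(
            [[0.0, 0.0], [-4.0, -4.0], [0.0, -4.0], [0.0, -8.0], [4.0, -4.0]]
        ), 4)
        # apex at (0,0); mitral endpoints (0,-4) and (0,-8) -> midpoint (0,-6)
        b = LVBorder(points=pts, apex_index=0, mitral_indices=(8, 12))
        assert long_axis_length(b) == pytest.approx(6.0)

    def test_full_ellipse_long_axis(self):
        b = ellipse_border(10.0, 5.0, n=1024)
        assert long_axis_length(b) == pytest.approx(20.0, rel=1e-4)


class TestRadialDistances:
    def test_circle_all_sixteen_equal(self):
        b = circle_border(7.0, n=256, apex_index=37)
        f = radial_distances(b)
        assert f.n_rays == 16
        assert np.all(np.abs(f.distances - 7.0) < 1e-6)

    def test_ellipse_polar_form(self):
        a_ax, b_ax = 10.0, 5.0
        border = ellipse_border(a_ax, b_ax, n=1024)
        f = radial_distances(border)
        # apex on the long axis: rays fall at multiples of 22.5° from it
        phi = np.deg2rad(f.angles_deg - f.angles_deg[0])
        expected = a_ax * b_ax / np.sqrt(
            (b_ax * np.cos(phi)) ** 2 + (a_ax * np.sin(phi)) ** 2
        )
        assert np.allclose(f.distances, expected, rtol=1e-3)
        assert f.distances[0] == pytest.approx(10.0, rel=1e-3)
        assert f.distances[8] == pytest.approx(10.0, rel=1e-3)
        assert f.distances[4] == pytest.approx(5.0, rel=1e-3)
        assert f.distances[12] == pytest.approx(5.0, rel=1e-3)

    def test_square_apex_at_corner(self):
        corners = np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]])
        b = LVBorder(points=densify(corners, 8), apex_index=0,
                     mitral_indices=(14, 18))
        f = radial_distances(b)
        assert f.distances[0] == pytest.approx(np.sqrt(2.0))
        assert f.distances[4] == pytest.approx(np.sqrt(2.0))
        # axis-aligned rays (90° multiples from the 45° apex ray) are shorter
        for k in (2, 6, 10, 14):
            assert f.distances[k] == pytest.approx(1.0)
        assert np.all(f.distances <= np.sqrt(2.0) + 1e-12)

    def test_rigid_motion_leaves_distances_unchanged(self):
        rng = np.random.default_rng(5)
        b = LVBorder(points=random_star_polygon(rng), apex_index=0,
                     mitral_indices=(20, 40))
        f0 = radial_distances(b)
        moved = b.transformed(angle_deg=73.0, shift=(12.0, -4.0))
        f1 = radial_distances(moved)
        assert np.allclose(f0.distances, f1.distances, atol=1e-9)
        # angles rotate with the border
        assert (f1.angles_deg[0] - f0.angles_deg[0]) % 360 == pytest.approx(
            73.0, abs=1e-6
        )

    def test_scaling_scales_distances_axis_and_sqrt_area(self):
        b = ellipse_border(9.0, 5.0, n=512)
        s = 2.5
        big = b.transformed(scale=s)
        assert np.allclose(radial_distances(big).distances,
                           s * radial_distances(b).distances, rtol=1e-12)
        assert long_axis_length(big) == pytest.approx(s * long_axis_length(b))
        assert np.sqrt(polygon_area(big)) == pytest.approx(
            s * np.sqrt(polygon_area(b))
        )

    def test_convex_border_rays_hit_boundary_once(self):
        b = ellipse_border(8.0, 6.0, n=128)
        cx, cy = border_center(b)
        f = radial_distances(b)
        boundary = b.polygon().exterior
        for ang in np.deg2rad(f.angles_deg):
            tip = (cx + 100 * np.cos(ang), cy + 100 * np.sin(ang))
            hit = LineString([(cx, cy), tip]).intersection(boundary)
            assert hit.geom_type == "Point"

    def test_center_outside_raises(self):
        # C-shaped annular ring: the centroid falls in the void
        th = np.linspace(np.deg2rad(30), np.deg2rad(330), 60)
        outer = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        inner = np.column_stack([9 * np.cos(th), 9 * np.sin(th)])[::-1]
        pts = np.vstack([outer, inner])
        b = LVBorder(points=pts, apex_index=0, mitral_indices=(10, 30))
        with pytest.raises(GeometryError):
            radial_distances(b)


class TestValidation:
    def test_too_few_vertices(self):
        with pytest.raises(BorderValidationError):
            LVBorder(points=np.array([[0, 0], [1, 0], [1, 1], [0, 1]],
                                     dtype=float),
                     apex_index=0, mitral_indices=(1, 2))

    def test_self_intersection_rejected(self):
        bow = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float)
        with pytest.raises(BorderValidationError):
            LVBorder(points=densify(bow, 5), apex_index=0,
                     mitral_indices=(5, 10))

    def test_landmarks_must_be_distinct(self):
        with pytest.raises(LandmarkError):
            LVBorder(points=circle_border().points, apex_index=3,
                     mitral_indices=(3, 10))

    def test_landmark_out_of_range(self):
        with pytest.raises(LandmarkError):
            LVBorder(points=circle_border().points, apex_index=999,
                     mitral_indices=(1, 2))

    def test_clockwise_input_normalized_with_landmarks(self):
        b_ccw = square_border(clockwise=False)
        b_cw = square_border(clockwise=True)
        # same apex coordinates after normalization
        assert polygon_area(b_cw) == pytest.approx(polygon_area(b_ccw))
        sig = 0.5 * np.sum(
            b_cw.points[:, 0] * np.roll(b_cw.points[:, 1], -1)
            - np.roll(b_cw.points[:, 0], -1) * b_cw.points[:, 1]
        )
        assert sig > 0  # stored counter-clockwise


class TestResample:
    def test_preserves_geometry_exactly(self):
        b = circle_border(7.0, n=64)
        r = resample_border(b, 256)
        assert r.n_vertices >= 256
        assert polygon_area(r) == pytest.approx(polygon_area(b), rel=1e-12)
        assert long_axis_length(r) == pytest.approx(long_axis_length(b))
        assert np.allclose(r.apex, b.apex)
        assert np.allclose(r.mitral_midpoint, b.mitral_midpoint)

    def test_dense_border_unchanged(self):
        b = circle_border(7.0, n=512)
        assert resample_border(b, 256) is b
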