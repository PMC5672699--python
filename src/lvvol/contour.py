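"""Endocardial border data model and radial featurization.

The left-ventricular (LV) endocardial border from a single-plane (4-chamber)
echocardiographic view is represented as a closed, simple polygon in
millimetre coordinates with two anatomical landmarks: the apical vertex and
the two endpoints of the mitral-annulus chord.  The border is summarised into
a fixed-length descriptor of 16 radial distances measured from the polygon's
area centroid to the boundary at equal 22.5-degree angular steps, with the
first ray aimed at the apex.  This descriptor is the input of the learned
volume estimators.

Conventions
-----------
* Coordinates are millimetres in a y-up frame; borders loaded from image
  space (y-down) must be flipped before construction.
* Stored vertex order is counter-clockwise; clockwise input is reversed on
  construction and landmark indices are remapped accordingly.
* "Center of border" is the polygon area centroid (robust to uneven vertex
  spacing from manual delineation), not the vertex mean.
* Rays sweep counter-clockwise from the apex ray; where a ray meets the
  boundary more than once the intersection farthest from the center is used,
  which is stable under small concavities of near-convex LV borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .errors import BorderValidationError, GeometryError, LandmarkError

__all__ = [
    "LVBorder",
    "RadialFeature",
    "polygon_area",
    "border_center",
    "long_axis_length",
    "radial_distances",
    "resample_border",
]


def _shoelace_signed_area(points: np.ndarray) -> float:
    """Signed area of a closed polygon given as an (n, 2) open vertex list.

    Positive for counter-clockwise orientation in a y-up frame.
    """
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _shoelace_centroid(points: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple polygon (open vertex list)."""
    x = points[:, 0]
    y = points[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-300:
        raise GeometryError("degenerate polygon: zero area")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return cx, cy


@dataclass
class LVBorder:
    """One closed 2D endocardial contour with anatomical landmarks.

    Parameters
    ----------
    points
        Ordered ``(n, 2)`` array of vertex coordinates in mm, ``n >= 16``.
        The polygon is implicitly closed (the last vertex joins the first).
    apex_index
        Index of the apical vertex.
    mitral_indices
        Pair of indices of the mitral-annulus chord endpoints.
    frame_id, case_id
        Identifiers carried through the pipeline.
    """

    points: np.ndarray
    apex_index: int
    mitral_indices: tuple[int, int]
    frame_id: str = "0"
    case_id: str = "0"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise BorderValidationError("points must be an (n, 2) array")
        # drop an explicit duplicate closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 16:
            raise BorderValidationError(
                f"border needs >= 16 vertices, got {len(pts)}"
            )
        if len(np.unique(pts.round(decimals=12), axis=0)) < 3:
            raise BorderValidationError("fewer than 3 distinct vertices")
        signed = _shoelace_signed_area(pts)
        if abs(signed) <= 0.0:
            raise BorderValidationError("polygon has zero area")
        n = len(pts)
        ai = int(self.apex_index)
        mi = (int(self.mitral_indices[0]), int(self.mitral_indices[1]))
        for idx in (ai, *mi):
            if not 0 <= idx < n:
                raise LandmarkError(f"landmark index {idx} out of range 0..{n - 1}")
        if len({ai, *mi}) != 3:
            raise LandmarkError("apex and mitral landmark indices must be distinct")
        if signed < 0:  # normalize to counter-clockwise, remap landmarks
            pts = pts[::-1].copy()
            ai = (n - 1) - ai
            mi = ((n - 1) - mi[0], (n - 1) - mi[1])
        if not Polygon(pts).is_valid:
            raise BorderValidationError("polygon is not simple (self-intersects)")
        self.points = pts
        self.apex_index = ai
        self.mitral_indices = mi

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def apex(self) -> np.ndarray:
        return self.points[self.apex_index]

    @property
    def mitral_midpoint(self) -> np.ndarray:
        i, j = self.mitral_indices
        return 0.5 * (self.points[i] + self.points[j])

    def polygon(self) -> Polygon:
        """The border as a shapely polygon."""
        return Polygon(self.points)

    def transformed(self, *, scale: float = 1.0, angle_deg: float = 0.0,
                    shift: tuple[float, float] = (0.0, 0.0)) -> "LVBorder":
        """Similarity-transformed copy (scale, then rotate, then translate)."""
        th = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = (self.points * scale) @ rot.T + np.asarray(shift, dtype=float)
        return replace(self, points=pts)


@dataclass
class RadialFeature:
    """Fixed-length radial descriptor of a border.

    ``distances[0]`` is the length of the ray aimed at the apex; subsequent
    rays advance counter-clockwise by a constant angular step, 22.5 degrees
    for the default 16 rays.
    """

    distances: np.ndarray
    center: tuple[float, float]
    angles_deg: np.ndarray
    frame_id: str = "0"
    case_id: str = "0"

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        a = np.asarray(self.angles_deg, dtype=float)
        if d.ndim != 1 or len(d) != len(a):
            raise BorderValidationError("distances and angles must align")
        if np.any(d <= 0):
            raise BorderValidationError("all radial distances must be > 0")
        step = 360.0 / len(d)
        if not np.allclose(np.diff(a), step, atol=1e-9):
            raise BorderValidationError(
                f"consecutive ray angles must differ by exactly {step} degrees"
            )
        self.distances = d
        self.angles_deg = a

    @property
    def n_rays(self) -> int:
        return len(self.distances)


def polygon_area(border: LVBorder) -> float:
    """Cavity area A in mm² (shoelace formula, orientation independent)."""
    return abs(_shoelace_signed_area(border.points))


def border_center(border: LVBorder) -> tuple[float, float]:
    """Area centroid of the border polygon, in mm."""
    return _shoelace_centroid(border.points)


def long_axis_length(border: LVBorder) -> float:
    """Long-axis length L in mm.

    Measured from the apical vertex to the midpoint of the chord joining the
    two mitral-annulus endpoints.
    """
    if border.apex_index in border.mitral_indices:
        raise LandmarkError("apex coincides with a mitral landmark")
    return float(np.linalg.norm(border.apex - border.mitral_midpoint))


def radial_distances(border: LVBorder, n_rays: int = 16) -> RadialFeature:
    """Equal-angle radial distances from the centroid to the boundary.

    Ray 0 points from the centroid toward the apex vertex; ray ``k`` is
    rotated counter-clockwise by ``k * 360 / n_rays`` degrees.  Each distance
    is measured to the boundary intersection farthest from the centroid.
    """
    if n_rays < 3:
        raise GeometryError("need at least 3 rays")
    cx, cy = border_center(border)
    poly = border.polygon()
    if not poly.contains(Point(cx, cy)):
        raise GeometryError("border center lies outside the polygon")
    apex = border.apex
    base_angle = float(np.arctan2(apex[1] - cy, apex[0] - cx))
    reach = 4.0 * float(
        np.max(np.linalg.norm(border.points - [cx, cy], axis=1))
    )
    boundary = poly.exterior
    step = 2.0 * np.pi / n_rays
    distances = np.empty(n_rays)
    for k in range(n_rays):
        ang = base_angle + k * step
        tip = (cx + reach * np.cos(ang), cy + reach * np.sin(ang))
        hit = LineString([(cx, cy), tip]).intersection(boundary)
        if hit.is_empty:
            raise GeometryError(f"ray {k} does not meet the boundary")
        # farthest intersection: covers Point, MultiPoint and (for rays
        # collinear with an edge) LineString pieces
        d = 0.0
        geoms = getattr(hit, "geoms", [hit])
        for g in geoms:
            for x, y in np.asarray(g.coords):
                d = max(d, float(np.hypot(x - cx, y - cy)))
        distances[k] = d
    angles = np.rad2deg(base_angle) + np.arange(n_rays) * (360.0 / n_rays)
    return RadialFeature(
        distances=distances,
        center=(cx, cy),
        angles_deg=angles,
        frame_id=border.frame_id,
        case_id=border.case_id,
    )


def resample_border(border: LVBorder, n_vertices: int = 256) -> LVBorder:
    """Geometry-preserving densification to at least ``n_vertices`` vertices.

    Every original vertex (landmarks included) is kept and each edge is
    subdivided uniformly until the total vertex count reaches the target, so
    the polygon is unchanged as a point set while chord and ray sampling
    gain resolution.  Borders already at or above the target density are
    returned unchanged; downsampling is never performed because it would cut
    corners and alter the geometry.
    """
    n = border.n_vertices
    if n >= n_vertices:
        return border
    pts = border.points
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.linalg.norm(edges, axis=1)
    perimeter = float(lengths.sum())
    spacing = perimeter / n_vertices
    # pieces per edge: at least 1, enough to reach the target overall
    pieces = np.maximum(1, np.ceil(lengths / spacing).astype(int))
    new_pts: list[np.ndarray] = []
    index_map: dict[int, int] = {}
    for i, (p, e, m) in enumerate(zip(pts, edges, pieces)):
        index_map[i] = sum(len(seg) for seg in new_pts)
        t = np.arange(m) / m  # includes the vertex, excludes the next one
        new_pts.append(p + t[:, None] * e)
    allpts = np.vstack(new_pts)
    return LVBorder(
        points=allpts,
        apex_index=index_map[border.apex_index],
        mitral_indices=(
            index_map[border.mitral_indices[0]],
            index_map[border.mitral_indices[1]],
        ),
        frame_id=border.frame_id,
        case_id=border.case_id,
    )
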