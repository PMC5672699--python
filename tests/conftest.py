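"""Shared fixtures and independent geometric oracles."""

from __future__ import annotations

import numpy as np
import pytest

from lvvol.contour import LVBorder


def densify(points: np.ndarray, pieces: int) -> np.ndarray:
    """Subdivide every edge of a closed polygon into ``pieces`` segments.

    Lets tests use geometrically exact low-vertex shapes (squares,
    triangles) while satisfying the >= 16 vertex border invariant; the
    polygon is unchanged as a point set.
    """
    points = np.asarray(points, dtype=float)
    out = []
    for p, q in zip(points, np.roll(points, -1, axis=0)):
        t = np.arange(pieces) / pieces
        out.append(p + t[:, None] * (q - p))
    return np.vstack(out)


def circle_border(radius: float = 7.0, center=(0.0, 0.0), n: int = 256,
                  apex_index: int = 0) -> LVBorder:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([
        center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)
    ])
    return LVBorder(points=pts, apex_index=apex_index,
                    mitral_indices=(n // 2 - 1, n // 2 + 1))


def ellipse_border(a: float = 10.0, b: float = 5.0, n: int = 1024) -> LVBorder:
    """Ellipse with the apex on the +x long axis and the mitral chord
    straddling the -x pole, so the landmark long axis is the full 2a."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    half = n // 2
    return LVBorder(points=pts, apex_index=0,
                    mitral_indices=(half - 1, half + 1))


@pytest.fixture
def circle7() -> LVBorder:
    return circle_border(7.0, n=256)


@pytest.fixture
def ellipse_20x10() -> LVBorder:
    """Dense ellipse border with L = 20 mm and D = 10 mm."""
    return ellipse_border(10.0, 5.0, n=2048)


def shoelace_reference(points: np.ndarray) -> float:
    """Independent area oracle: fan triangulation from the first vertex."""
    p0 = points[0]
    total = 0.0
    for p1, p2 in zip(points[1:-1], points[2:]):
        u, v = p1 - p0, p2 - p0
        total += 0.5 * (u[0] * v[1] - u[1] * v[0])
    return abs(float(total))


def exact_revolution_ml(border: LVBorder) -> float:
    """Exact method-of-disks volume of a polygon border, in ml.

    The chord function of a polygon is piecewise linear between the axial
    projections of its vertices, so the disk integral ∫(π/4)d(z)²dz is
    integrated exactly interval by interval.  Independent of simpson_volume's
    finite slicing.
    """
    from shapely.geometry import LineString

    apex = border.apex
    mid = border.mitral_midpoint
    length = float(np.linalg.norm(mid - apex))
    axis = (mid - apex) / length
    normal = np.array([-axis[1], axis[0]])
    reach = 4.0 * float(np.max(np.ptp(border.points, axis=0))) + length
    poly = border.polygon()

    def chord(z: float) -> float:
        p = apex + axis * z
        line = LineString([p - reach * normal, p + reach * normal])
        return float(line.intersection(poly).length)

    z = np.union1d(
        np.unique(np.clip((border.points - apex) @ axis, 0.0, length)),
        [0.0, length],
    )
    d = np.array([chord(zi) for zi in z])
    total = sum(
        (z2 - z1) * (d1 * d1 + d1 * d2 + d2 * d2) / 3.0
        for z1, z2, d1, d2 in zip(z, z[1:], d, d[1:])
    )
    return (np.pi / 4.0) * total / 1000.0


def random_star_polygon(rng: np.random.Generator, n: int = 64) -> np.ndarray:
    """A random simple (star-shaped) polygon for property tests."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    k = rng.integers(2, 6)
    r = 5.0 + rng.uniform(0.5, 2.0) * np.sin(k * th + rng.uniform(0, 2 * np.pi))
    r += rng.uniform(0.0, 0.5, size=n)
    c = rng.uniform(-10, 10, size=2)
    return np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)])
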