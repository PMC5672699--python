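"""Closed-form single-plane volume estimators.

Two classical estimators convert the 2D endocardial border area into a 3D
cavity volume under a geometric assumption:

* **Area-length** assumes the cavity is a prolate spheroid seen along its
  long axis.  With the single-plane area A (mm²) and long-axis length L (mm)
  the minor diameter is D = 4A/(πL) and the volume is

      V = 8 A² / (3 π L)            (= π L D² / 6 for a true ellipse).

* **Simpson's method of disks** stacks ``h`` short cylinders perpendicular
  to the long axis from apex to mitral midpoint.  With the chord (diameter)
  d_i of the border measured at the midpoint of slice i,

      V = (π/4) Σ d_i² · (L/h).

  The printed clinical formula often omits the slice height L/h; it is
  required for dimensional consistency and is included here.

Coordinates are mm; volumes are returned in ml (1 ml = 1000 mm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from shapely.geometry import LineString

from .contour import LVBorder, long_axis_length, polygon_area, resample_border
from .errors import ConfigurationError, GeometryError

__all__ = ["SimpsonConfig", "VolumeResult", "area_length_volume", "simpson_volume"]

MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class SimpsonConfig:
    """Discretization of Simpson's method of disks.

    ``n_slices`` is the number of cylinders h stacked along the long axis
    (clinical practice commonly uses 20); ``resample_vertices`` is the
    minimum boundary density used for chord measurement.
    """

    n_slices: int = 20
    resample_vertices: int = 256

    def __post_init__(self) -> None:
        if self.n_slices < 4:
            raise ConfigurationError("n_slices must be >= 4")
        if self.resample_vertices < 16:
            raise ConfigurationError("resample_vertices must be >= 16")


@dataclass
class VolumeResult:
    """A volume estimate with named intermediates for audit."""

    volume_ml: float
    method: str
    intermediates: dict[str, Any] = field(default_factory=dict)


def area_length_volume(border: LVBorder) -> VolumeResult:
    """Single-plane area-length volume, V = 8A²/(3πL), in ml."""
    area = polygon_area(border)
    length = long_axis_length(border)
    if length <= 0:
        raise GeometryError("long axis has zero length")
    diameter = 4.0 * area / (np.pi * length)
    volume_mm3 = 8.0 * area**2 / (3.0 * np.pi * length)
    return VolumeResult(
        volume_ml=volume_mm3 / MM3_PER_ML,
        method="area-length",
        intermediates={"A_mm2": area, "L_mm": length, "D_mm": diameter},
    )


def _chord_length(border: LVBorder, point: np.ndarray, normal: np.ndarray,
                  reach: float) -> float:
    """Total chord length of the border cut by the line through ``point``
    with direction ``normal``.  Multiple segments (concavities) are summed."""
    line = LineString([point - reach * normal, point + reach * normal])
    cut = line.intersection(border.polygon())
    return float(cut.length)


def simpson_volume(border: LVBorder, config: SimpsonConfig | None = None) -> VolumeResult:
    """Single-plane Simpson (method of disks) volume in ml.

    The long axis (apex → mitral midpoint) is divided into ``h`` equal
    slices; the disk diameter of slice i is the border chord perpendicular
    to the axis through the slice midpoint.  Slices whose plane misses the
    border (landmark jitter near the apex) contribute zero.
    """
    config = config or SimpsonConfig()
    border = resample_border(border, config.resample_vertices)
    length = long_axis_length(border)
    if length <= 0:
        raise GeometryError("long axis has zero length")
    apex = border.apex
    axis = (border.mitral_midpoint - apex) / length
    normal = np.array([-axis[1], axis[0]])
    reach = 4.0 * float(np.max(np.ptp(border.points, axis=0))) + length
    h = config.n_slices
    dz = length / h
    diameters = np.empty(h)
    for i in range(h):
        mid = apex + axis * (i + 0.5) * dz
        diameters[i] = _chord_length(border, mid, normal, reach)
    if np.all(diameters == 0):
        raise GeometryError("every slice chord is empty")
    volume_mm3 = (np.pi / 4.0) * float(np.sum(diameters**2)) * dz
    return VolumeResult(
        volume_ml=volume_mm3 / MM3_PER_ML,
        method="simpson",
        intermediates={
            "L_mm": length,
            "n_slices": h,
            "slice_height_mm": dz,
            "d_mm": diameters,
        },
    )
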