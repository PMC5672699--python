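"""Cardiac-function indices from a per-cycle volume series.

Given one cardiac cycle of left-ventricular volumes (40 frames in the
standard acquisition), the end-diastolic volume (EDV) is the cycle maximum,
the end-systolic volume (ESV) the minimum, and

    SV = EDV − ESV          (stroke volume, ml)
    EF = SV / EDV           (ejection fraction, dimensionless)

ED/ES are read off the volume curve itself rather than from ECG gating,
matching how a reconstructed fetal cycle is analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .contour import LVBorder, RadialFeature
from .errors import BorderValidationError, DegenerateCycleWarning

__all__ = ["FrameRecord", "CycleSeries", "FunctionIndices", "compute_indices"]


@dataclass
class FrameRecord:
    """One frame of a cycle: identifier, volume, and optionally the border
    and/or its radial feature."""

    frame_id: str
    volume_ml: float
    border: Optional[LVBorder] = None
    feature: Optional[RadialFeature] = None


@dataclass
class CycleSeries:
    """One cardiac cycle of a single case (40 frames by default)."""

    case_id: str
    frames: list[FrameRecord]

    def __post_init__(self) -> None:
        if not self.frames:
            raise BorderValidationError("cycle has no frames")
        if any(f.volume_ml <= 0 for f in self.frames):
            raise BorderValidationError("all cycle volumes must be > 0")

    @property
    def volumes(self) -> np.ndarray:
        return np.array([f.volume_ml for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class FunctionIndices:
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef: float
    ed_frame: int
    es_frame: int


def compute_indices(series: CycleSeries, smooth: bool = False) -> FunctionIndices:
    """EDV, ESV, SV and EF for one cycle.

    With ``smooth=True`` a circular 3-frame median filter is applied to the
    volume curve before picking the extremes, damping single-frame estimator
    noise.  A flat cycle (EDV == ESV) yields SV = EF = 0 with a
    :class:`DegenerateCycleWarning`.
    """
    v = series.volumes
    if smooth and len(v) >= 3:
        stacked = np.column_stack([np.roll(v, 1), v, np.roll(v, -1)])
        v = np.median(stacked, axis=1)
    ed = int(np.argmax(v))
    es = int(np.argmin(v))
    edv = float(v[ed])
    esv = float(v[es])
    sv = edv - esv
    if sv == 0.0:
        warnings.warn("constant volume curve: SV = EF = 0",
                      DegenerateCycleWarning, stacklevel=2)
        return FunctionIndices(edv, esv, 0.0, 0.0, ed, es)
    return FunctionIndices(edv, esv, sv, sv / edv, ed, es)
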