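"""Plain-text file formats: contour, feature and volume tables.

Contour files are tidy CSV with one row per vertex (``case_id, frame_id,
vertex_index, x_mm, y_mm``) plus landmark columns (``apex_index,
mitral_index_a, mitral_index_b``) repeated on every row of a frame.  Feature
files carry one row per frame with columns ``d01..d16`` (mm); volume files
one row per frame with ``volume_ml``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .contour import LVBorder, RadialFeature, radial_distances, resample_border
from .errors import BorderValidationError

__all__ = [
    "write_contours",
    "read_contours",
    "write_features",
    "read_features",
    "write_volumes",
    "read_volumes",
]


def write_contours(borders: Iterable[LVBorder], path: str | Path) -> None:
    rows = []
    for b in borders:
        for k, (x, y) in enumerate(b.points):
            rows.append({
                "case_id": b.case_id, "frame_id": b.frame_id,
                "vertex_index": k, "x_mm": x, "y_mm": y,
                "apex_index": b.apex_index,
                "mitral_index_a": b.mitral_indices[0],
                "mitral_index_b": b.mitral_indices[1],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours(path: str | Path, canonical_vertices: int = 256
                  ) -> list[LVBorder]:
    """Read a contour CSV, validating vertex ordering and closure.

    Borders are resampled on load to an arc-length parameterization of at
    least ``canonical_vertices`` vertices so downstream geometry has bounded
    discretization error regardless of input density.
    """
    df = pd.read_csv(path, dtype={"case_id": str, "frame_id": str})
    borders = []
    for (case_id, frame_id), grp in df.groupby(["case_id", "frame_id"],
                                               sort=False):
        grp = grp.sort_values("vertex_index")
        idx = grp["vertex_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise BorderValidationError(
                f"{case_id}/{frame_id}: vertex_index must run 0..n-1"
            )
        border = LVBorder(
            points=grp[["x_mm", "y_mm"]].to_numpy(dtype=float),
            apex_index=int(grp["apex_index"].iloc[0]),
            mitral_indices=(int(grp["mitral_index_a"].iloc[0]),
                            int(grp["mitral_index_b"].iloc[0])),
            frame_id=str(frame_id), case_id=str(case_id),
        )
        borders.append(resample_border(border, canonical_vertices))
    return borders


def write_features(features: Iterable[RadialFeature], path: str | Path) -> None:
    rows = []
    for f in features:
        row = {"case_id": f.case_id, "frame_id": f.frame_id}
        row.update({f"d{i + 1:02d}": v for i, v in enumerate(f.distances)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    """Feature table indexed by (case_id, frame_id) with columns d01..d16."""
    df = pd.read_csv(path, dtype={"case_id": str, "frame_id": str})
    cols = [f"d{i + 1:02d}" for i in range(16)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise BorderValidationError(f"feature file missing columns {missing}")
    return df.set_index(["case_id", "frame_id"])[cols]


def write_volumes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_volumes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "frame_id": str})
    if "volume_ml" not in df.columns:
        raise BorderValidationError("volume file needs a volume_ml column")
    return df


def featurize_borders(borders: Iterable[LVBorder]) -> list[RadialFeature]:
    """Convenience: radial features for a batch of borders."""
    return [radial_distances(b) for b in borders]
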