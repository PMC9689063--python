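"""File-boundary IO: MHD/RAW and NIfTI volumes, LUNA16-dialect CSVs.

The CSV dialect stores world-mm coordinates in ``coordX, coordY,
coordZ`` order while everything in memory is ``(z, y, x)``; these
readers/writers are the only place the axis order is flipped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import Candidate, CTVolume, LungMask, NoduleAnnotation

__all__ = [
    "read_volume",
    "write_volume",
    "write_luna_csv",
    "read_luna_csv",
    "write_candidates_csv",
    "read_candidates_csv",
    "write_sidecar",
    "read_sidecar",
]

ANNOTATION_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"]
CANDIDATE_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "probability"]


def read_volume(path: str | Path) -> CTVolume:
    """Read an MHD/RAW or NIfTI volume into (z,y,x) memory order."""
    img = sitk.ReadImage(str(path))
    grid = sitk.GetArrayFromImage(img)  # already (z,y,x)
    spacing = tuple(img.GetSpacing()[::-1])
    origin = tuple(img.GetOrigin()[::-1])
    return CTVolume(grid=grid, spacing=spacing, origin=origin)


def write_volume(vol: CTVolume | LungMask, path: str | Path) -> None:
    """Write to MHD or NIfTI; the extension selects the format."""
    img = sitk.GetImageFromArray(np.asarray(vol.grid))
    img.SetSpacing(tuple(float(s) for s in vol.spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in vol.origin[::-1]))
    sitk.WriteImage(img, str(path))


def write_luna_csv(annotations: list[NoduleAnnotation], path: str | Path) -> None:
    """Write annotations (world mm) in the LUNA16 column dialect."""
    rows = []
    for a in annotations:
        if a.unit != "world":
            raise ValueError("write_luna_csv requires world-mm annotations")
        z, y, x = a.center
        rows.append((a.scan_id, x, y, z, a.diameter))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_luna_csv(path: str | Path) -> list[NoduleAnnotation]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                NoduleAnnotation(
                    scan_id=str(row.seriesuid),
                    center=(float(row.coordZ), float(row.coordY), float(row.coordX)),
                    diameter=float(row.diameter_mm),
                    unit="world",
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: malformed row at line {i}: {err}") from err
    return out


def write_candidates_csv(candidates: list[Candidate],
                         centers_world: list[tuple[float, float, float]],
                         path: str | Path) -> None:
    """Candidate submission dialect (scan id, coordX/Y/Z, probability)."""
    rows = []
    for c, (z, y, x) in zip(candidates, centers_world):
        rows.append((c.scan_id, x, y, z, c.probability))
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_candidates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_sidecar(path: str | Path, crop_offset, original_shape,
                  spacing, origin) -> None:
    """JSON sidecar recording how a pre-image maps back to the raw scan."""
    payload = {
        "crop_offset_zyx": [int(v) for v in crop_offset],
        "original_shape_zyx": [int(v) for v in original_shape],
        "spacing_zyx": [float(v) for v in spacing],
        "origin_zyx": [float(v) for v in origin],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
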