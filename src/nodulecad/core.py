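"""Core domain types shared across the CAD pipeline.

Conventions
-----------
* All in-memory grids are indexed ``(z, y, x)``, 0-based voxel units.
* World coordinates (millimetres) appear only at file boundaries
  (LUNA16-dialect CSVs, MHD/NIfTI headers); the CSV column order is
  ``coordX, coordY, coordZ``, i.e. reversed with respect to memory.
* ``spacing`` and ``origin`` are ``(z, y, x)`` triples in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CTVolume", "LungMask", "NoduleAnnotation", "Candidate"]


@dataclass
class CTVolume:
    """A 3D scalar grid with geometry metadata.

    ``grid`` holds HU before intensity windowing and gray values in
    [0, 255] afterwards.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("CTVolume grid must be 3D (z,y,x)")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def world_to_voxel(self, world_zyx) -> np.ndarray:
        w = np.asarray(world_zyx, dtype=float)
        return (w - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_to_world(self, voxel_zyx) -> np.ndarray:
        v = np.asarray(voxel_zyx, dtype=float)
        return v * np.asarray(self.spacing) + np.asarray(self.origin)

    def copy_with(self, **kwargs) -> "CTVolume":
        return replace(self, **kwargs)


@dataclass
class LungMask:
    """Binary mask sharing geometry with its CTVolume."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(np.uint8)
        if self.grid.ndim != 3:
            raise ValueError("LungMask grid must be 3D (z,y,x)")

    @property
    def shape(self):
        return self.grid.shape


@dataclass
class NoduleAnnotation:
    """Ground-truth nodule: center, diameter and the unit of the center.

    ``unit`` is ``"world"`` (mm, in the scanner frame) or ``"voxel"``
    (continuous voxel index in some stated grid).  ``diameter`` is in mm
    for world annotations and in voxels for voxel annotations.
    """

    scan_id: str
    center: tuple[float, float, float]  # (z, y, x)
    diameter: float
    unit: str = "world"

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("nodule diameter must be positive")
        if self.unit not in ("world", "voxel"):
            raise ValueError(f"unknown unit {self.unit!r}")
        self.center = tuple(float(c) for c in self.center)
        self.diameter = float(self.diameter)

    def to_voxel(self, vol: CTVolume) -> "NoduleAnnotation":
        if self.unit == "voxel":
            return self
        center = tuple(vol.world_to_voxel(self.center))
        # isotropic grids only: diameter scales by the (common) spacing
        sp = vol.spacing
        if max(sp) - min(sp) > 1e-6:
            raise ValueError("voxel-diameter conversion requires isotropic spacing")
        return NoduleAnnotation(self.scan_id, center, self.diameter / sp[0], "voxel")

    def to_world(self, vol: CTVolume) -> "NoduleAnnotation":
        if self.unit == "world":
            return self
        center = tuple(vol.voxel_to_world(self.center))
        sp = vol.spacing
        if max(sp) - min(sp) > 1e-6:
            raise ValueError("world-diameter conversion requires isotropic spacing")
        return NoduleAnnotation(self.scan_id, center, self.diameter * sp[0], "world")


@dataclass
class Candidate:
    """A predicted nodule box with detector probability and optional
    second-stage score / lung-mask mean density."""

    center: tuple[float, float, float]  # (z, y, x), pre-image voxels
    diameter: float
    probability: float
    score: float | None = None
    mean_density: float | None = None
    scan_id: str = ""

    def __post_init__(self):
        self.center = tuple(float(c) for c in self.center)
        self.diameter = float(self.diameter)
        self.probability = float(self.probability)

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (*self.center, self.diameter)
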