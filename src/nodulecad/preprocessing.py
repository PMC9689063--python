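"""Raw CT scan -> pre-image and lung mask.

Pipeline (all grids (z,y,x)):

1. resample to isotropic spacing (linear interpolation);
2. binarize at -600 HU (air/lung foreground, strictly below threshold);
3. body mask: region-grow the exterior air from the 8 volume corners,
   logical-NOT, keep the largest connected component;
4. coarse lung mask = thresholded air inside the body; clean mask =
   dilation with a spherical structuring element of radius 6 voxels;
5. crop both to the mask bounding box, window HU [-1200, 600] to gray
   [0, 255] (floor, then clip) and fill non-lung voxels with gray 170.

The crop offset is returned so detections in pre-image coordinates can
be mapped back to the raw scan frame.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .core import CTVolume, LungMask

__all__ = [
    "HU_THRESHOLD",
    "FILL_GRAY",
    "resample_isotropic",
    "binarize_hu",
    "body_mask",
    "lung_mask",
    "crop_and_window",
    "preprocess_scan",
]

HU_THRESHOLD = -600.0
HU_WINDOW = (-1200.0, 600.0)
FILL_GRAY = 170
DILATION_RADIUS = 6

_CONN6 = ndimage.generate_binary_structure(3, 1)


def resample_isotropic(vol: CTVolume, target=(1.0, 1.0, 1.0)) -> CTVolume:
    """Resample to ``target`` mm/voxel with per-axis linear interpolation."""
    target = tuple(float(t) for t in target)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    factors = np.asarray(vol.spacing) / np.asarray(target)
    new_shape = np.round(np.asarray(vol.shape) * factors).astype(int)
    if np.allclose(new_shape, vol.shape) and np.allclose(vol.spacing, target):
        return vol.copy_with(grid=vol.grid.copy())
    zoom = new_shape / np.asarray(vol.shape)
    grid = ndimage.zoom(vol.grid.astype(np.float32), zoom, order=1,
                        mode="nearest", grid_mode=True)
    return CTVolume(grid=grid, spacing=target, origin=vol.origin)


def binarize_hu(vol: CTVolume, threshold: float = HU_THRESHOLD) -> np.ndarray:
    """Air/lung foreground: HU strictly below the threshold."""
    return (np.asarray(vol.grid) < threshold).astype(np.uint8)


def body_mask(binary: np.ndarray) -> np.ndarray:
    """Body = largest component of NOT(air connected to the corners).

    The exterior air is region-grown (6-connectivity) from the 8 volume
    vertices of the binarized image.
    """
    binary = np.asarray(binary).astype(bool)
    labels, _ = ndimage.label(binary, structure=_CONN6)
    nz, ny, nx = binary.shape
    corner_labels = {
        labels[z, y, x]
        for z in (0, nz - 1) for y in (0, ny - 1) for x in (0, nx - 1)
    } - {0}
    exterior = np.isin(labels, sorted(corner_labels)) if corner_labels else np.zeros_like(binary)
    body = ~exterior
    lab, n = ndimage.label(body, structure=_CONN6)
    if n == 0:
        raise ValueError("degenerate scan: empty body mask")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    body = lab == sizes.argmax()
    if not body.any():
        raise ValueError("degenerate scan: empty body mask")
    return body.astype(np.uint8)


def lung_mask(binary: np.ndarray, body: np.ndarray,
              dilation_radius: int = DILATION_RADIUS,
              spacing=(1.0, 1.0, 1.0)) -> LungMask:
    """Coarse lung = thresholded air inside the body; clean = dilated coarse."""
    if binary.shape != body.shape:
        raise ValueError("binary and body masks must share geometry")
    coarse = np.asarray(binary).astype(bool) & np.asarray(body).astype(bool)
    if not coarse.any():
        raise ValueError("degenerate scan: empty lung mask")
    clean = ndimage.binary_dilation(coarse, structure=ball(dilation_radius))
    return LungMask(grid=clean.astype(np.uint8), spacing=spacing)


def window_hu(grid: np.ndarray) -> np.ndarray:
    """HU [-1200, 600] -> gray [0, 255]; floor then clip."""
    lo, hi = HU_WINDOW
    gray = np.floor((np.asarray(grid, dtype=np.float64) - lo) / (hi - lo) * 255.0)
    return np.clip(gray, 0, 255).astype(np.uint8)


def crop_and_window(vol: CTVolume, mask: LungMask
                    ) -> tuple[CTVolume, LungMask, tuple[int, int, int]]:
    """Crop to the mask bounding box, window to gray, fill non-lung with 170."""
    m = np.asarray(mask.grid).astype(bool)
    if not m.any():
        raise ValueError("empty lung mask")
    slices = ndimage.find_objects(m.astype(np.uint8))[0]
    offset = tuple(int(s.start) for s in slices)
    sub_mask = m[slices]
    gray = window_hu(np.asarray(vol.grid)[slices])
    gray[~sub_mask] = FILL_GRAY
    pre = CTVolume(grid=gray, spacing=vol.spacing,
                   origin=tuple(o + s * sp for o, s, sp
                                in zip(vol.origin, offset, vol.spacing)))
    return pre, LungMask(grid=sub_mask.astype(np.uint8), spacing=vol.spacing,
                         origin=pre.origin), offset


def preprocess_scan(vol: CTVolume, target=(1.0, 1.0, 1.0)
                    ) -> tuple[CTVolume, LungMask, tuple[int, int, int]]:
    """Full pipeline: returns (pre-image, lung mask, crop offset).

    The crop offset is in the resampled (isotropic) frame.
    """
    iso = resample_isotropic(vol, target)
    binary = binarize_hu(iso)
    body = body_mask(binary)
    mask = lung_mask(binary, body, spacing=iso.spacing)
    return crop_and_window(iso, mask)
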