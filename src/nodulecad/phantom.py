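"""Synthetic lung phantoms with ground truth.

A phantom is a crude but geometrically honest chest: an elliptic-
cylinder body of soft tissue (+40 HU) in air (-1000 HU), containing two
ellipsoidal lung fields of air-like density (-800 HU).  Spherical
nodules (HU near water) are planted strictly inside the lung fields
with a small-diameter-skewed size law, and random-walk tubes at
nodule-like density act as vessel confounders — the structures a
detector must learn not to call nodules.

The generator is bit-deterministic for a fixed seed and returns the
volume, the truth lung mask, and world-mm annotations, so every
downstream stage (preprocessing, detection, scoring, evaluation) can be
exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CTVolume, LungMask, NoduleAnnotation
from .io import read_luna_csv, write_luna_csv  # re-exported for convenience

__all__ = [
    "PhantomSpec",
    "PhantomPackingError",
    "generate_phantom",
    "sample_diameters",
    "write_luna_csv",
    "read_luna_csv",
]


class PhantomPackingError(RuntimeError):
    """Raised when the requested nodules cannot be placed without overlap."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic chest volume.

    Defaults emulate the screening-dataset regime the system targets:
    nodule diameters 3-30 mm skewed toward small nodules (log-normal,
    median ~7 mm, mean ~8.3 mm), lungs at -800 HU inside a +40 HU body,
    nodules near water density, and mild acquisition noise.
    """

    volume_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_nodules: int = 5
    diameter_range: tuple[float, float] = (3.0, 30.0)
    diameter_skew: float = 0.55  # sigma of the log-normal size law
    n_vessels: int = 8
    hu_lung: float = -800.0
    hu_body: float = 40.0
    hu_nodule_range: tuple[float, float] = (-100.0, 100.0)
    hu_air: float = -1000.0
    noise_sd: float = 20.0
    seed: int = 0
    scan_id: str = ""

    def __post_init__(self):
        lo, hi = self.diameter_range
        if not (3.0 <= lo <= hi <= 30.0):
            raise ValueError("diameter_range must lie within [3, 30] mm")
        if self.n_nodules < 0 or self.n_vessels < 0:
            raise ValueError("counts must be nonnegative")
        if not self.scan_id:
            self.scan_id = f"phantom-{self.seed}"


def sample_diameters(n: int, rng: np.random.Generator,
                     diameter_range=(3.0, 30.0), skew: float = 0.55,
                     median: float = 7.0) -> np.ndarray:
    """Truncated log-normal diameters (mm), small-nodule dominated.

    Sampling is by inverse CDF between the truncation bounds, so narrow
    (even degenerate) ranges are exact and never loop.
    """
    lo, hi = diameter_range
    if hi == lo:
        return np.full(n, float(lo))
    dist = stats.lognorm(s=skew, scale=median)
    a, b = dist.cdf(lo), dist.cdf(hi)
    u = rng.uniform(a, b, size=n)
    return dist.ppf(u)


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _lung_geometry(shape):
    """Two lung ellipsoids inside an elliptic-cylinder body."""
    nz, ny, nx = shape
    body_center = (ny / 2.0, nx / 2.0)
    body_semi = (0.46 * ny, 0.46 * nx)
    lungs = []
    for fx in (0.32, 0.68):
        center = (nz / 2.0, ny / 2.0, fx * nx)
        semi = (0.40 * nz, 0.32 * ny, 0.17 * nx)
        lungs.append((center, semi))
    return body_center, body_semi, lungs


def _paint_ball(grid: np.ndarray, center, radius: float, value) -> None:
    zc, yc, xc = center
    lo = [max(0, int(np.floor(c - radius - 1))) for c in center]
    hi = [min(s, int(np.ceil(c + radius + 2))) for c, s in zip(center, grid.shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ball = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2 <= radius**2
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[ball] = value


def _place_nodules(spec: PhantomSpec, lungs, rng) -> list[tuple[np.ndarray, float]]:
    """Sample non-overlapping nodule centers strictly inside a lung."""
    diam_vox = sample_diameters(
        spec.n_nodules, rng, spec.diameter_range, spec.diameter_skew
    ) / spec.spacing[0]  # isotropic phantoms
    placed: list[tuple[np.ndarray, float]] = []
    for d in diam_vox:
        r = d / 2.0
        ok = False
        for _ in range(500):
            center, semi = lungs[rng.integers(len(lungs))]
            eff = np.asarray(semi) - r - 1.0
            if np.any(eff <= 0):
                continue
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(u**2) > 1.0:
                continue
            cand = np.asarray(center) + u * eff
            if all(
                np.linalg.norm(cand - c0) > (d + d0) / 2.0 + 2.0
                for c0, d0 in placed
            ):
                placed.append((cand, float(d)))
                ok = True
                break
        if not ok:
            raise PhantomPackingError(
                f"could not place {spec.n_nodules} non-overlapping nodules "
                f"(placed {len(placed)})"
            )
    return placed


def _grow_vessels(grid, lung_union, lungs, spec, rng) -> None:
    """Random-walk tubes of radius 1-3 voxels at nodule-like HU."""
    for _ in range(spec.n_vessels):
        center, semi = lungs[rng.integers(len(lungs))]
        pos = np.asarray(center) + rng.uniform(-0.5, 0.5, 3) * np.asarray(semi)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(1.0, 3.0)
        hu = rng.uniform(*spec.hu_nodule_range)
        n_steps = int(rng.integers(30, 80))
        for _ in range(n_steps):
            ip = tuple(np.clip(np.round(pos), 0, np.asarray(grid.shape) - 1).astype(int))
            if not lung_union[ip]:
                break
            _paint_ball(grid, pos, radius, hu)
            direction += 0.3 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, LungMask, list[NoduleAnnotation]]:
    """Build a phantom volume, its truth lung mask and annotations.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`PhantomPackingError` if the nodules cannot be packed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.volume_shape)
    grid = np.full(shape, spec.hu_air, dtype=np.float32)

    body_center, body_semi, lungs = _lung_geometry(shape)
    yy, xx = np.ogrid[: shape[1], : shape[2]]
    body2d = (
        ((yy - body_center[0]) / body_semi[0]) ** 2
        + ((xx - body_center[1]) / body_semi[1]) ** 2
    ) <= 1.0
    grid[:, body2d] = spec.hu_body

    lung_union = np.zeros(shape, dtype=bool)
    for center, semi in lungs:
        lung_union |= _ellipsoid_mask(shape, center, semi)
    grid[lung_union] = spec.hu_lung

    _grow_vessels(grid, lung_union, lungs, spec, rng)

    annotations: list[NoduleAnnotation] = []
    if spec.n_nodules:
        for center, d_vox in _place_nodules(spec, lungs, rng):
            hu = rng.uniform(*spec.hu_nodule_range)
            _paint_ball(grid, center, d_vox / 2.0, hu)
            world = center * np.asarray(spec.spacing)
            annotations.append(
                NoduleAnnotation(
                    scan_id=spec.scan_id,
                    center=tuple(world),
                    diameter=d_vox * spec.spacing[0],
                    unit="world",
                )
            )

    if spec.noise_sd > 0:
        grid += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    vol = CTVolume(grid=grid, spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    mask = LungMask(grid=lung_union.astype(np.uint8), spacing=spec.spacing)
    return vol, mask, annotations
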