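"""Volumetric containers with physical geometry.

A :class:`VoxelGrid` couples a 3D scalar array (indexed ``(z, y, x)``,
0-based, voxel centers at integer indices) with per-axis physical spacing
in µm and the linear expansion factor of the sample.  All physical
coordinates in this package are *expanded-sample* µm unless a function
explicitly converts to biological scale; :func:`effective_resolution`
performs that conversion for lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


@dataclass
class VoxelGrid:
    """3D scalar intensity field with physical metadata.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``.  Voxel centers sit at integer
        indices; the voxel at index ``i`` spans
        ``[i*spacing - spacing/2, i*spacing + spacing/2)`` physically.
    spacing
        ``(dz, dy, dx)`` in µm per voxel, all strictly positive.
    expansion_factor
        Dimensionless linear expansion of the specimen (1 = unexpanded).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"data must be 3D with positive extents, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(math.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive finite values, got {self.spacing}")
        if not self.expansion_factor >= 1:
            raise ValueError(f"expansion_factor must be >= 1, got {self.expansion_factor}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def nbytes(self) -> int:
        return self.data.nbytes

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's geometry."""
        return replace(self, data=data)

    def physical_extent(self) -> tuple[float, float, float]:
        """Per-axis physical extent in µm (voxel-span convention)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned physical box, half-open ``[lower, upper)`` per axis, in µm."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", tuple(float(v) for v in self.lower))
        object.__setattr__(self, "upper", tuple(float(v) for v in self.upper))
        if not all(lo < hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError(f"RegionBox requires lower < upper on every axis: {self.lower} vs {self.upper}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of ``(n, 3)`` physical points (z, y, x order)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.array(self.lower)
        hi = np.array(self.upper)
        return np.all((pts >= lo) & (pts < hi), axis=1)


def crop(grid: VoxelGrid, box: RegionBox) -> VoxelGrid:
    """Extract the sub-grid of voxels whose centers fall inside ``box``.

    Spacing is unchanged.  Raises ``ValueError`` on empty intersection.
    Used e.g. to split an organism into head and trunk compartments, or to
    cut a fixed-size census region.
    """
    slices = []
    for ax in range(3):
        s = grid.spacing[ax]
        # voxel center i*s in [lower, upper)
        first = max(0, math.ceil(box.lower[ax] / s - 1e-9))
        last = min(grid.shape[ax], math.ceil(box.upper[ax] / s - 1e-9))
        if last <= first:
            raise ValueError(f"box {box} does not intersect grid on axis {ax}")
        slices.append(slice(first, last))
    return grid.with_data(grid.data[tuple(slices)])


def resample(
    grid: VoxelGrid,
    target_spacing: tuple[float, float, float] | None = None,
    max_bytes: int | None = None,
) -> VoxelGrid:
    """Linearly resample a grid to a coarser spacing or under a byte budget.

    Exactly one of ``target_spacing`` / ``max_bytes`` must be given.
    Budget mode applies an isotropic (in voxel counts) downscale factor
    ``f = max(1, (nbytes/max_bytes)**(1/3))``, rounded up to the nearest
    rational giving integer extents, so the output fits the budget while
    preserving aspect ratios.  Interpolation is linear; downsampling only.
    """
    if (target_spacing is None) == (max_bytes is None):
        raise ValueError("give exactly one of target_spacing or max_bytes")
    shape = grid.shape
    if max_bytes is not None:
        if max_bytes <= 0:
            raise ValueError("byte budget must be positive")
        f = max(1.0, (grid.nbytes / max_bytes) ** (1.0 / 3.0))
        new_shape = tuple(max(1, math.floor(n / f)) for n in shape)
    else:
        ts = tuple(float(t) for t in target_spacing)
        if any(t < s - 1e-12 for t, s in zip(ts, grid.spacing)):
            raise ValueError(f"resample only downsamples: target {ts} finer than spacing {grid.spacing}")
        new_shape = tuple(max(1, round(n * s / t)) for n, s, t in zip(shape, grid.spacing, ts))
    if any(n < 1 for n in new_shape):
        raise ValueError("resampling would produce an empty grid")
    zoom = [nn / n for nn, n in zip(new_shape, shape)]
    out = ndimage.zoom(grid.data.astype(np.float32, copy=False), zoom, order=1, mode="nearest", grid_mode=True)
    new_spacing = tuple(s * n / nn for s, n, nn in zip(grid.spacing, shape, new_shape))
    return VoxelGrid(out, spacing=new_spacing, expansion_factor=grid.expansion_factor)


def effective_resolution(
    optical_resolution: tuple[float, ...] | float,
    expansion_factor: float,
) -> tuple[float, ...] | float:
    """Post-expansion (biological-scale) resolution.

    Physical expansion magnifies the specimen by ``expansion_factor``
    linearly, so a microscope resolving ``r`` µm in the expanded gel
    resolves ``r / expansion_factor`` µm of original tissue.  E.g. a
    5 µm axial optical resolution at 4× expansion gives 1.25 µm effective.
    """
    if not expansion_factor > 0:
        raise ValueError("expansion_factor must be positive")
    scalar = np.isscalar(optical_resolution)
    res = np.atleast_1d(np.asarray(optical_resolution, dtype=float))
    if np.any(res <= 0):
        raise ValueError("optical resolution components must be positive")
    eff = res / float(expansion_factor)
    return float(eff[0]) if scalar else tuple(float(v) for v in eff)
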