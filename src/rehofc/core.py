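"""Shared spatial data model: grids, 4D volumes, masks, motion traces, stat maps.

All images live on an :class:`ImageGrid` — a voxel lattice with a NIfTI-style
4x4 affine mapping 0-based voxel indices to millimetre coordinates (RAS+
assumed for synthetic data).  Every downstream operation (preprocessing, ReHo,
seed connectivity, group statistics) consumes and produces these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ImageGrid",
    "Volume4D",
    "BrainMask",
    "MotionTrace",
    "StatMap",
    "voxel_to_mm",
    "mm_to_voxel",
    "sphere_mask",
]

StatKind = Literal["W", "mW", "r", "z", "t", "p"]


class GridMismatchError(ValueError):
    """Two objects that must share a grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3D voxel lattice with an affine index->mm mapping.

    Parameters
    ----------
    dims : tuple of int
        Grid extent ``(nx, ny, nz)``; every entry >= 1.
    affine : (4, 4) ndarray
        Invertible homogeneous matrix taking 0-based voxel indices to mm.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {self.dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @classmethod
    def isotropic(
        cls,
        dims: tuple[int, int, int],
        voxel_size_mm: float = 3.0,
        origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "ImageGrid":
        """Axis-aligned grid with equal voxel size; index (0,0,0) maps to *origin_mm*."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
        aff[:3, 3] = origin_mm
        return cls(dims=tuple(dims), affine=aff)

    def same_geometry(self, other: "ImageGrid", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)


def voxel_to_mm(grid: ImageGrid, index) -> np.ndarray:
    """Map voxel indices (0-based, possibly fractional) to mm coordinates.

    Accepts a single triple or an (N, 3) array; returns the same shape.
    """
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    out = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return out[0] if np.asarray(index).ndim == 1 else out


def mm_to_voxel(grid: ImageGrid, coord_mm) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm`; returns fractional voxel indices."""
    inv = np.linalg.inv(grid.affine)
    xyz = np.atleast_2d(np.asarray(coord_mm, dtype=float))
    out = xyz @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if np.asarray(coord_mm).ndim == 1 else out


@dataclass
class Volume4D:
    """One subject's BOLD series: ``data`` of shape ``(*grid.dims, n_timepoints)``."""

    grid: ImageGrid
    data: np.ndarray
    tr_seconds: float = 3.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D data must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.dims:
            raise GridMismatchError(
                f"data spatial shape {self.data.shape[:3]} != grid dims {self.grid.dims}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def copy_with(self, data: np.ndarray) -> "Volume4D":
        return Volume4D(grid=self.grid, data=data, tr_seconds=self.tr_seconds)


@dataclass
class BrainMask:
    """Boolean voxel set on a grid; at least one voxel inside."""

    grid: ImageGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise GridMismatchError(
                f"mask shape {self.data.shape} != grid dims {self.grid.dims}"
            )
        if not self.data.any():
            raise ValueError("mask is empty")

    @property
    def n_inside(self) -> int:
        return int(self.data.sum())

    def check_same_grid(self, other) -> None:
        if not self.grid.same_geometry(other.grid):
            raise GridMismatchError("objects are on different grids")


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per timepoint.

    ``translations_mm``: (n, 3) head shift along x, y, z in millimetres.
    ``rotations_rad``: (n, 3) rotation about x, y, z in radians (the common
    rp-file dialect; degree thresholds are converted at comparison time).
    """

    translations_mm: np.ndarray
    rotations_rad: np.ndarray

    def __post_init__(self):
        self.translations_mm = np.asarray(self.translations_mm, dtype=float)
        self.rotations_rad = np.asarray(self.rotations_rad, dtype=float)
        for arr, name in ((self.translations_mm, "translations_mm"), (self.rotations_rad, "rotations_rad")):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must have shape (n, 3)")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
        if len(self.translations_mm) != len(self.rotations_rad):
            raise ValueError("translation and rotation lengths differ")

    @property
    def n_timepoints(self) -> int:
        return len(self.translations_mm)

    @property
    def rotations_deg(self) -> np.ndarray:
        return np.degrees(self.rotations_rad)


@dataclass
class StatMap:
    """Scalar statistic per voxel (W, r, z, t or p) with its mask and provenance.

    ``data`` covers the full grid; out-of-mask voxels are zero by convention.
    ``flags`` marks voxels whose value is degenerate (zero variance, truncated
    neighborhood, clamped correlation) and is carried through I/O sidecars.
    """

    grid: ImageGrid
    mask: BrainMask
    kind: StatKind
    data: np.ndarray
    meta: dict = field(default_factory=dict)
    flags: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.dims:
            raise GridMismatchError(
                f"stat data shape {self.data.shape} != grid dims {self.grid.dims}"
            )
        if not self.mask.grid.same_geometry(self.grid):
            raise GridMismatchError("mask grid differs from stat map grid")
        inside = self.data[self.mask.data]
        if not np.isfinite(inside).all():
            raise ValueError("non-finite values inside mask")
        lo, hi = {"W": (0, 1), "r": (-1, 1), "p": (0, 1)}.get(self.kind, (None, None))
        if lo is not None and ((inside < lo - 1e-9).any() or (inside > hi + 1e-9).any()):
            raise ValueError(f"kind {self.kind!r} values outside [{lo}, {hi}]")
        # enforce the out-of-mask = 0 convention
        out = ~self.mask.data
        if out.any():
            self.data = self.data.copy()
            self.data[out] = 0.0

    @property
    def values(self) -> np.ndarray:
        """In-mask values, flattened in C order of the mask."""
        return self.data[self.mask.data]


def sphere_mask(grid: ImageGrid, center_mm, radius_mm: float) -> np.ndarray:
    """Boolean array of voxels whose center lies within *radius_mm* of *center_mm*.

    Inclusion is by center-to-center Euclidean distance with a <= comparison.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    nx, ny, nz = grid.dims
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    mm = voxel_to_mm(grid, idx)
    d2 = ((mm - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=1)
    return (d2 <= radius_mm**2 + 1e-9).reshape(grid.dims)
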