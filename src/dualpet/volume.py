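"""Voxel grids, activity volumes, VOIs and geometric primitives.

World coordinates are axis-aligned, in millimetres, and voxel-center based:
voxel index ``i`` along an axis sits at ``origin_mm + i * voxel_size_mm``.
A voxel belongs to a shape iff its *center* lies inside the shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "ActivityVolume",
    "VOI",
    "Ellipsoid",
    "Cylinder",
    "Box",
    "save_nifti",
    "load_nifti",
]


@dataclass(frozen=True)
class Grid:
    """Geometry of a voxel lattice: shape, isotropic spacing and world origin."""

    shape: tuple[int, int, int]
    voxel_size_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @classmethod
    def centered(cls, shape: Sequence[int], voxel_size_mm: float) -> "Grid":
        """Grid whose world origin puts (0, 0, 0) at the lattice center."""
        shape = tuple(int(n) for n in shape)
        origin = tuple(-(n - 1) / 2.0 * voxel_size_mm for n in shape)
        return cls(shape, float(voxel_size_mm), origin)

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open (broadcastable) arrays of voxel-center world coordinates."""
        axes = [
            self.origin_mm[k] + self.voxel_size_mm * np.arange(self.shape[k], dtype=float)
            for k in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore[return-value]

    def world_to_index(self, point_mm: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index for a world point; raises if outside the grid."""
        idx = tuple(
            int(round((float(point_mm[k]) - self.origin_mm[k]) / self.voxel_size_mm))
            for k in range(3)
        )
        if any(i < 0 or i >= self.shape[k] for k, i in enumerate(idx)):
            raise ValueError(f"point {tuple(point_mm)} mm lies outside the grid")
        return idx  # type: ignore[return-value]

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass
class ActivityVolume:
    """3-D activity-concentration image in Bq/mL on a :class:`Grid`."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")

    @property
    def voxel_size_mm(self) -> float:
        return self.grid.voxel_size_mm


@dataclass
class VOI:
    """Boolean voxel mask on a parent grid, with label and placement provenance."""

    mask: np.ndarray
    grid: Grid
    label: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("VOI mask shape does not match grid")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mL(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mL

    @property
    def empty(self) -> bool:
        return not self.mask.any()


# ---------------------------------------------------------------------------
# geometric primitives (all dimensions in mm, world coordinates)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("ellipsoid radii must be > 0")

    @property
    def volume_mL(self) -> float:
        return 4.0 / 3.0 * np.pi * np.prod(self.radii) / 1000.0

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    def mask(self, grid: Grid) -> np.ndarray:
        x, y, z = grid.coordinate_arrays()
        return self.contains(x, y, z)


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder; ``axis`` is the long axis (default 2 = cranio-caudal)."""

    center: tuple[float, float, float]
    radius_mm: float
    height_mm: float
    axis: int = 2

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise ValueError("cylinder radius and height must be > 0")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")

    @property
    def volume_mL(self) -> float:
        return np.pi * self.radius_mm**2 * self.height_mm / 1000.0

    def contains(self, x, y, z) -> np.ndarray:
        coords = [x, y, z]
        d_long = np.abs(coords[self.axis] - self.center[self.axis])
        trans = [k for k in range(3) if k != self.axis]
        r2 = sum((coords[k] - self.center[k]) ** 2 for k in trans)
        return (d_long <= self.height_mm / 2.0) & (r2 <= self.radius_mm**2)

    def mask(self, grid: Grid) -> np.ndarray:
        x, y, z = grid.coordinate_arrays()
        return self.contains(x, y, z)


@dataclass(frozen=True)
class Box:
    center: tuple[float, float, float]
    size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("box sizes must be > 0")

    @property
    def volume_mL(self) -> float:
        return float(np.prod(self.size_mm)) / 1000.0

    def contains(self, x, y, z) -> np.ndarray:
        out = True
        for coord, c, s in zip((x, y, z), self.center, self.size_mm):
            out = out & (np.abs(coord - c) <= s / 2.0)
        return out

    def mask(self, grid: Grid) -> np.ndarray:
        x, y, z = grid.coordinate_arrays()
        return self.contains(x, y, z)


Shape = Ellipsoid | Cylinder | Box


def shift_integer_voxels(values: np.ndarray, shift: Sequence[int], fill=0) -> np.ndarray:
    """Rigidly shift a voxel array by whole voxels, filling exposed edges.

    Used for co-registration robustness experiments: the two scans of a dual
    study share one grid (identity registration), and this applies a
    controlled integer-voxel mis-registration.
    """
    out = np.full_like(values, fill)
    src, dst = [], []
    for n, s in zip(values.shape, shift):
        s = int(s)
        if abs(s) >= n:
            return out
        src.append(slice(max(0, -s), min(n, n - s)))
        dst.append(slice(max(0, s), min(n, n + s)))
    out[tuple(dst)] = values[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# NIfTI round trip


def save_nifti(values: np.ndarray, grid: Grid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(values), grid.affine())
    img.header.set_zooms((grid.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError("only isotropic voxels are supported")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    grid = Grid(tuple(img.shape[:3]), float(zooms[0]), origin)
    return np.asarray(img.dataobj, dtype=float), grid
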