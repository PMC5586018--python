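"""Volume and mask containers on a regular voxel grid.

Conventions used throughout the package:

* arrays are indexed ``values[i, j, k]`` with axis order (x, y, z);
* voxel indices are 0-based and a voxel's *center* sits at world position
  ``origin_mm + index * voxel_size_mm`` (millimetres, elementwise);
* grids are axis-aligned — orientation is carried by rigid transforms, not
  by the grid itself.

The value of a PET voxel is a standardized uptake value (SUV), a
dimensionless, non-negative activity concentration normalized to injected
dose and body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = ["GridGeometry", "SUVVolume", "ROIMask", "GeometryError"]


class GeometryError(ValueError):
    """Raised when grids that must share a geometry do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of a regular voxel grid."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to world mm coordinates (voxel centers)."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(
            self.voxel_size_mm
        )

    def world_to_index(self, world_mm: np.ndarray) -> np.ndarray:
        """Map (…, 3) world mm coordinates to fractional voxel indices."""
        return (np.asarray(world_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(
            self.voxel_size_mm
        )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        )
        return self.index_to_world(idx)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((self.shape, self.voxel_size_mm, self.origin_mm))


def _require_same_geometry(a: "GridGeometry", b: "GridGeometry", what: str) -> None:
    if a != b:
        raise GeometryError(f"{what}: geometries differ ({a} vs {b})")


@dataclass
class SUVVolume:
    """A 3-D grid of standardized uptake values.

    Values are finite and non-negative; spacing defaults to the 1 x 1 x 2 mm
    analysis grid.
    """

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("SUVVolume values must be a 3-D array")
        if tuple(self.values.shape) != self.geometry.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.geometry.shape

    def copy(self) -> "SUVVolume":
        return SUVVolume(self.values.copy(), self.geometry)


@dataclass
class ROIMask:
    """A binary region-of-interest mask aligned to a volume grid.

    ``label`` names the anatomical role: the contoured primary tumor
    (equal to the gross tumor volume), the contoured recurrent tumor mapped
    into the pre-treatment frame, or a muscle reference region.
    """

    values: np.ndarray
    geometry: GridGeometry
    label: str = "primary"

    VALID_LABELS = ("primary", "recurrence", "muscle", "hypoxia")

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError("ROIMask values must be a 3-D array")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary (0/1)")
            arr = arr.astype(bool)
        self.values = arr
        if tuple(arr.shape) != self.geometry.shape:
            raise GeometryError(
                f"mask shape {arr.shape} != geometry shape {self.geometry.shape}"
            )
        if self.label not in self.VALID_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def n_voxels(self) -> int:
        """Cardinality of the mask (number of selected voxels)."""
        return int(self.values.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) integer indices of selected voxels, in C order."""
        return np.argwhere(self.values)

    def issubset(self, other: "ROIMask") -> bool:
        _require_same_geometry(self.geometry, other.geometry, "mask comparison")
        return bool(np.all(~self.values | other.values))

    def copy(self) -> "ROIMask":
        return ROIMask(self.values.copy(), self.geometry, self.label)
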