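"""Tumor-to-muscle ratio (TMR) normalization and grayscale data-file export.

FMISO uptake is normalized to resting muscle: four spherical reference
regions of 1 cm radius are placed on the posterior cervical muscles, the
maximum SUV inside each sphere is taken, and the mean of the four maxima
is the muscle reference. Dividing every voxel SUV by that reference gives
the TMR, the hypoxia surrogate all downstream statistics run on.

The original analysis exchanged images as 256-level grayscale data files:
per-slice integer matrices with 0 reserved for voxels outside the region
of interest. `quantize_255` / `export_datafile` / `read_datafile`
reproduce that representation losslessly; the statistics in
:mod:`fmisovox.stats` use the continuous TMR values by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import GeometryError, GridGeometry, ROIMask, SUVVolume, _require_same_geometry

__all__ = [
    "MuscleROISpec",
    "TMRMap",
    "QuantizedGrid",
    "EmptyMuscleROIError",
    "muscle_reference",
    "compute_tmr",
    "mask_outside",
    "quantize_255",
    "export_datafile",
    "read_datafile",
]


class EmptyMuscleROIError(ValueError):
    """A muscle reference sphere contains no voxel of the volume."""


@dataclass(frozen=True)
class MuscleROISpec:
    """Four spherical muscle reference regions (world mm).

    A voxel belongs to a sphere when its center lies within ``radius_mm``
    of the sphere center.
    """

    centers_mm: tuple[tuple[float, float, float], ...]
    radius_mm: float = 10.0

    def __post_init__(self) -> None:
        centers = tuple(tuple(float(c) for c in ctr) for ctr in self.centers_mm)
        if len(centers) != 4:
            raise ValueError(f"exactly 4 muscle ROI centers required, got {len(centers)}")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        object.__setattr__(self, "centers_mm", centers)

    def sphere_mask(self, geometry: GridGeometry, which: int) -> np.ndarray:
        """Boolean voxel mask of sphere ``which`` on ``geometry``."""
        centers = geometry.voxel_centers()
        d2 = np.sum((centers - np.asarray(self.centers_mm[which])) ** 2, axis=-1)
        return d2 <= self.radius_mm**2

    def masks(self, geometry: GridGeometry) -> list[np.ndarray]:
        return [self.sphere_mask(geometry, i) for i in range(4)]


@dataclass
class TMRMap:
    """Per-voxel tumor-to-muscle ratios plus the muscle reference used.

    Voxels excluded from analysis (outside the region of interest) are
    NaN — deliberately distinct from a genuine TMR of 0, so the exported
    grayscale convention "0 = outside" never collides with a measurement.
    """

    values: np.ndarray
    geometry: GridGeometry
    reference_suvmax: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or tuple(self.values.shape) != self.geometry.shape:
            raise GeometryError("TMR values shape must match geometry")
        if not self.reference_suvmax > 0:
            raise ValueError("reference_suvmax must be positive")

    @property
    def defined_mask(self) -> np.ndarray:
        """Boolean mask of voxels carrying a TMR value (not excluded)."""
        return np.isfinite(self.values)

    def defined_values(self) -> np.ndarray:
        """Flat array of the non-excluded TMR values."""
        return self.values[self.defined_mask]


@dataclass
class QuantizedGrid:
    """Integer 0–255 grayscale grid; 0 is reserved for outside-ROI voxels."""

    values: np.ndarray
    geometry: GridGeometry
    window: tuple[float, float]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.dtype != np.uint8:
            if vals.min() < 0 or vals.max() > 255:
                raise ValueError("quantized values must lie in 0..255")
            vals = vals.astype(np.uint8)
        self.values = vals
        if tuple(vals.shape) != self.geometry.shape:
            raise GeometryError("quantized grid shape must match geometry")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("window must satisfy lo < hi")


def muscle_reference(volume: SUVVolume, spec: MuscleROISpec) -> float:
    """Mean over the four muscle spheres of each sphere's maximum SUV.

    Raises
    ------
    EmptyMuscleROIError
        If a sphere contains no voxel center (sphere outside the field of
        view); the error names the offending ROI.
    """
    maxima = []
    for i, mask in enumerate(spec.masks(volume.geometry)):
        if not mask.any():
            raise EmptyMuscleROIError(
                f"muscle ROI {i} at {spec.centers_mm[i]} mm contains no voxel"
            )
        maxima.append(float(volume.values[mask].max()))
    return float(np.mean(maxima))


def compute_tmr(volume: SUVVolume, reference: float) -> TMRMap:
    """Divide every voxel SUV by the muscle reference SUVmax."""
    if not reference > 0:
        raise ValueError(f"muscle reference must be positive, got {reference}")
    return TMRMap(volume.values / float(reference), volume.geometry, float(reference))


def mask_outside(tmr: TMRMap, roi: ROIMask) -> TMRMap:
    """Exclude (set to NaN) every voxel outside ``roi``; keep the rest."""
    _require_same_geometry(tmr.geometry, roi.geometry, "mask_outside")
    vals = np.where(roi.values, tmr.values, np.nan)
    return TMRMap(vals, tmr.geometry, tmr.reference_suvmax)


def quantize_255(tmr: TMRMap, window: tuple[float, float] = (0.0, 4.0)) -> QuantizedGrid:
    """Linearly map TMR in ``[lo, hi]`` to gray levels 1..255, clamping.

    Excluded (NaN) voxels map to 0; the map is monotone in TMR. The default
    window (0, 4) covers every ratio the analysis produces with headroom.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError(f"reversed or empty window {window}")
    defined = tmr.defined_mask
    scaled = 1.0 + 254.0 * (tmr.values - lo) / (hi - lo)
    with np.errstate(invalid="ignore"):
        levels = np.clip(np.rint(scaled), 1, 255)
    out = np.where(defined, levels, 0.0).astype(np.uint8)
    return QuantizedGrid(out, tmr.geometry, (lo, hi))


def export_datafile(grid: QuantizedGrid, path: str | Path, matrix_size: int = 512) -> Path:
    """Write per-axial-slice integer matrices, zero-padded to a square matrix.

    One whitespace-delimited ``matrix_size`` x ``matrix_size`` block per z
    slice, blocks separated by a blank line, with the grid placed in the
    top-left corner. Round-trips losslessly through :func:`read_datafile`.
    """
    nx, ny, nz = grid.geometry.shape
    if nx > matrix_size or ny > matrix_size:
        raise ValueError(
            f"grid plane {nx}x{ny} exceeds target matrix {matrix_size}x{matrix_size}"
        )
    path = Path(path)
    lo, hi = grid.window
    with path.open("w") as fh:
        fh.write(f"# fmisovox datafile nx={nx} ny={ny} nz={nz} matrix={matrix_size}\n")
        fh.write(f"# window_lo={lo!r} window_hi={hi!r}\n")
        padded = np.zeros((matrix_size, matrix_size), dtype=np.uint16)
        for k in range(nz):
            padded[:, :] = 0
            padded[:nx, :ny] = grid.values[:, :, k]
            np.savetxt(fh, padded, fmt="%d")
            fh.write("\n")
    return path


def read_datafile(path: str | Path) -> QuantizedGrid:
    """Read a data file written by :func:`export_datafile`.

    Warns when the file contains no in-ROI voxel (all values 0).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# fmisovox datafile"):
            raise ValueError(f"{path} is not a recognized datafile")
        meta = dict(tok.split("=") for tok in header.split()[3:])
        wline = fh.readline().strip()
        wmeta = dict(tok.split("=") for tok in wline.split()[1:])
        nx, ny, nz = int(meta["nx"]), int(meta["ny"]), int(meta["nz"])
        msize = int(meta["matrix"])
        flat = np.loadtxt(fh, dtype=np.uint16)
    planes = flat.reshape(nz, msize, msize)
    values = np.transpose(planes, (1, 2, 0))[:nx, :ny, :].astype(np.uint8)
    if not values.any():
        warnings.warn("datafile contains no in-ROI voxels (all zero)", stacklevel=2)
    geom = GridGeometry((nx, ny, nz))
    return QuantizedGrid(values, geom, (float(wmeta["window_lo"]), float(wmeta["window_hi"])))
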