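"""Landmark-based rigid registration and grid resampling.

Recurrence-time image sets are aligned to the pre-treatment frame by a
proper rigid motion (rotation + translation, no scaling or shear) fitted
to paired anatomical landmarks — in practice bone landmarks, which are
unaffected by tumor regression. The fit is the closed-form least-squares
solution (Kabsch/Umeyama): it minimizes the sum of squared distances
between transformed moving landmarks and their fixed counterparts, with
the reflection-optimal case resolved to a proper rotation.

Transforms map the *moving* frame into the *fixed* frame:
``x_fixed = R @ x_moving + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridGeometry, ROIMask, SUVVolume

__all__ = [
    "RigidTransform",
    "LandmarkSet",
    "DegenerateLandmarksError",
    "fit_rigid_landmarks",
    "landmark_rmsd",
    "resample",
]

_ORTHO_TOL = 1e-9


class DegenerateLandmarksError(ValueError):
    """Landmark configuration does not determine a unique rigid motion."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: ``x_out = rotation @ x_in + translation_mm``."""

    rotation: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation_mm, dtype=np.float64).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation must be orthonormal (R^T R = I)")
        if np.linalg.det(r) < 0:
            raise ValueError("improper rotation (det = -1): reflections are not rigid motions")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation_mm", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis: tuple[float, float, float],
        angle_deg: float,
        translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
        center_mm: tuple[float, float, float] | None = None,
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` (optionally about ``center_mm``)
        followed by a translation."""
        from scipy.spatial.transform import Rotation

        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        r = Rotation.from_rotvec(np.deg2rad(angle_deg) * ax).as_matrix()
        t = np.asarray(translation_mm, dtype=float)
        if center_mm is not None:
            c = np.asarray(center_mm, dtype=float)
            t = t + c - r @ c
        return cls(r, t)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Transform (…, 3) world coordinates."""
        pts = np.asarray(points_mm, dtype=float)
        return pts @ self.rotation.T + self.translation_mm

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation_mm + self.translation_mm,
        )

    def is_identity(self, atol: float = 1e-12) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=atol) and np.allclose(
            self.translation_mm, 0.0, atol=atol
        )


@dataclass
class LandmarkSet:
    """Ordered anatomical landmark coordinates in world millimetres."""

    points_mm: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_mm, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points_mm must be (n, 3)")
        self.points_mm = pts
        if self.names is not None and len(self.names) != len(pts):
            raise ValueError("names length must match number of points")

    def __len__(self) -> int:
        return len(self.points_mm)

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(t.apply(self.points_mm), self.names)


def _check_pairs(moving: LandmarkSet, fixed: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    if len(moving) == 0 or len(fixed) == 0:
        raise ValueError("landmark sets must be non-empty")
    if len(moving) != len(fixed):
        raise ValueError(f"unpaired landmark sets: {len(moving)} vs {len(fixed)}")
    return moving.points_mm, fixed.points_mm


def fit_rigid_landmarks(moving: LandmarkSet, fixed: LandmarkSet) -> RigidTransform:
    """Least-squares proper rigid motion taking ``moving`` onto ``fixed``.

    Closed-form Kabsch solution: centroids are subtracted, the rotation is
    recovered from the SVD of the cross-covariance with the determinant
    corrected to +1, and the translation follows from the centroids.

    Raises
    ------
    DegenerateLandmarksError
        Fewer than 3 pairs, or (near-)collinear moving points — the
        rotation about the common line would be unconstrained.
    """
    m, f = _check_pairs(moving, fixed)
    if len(m) < 3:
        raise DegenerateLandmarksError("at least 3 landmark pairs are required")

    mc = m.mean(axis=0)
    fc = f.mean(axis=0)
    m0 = m - mc
    f0 = f - fc

    # Collinearity: centered moving points must span at least a plane.
    sv = np.linalg.svd(m0, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    if sv[1] / scale < 1e-9:
        raise DegenerateLandmarksError(
            "collinear landmarks: rotation about the line is unconstrained"
        )

    h = m0.T @ f0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    # Flip the weakest singular direction if the optimum is a reflection.
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = fc - r @ mc
    return RigidTransform(r, t)


def landmark_rmsd(t: RigidTransform, moving: LandmarkSet, fixed: LandmarkSet) -> float:
    """Root-mean-square residual distance (mm) after applying ``t`` to ``moving``."""
    m, f = _check_pairs(moving, fixed)
    resid = t.apply(m) - f
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def _resample_values(
    values: np.ndarray,
    source: GridGeometry,
    t: RigidTransform,
    target: GridGeometry,
    order: int,
) -> np.ndarray:
    """Sample ``values`` (on ``source``) at target voxel centers pulled back
    through ``t`` (which maps source/moving world → target/fixed world)."""
    tinv = t.inverse()
    target_world = target.voxel_centers().reshape(-1, 3)
    source_world = tinv.apply(target_world)
    source_idx = source.world_to_index(source_world)
    out = ndimage.map_coordinates(
        np.asarray(values, dtype=np.float64),
        source_idx.T,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return out.reshape(target.shape)


def resample(
    obj: SUVVolume | ROIMask,
    t: RigidTransform,
    target: GridGeometry | None = None,
) -> SUVVolume | ROIMask:
    """Resample a volume or mask through a rigid transform onto ``target``.

    SUV volumes are interpolated trilinearly (intensities are smooth);
    masks by nearest neighbor (binary values preserved). Voxels that pull
    back outside the source field of view become 0 / background.
    """
    if not isinstance(t, RigidTransform):
        raise TypeError("resample requires a RigidTransform")
    if target is None:
        target = obj.geometry

    if isinstance(obj, ROIMask):
        vals = _resample_values(obj.values.astype(np.float64), obj.geometry, t, target, order=0)
        return ROIMask(vals > 0.5, target, obj.label)
    if isinstance(obj, SUVVolume):
        vals = _resample_values(obj.values, obj.geometry, t, target, order=1)
        # trilinear interpolation of non-negative data is non-negative;
        # clip guards against -0.0 and rounding at the boundary
        np.clip(vals, 0.0, None, out=vals)
        return SUVVolume(vals, target)
    raise TypeError(f"cannot resample {type(obj).__name__}")
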