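"""Synthetic head-and-neck FMISO-PET phantoms with known ground truth.

No patient images accompany the published analysis, so every downstream
stage is exercised on phantoms that reproduce the *statistical* structure
the method assumes:

* a 1 x 1 x 2 mm voxel grid;
* an ellipsoidal primary tumor (the contoured gross tumor volume) of
  roughly 1,200–40,000 voxels;
* an ellipsoidal high-uptake (hypoxic) subvolume strictly inside it;
* four 1-cm-radius muscle reference spheres clear of the tumor;
* a recurrence region whose per-voxel membership follows a logistic law
  in TMR with known intercept/slope — the ground truth that parameter
  recovery tests check against;
* an optional rigid misalignment of the recurrence-time images, to be
  undone by landmark registration.

The noise model is additive Gaussian on SUV, clipped at zero. No PET
physics (point-spread function, scatter, reconstruction) is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special, stats as sps

from .grids import GridGeometry, ROIMask, SUVVolume
from .registration import LandmarkSet, RigidTransform, resample
from .tmr import MuscleROISpec, TMRMap

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "DegenerateMaskError",
    "generate_phantom",
    "sample_recurrence_mask",
    "apply_misalignment",
    "make_landmarks",
]

# published-curve anchors used as the default generating law:
# slope = log of the per-unit-TMR odds ratio 5.18; intercept places the
# 50% recurrence probability at TMR 1.88
DEFAULT_SLOPE = float(np.log(5.18))
DEFAULT_INTERCEPT = -1.88 * DEFAULT_SLOPE  # = -3.0923...


class DegenerateMaskError(ValueError):
    """A sampled recurrence mask is all-zero or all-one (useless downstream)."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of a synthetic patient.

    Defaults give a ~11,300-voxel tumor (near the cohort median of ~11k),
    a hypoxic core whose TMR reaches ~1.9 against a muscle reference of
    ~1.25, and a mean in-tumor TMR just below 1 — the regime the published
    cohort occupies.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 60)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    tumor_center_mm: tuple[float, float, float] = (48.0, 48.0, 60.0)
    tumor_radii_mm: tuple[float, float, float] = (20.0, 18.0, 15.0)
    hypoxia_center_mm: tuple[float, float, float] = (54.0, 48.0, 60.0)
    hypoxia_radii_mm: tuple[float, float, float] = (8.0, 7.0, 6.0)
    background_suv: float = 1.0
    tumor_suv: float = 1.2
    hypoxic_suv: float = 2.4
    noise_sd: float = 0.1
    muscle_centers_mm: tuple[tuple[float, float, float], ...] = (
        (14.0, 14.0, 60.0),
        (14.0, 82.0, 60.0),
        (82.0, 14.0, 60.0),
        (82.0, 82.0, 60.0),
    )
    muscle_radius_mm: float = 10.0
    true_intercept: float = DEFAULT_INTERCEPT
    true_slope: float = DEFAULT_SLOPE
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("background_suv", "tumor_suv", "hypoxic_suv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.muscle_centers_mm) != 4:
            raise ValueError("exactly 4 muscle reference centers required")
        if not _ellipsoid_inside_ellipsoid(
            self.hypoxia_center_mm,
            self.hypoxia_radii_mm,
            self.tumor_center_mm,
            self.tumor_radii_mm,
        ):
            raise ValueError("hypoxic ellipsoid must lie fully inside the tumor ellipsoid")
        for c in self.muscle_centers_mm:
            if _point_in_ellipsoid(c, self.tumor_center_mm, self.tumor_radii_mm):
                raise ValueError(f"muscle center {c} lies inside the tumor")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.grid_shape, self.voxel_size_mm)

    @property
    def muscle_spec(self) -> MuscleROISpec:
        return MuscleROISpec(self.muscle_centers_mm, self.muscle_radius_mm)


@dataclass
class GroundTruth:
    """Generating parameters of a phantom, for recovery tests."""

    true_intercept: float
    true_slope: float
    true_transform: RigidTransform
    hypoxia_mask: ROIMask

    def probability(self, tmr: np.ndarray | float) -> np.ndarray | float:
        """Recurrence-membership probability at a TMR value:
        ``1 / (1 + exp(-(a* + b* t)))``."""
        return special.expit(self.true_intercept + self.true_slope * np.asarray(tmr, float))


def _point_in_ellipsoid(p, center, radii) -> bool:
    d = (np.asarray(p, float) - np.asarray(center, float)) / np.asarray(radii, float)
    return bool(np.sum(d**2) <= 1.0)


def _ellipsoid_inside_ellipsoid(c_in, r_in, c_out, r_out, n_theta=48, n_phi=24) -> bool:
    """Check containment by sampling the inner ellipsoid's surface."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    phi = np.linspace(0, np.pi, n_phi)
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    unit = np.stack(
        [np.sin(ph) * np.cos(th), np.sin(ph) * np.sin(th), np.cos(ph)], axis=-1
    )
    surface = np.asarray(c_in, float) + unit * np.asarray(r_in, float)
    d = (surface - np.asarray(c_out, float)) / np.asarray(r_out, float)
    return bool(np.all(np.sum(d**2, axis=-1) <= 1.0 + 1e-12))


def _ellipsoid_mask(geometry: GridGeometry, center_mm, radii_mm) -> np.ndarray:
    centers = geometry.voxel_centers()
    d = (centers - np.asarray(center_mm, float)) / np.asarray(radii_mm, float)
    return np.sum(d**2, axis=-1) <= 1.0


def generate_phantom(
    config: PhantomConfig,
) -> tuple[SUVVolume, ROIMask, MuscleROISpec, GroundTruth]:
    """Build the pre-treatment image set of one synthetic patient.

    The SUV grid is background everywhere, ``tumor_suv`` inside the tumor
    ellipsoid, ``hypoxic_suv`` inside the hypoxic ellipsoid, plus additive
    Gaussian noise clipped at zero. Identical configs (the seed is part of
    the config) give bit-identical output.
    """
    geom = config.geometry
    tumor = _ellipsoid_mask(geom, config.tumor_center_mm, config.tumor_radii_mm)
    hypoxia = _ellipsoid_mask(geom, config.hypoxia_center_mm, config.hypoxia_radii_mm)
    if not np.all(~hypoxia | tumor):
        raise ValueError("voxelized hypoxic region escapes the tumor mask")

    suv = np.full(geom.shape, config.background_suv, dtype=np.float64)
    suv[tumor] = config.tumor_suv
    suv[hypoxia] = config.hypoxic_suv
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        suv = suv + rng.normal(0.0, config.noise_sd, size=geom.shape)
    np.clip(suv, 0.0, None, out=suv)

    truth = GroundTruth(
        true_intercept=config.true_intercept,
        true_slope=config.true_slope,
        true_transform=RigidTransform.identity(),
        hypoxia_mask=ROIMask(hypoxia, geom, "hypoxia"),
    )
    return (
        SUVVolume(suv, geom),
        ROIMask(tumor, geom, "primary"),
        config.muscle_spec,
        truth,
    )


def sample_recurrence_mask(
    tmr: TMRMap,
    primary: ROIMask,
    truth: GroundTruth,
    mode: str = "independent",
    seed: int | None = 0,
    smoothing_mm: float = 4.0,
) -> ROIMask:
    """Draw a recurrence region inside the primary tumor.

    ``independent`` mode draws each in-tumor voxel Bernoulli with
    probability given by the logistic law in that voxel's TMR — exactly
    the independence assumption of the voxel-level analysis, so fitted
    parameters are unbiased for the ground truth.

    ``contiguous`` mode produces a spatially coherent region with the same
    marginal probabilities: Gaussian white noise is smoothed (kernel
    ``smoothing_mm``), standardized to normal marginals over the in-tumor
    voxels, and voxel i is selected when ``Phi(z_i) < p_i``. Used for
    robustness checks of the independence assumption, not for unbiased
    recovery.
    """
    if mode not in ("independent", "contiguous"):
        raise ValueError(f"unknown mode {mode!r}")
    geom = primary.geometry
    in_tumor = primary.values
    p = np.zeros(geom.shape)
    p[in_tumor] = truth.probability(tmr.values[in_tumor])

    rng = np.random.default_rng(seed)
    if mode == "independent":
        draw = rng.random(geom.shape)
        rec = in_tumor & (draw < p)
    else:
        noise = rng.standard_normal(geom.shape)
        sigma_vox = np.asarray(smoothing_mm) / np.asarray(geom.voxel_size_mm)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        z = smooth[in_tumor]
        z = (z - z.mean()) / z.std()
        sel = sps.norm.cdf(z) < p[in_tumor]
        rec = np.zeros(geom.shape, dtype=bool)
        rec[in_tumor] = sel

    n_rec = int(rec.sum())
    if n_rec == 0:
        raise DegenerateMaskError(
            "recurrence mask is empty: generating parameters saturate the "
            "logistic law at zero (a recurrent patient must recur somewhere)"
        )
    return ROIMask(rec, geom, "recurrence")


def make_landmarks(geometry: GridGeometry, n: int = 6, seed: int = 0) -> LandmarkSet:
    """Synthetic bone-landmark coordinates: well-spread, non-collinear
    points near the edge of the field of view."""
    rng = np.random.default_rng(seed)
    extent = np.asarray(geometry.shape) * np.asarray(geometry.voxel_size_mm)
    # corners of a box at 15% inset, jittered so no three are collinear
    base = np.array(
        [
            [0.15, 0.15, 0.15],
            [0.85, 0.15, 0.2],
            [0.15, 0.85, 0.25],
            [0.85, 0.85, 0.8],
            [0.5, 0.2, 0.85],
            [0.2, 0.5, 0.5],
            [0.8, 0.5, 0.35],
            [0.5, 0.8, 0.65],
        ]
    )
    if n > len(base):
        raise ValueError(f"at most {len(base)} landmarks supported")
    pts = base[:n] * extent + rng.normal(0, 1.0, size=(n, 3))
    names = [f"bone_{i}" for i in range(n)]
    return LandmarkSet(pts, names)


def apply_misalignment(
    volume: SUVVolume,
    mask: ROIMask,
    transform: RigidTransform,
    landmarks: LandmarkSet,
) -> tuple[SUVVolume, ROIMask, LandmarkSet]:
    """Move an image set rigidly, emulating a recurrence-time acquisition.

    The returned volume/mask are the input resampled through ``transform``
    on the same grid, and the returned landmarks are the input landmarks
    mapped through it — exactly what an operator would hand to
    :func:`fmisovox.registration.fit_rigid_landmarks` to register the
    moved set back (fit with moving = moved landmarks, fixed = originals
    recovers ``transform.inverse()``).
    """
    if not isinstance(transform, RigidTransform):
        raise TypeError("transform must be a proper RigidTransform")
    if transform.is_identity():
        moved_vol = volume.copy()
        moved_mask = mask.copy()
    else:
        moved_vol = resample(volume, transform, volume.geometry)
        moved_mask = resample(mask, transform, mask.geometry)
    return moved_vol, moved_mask, landmarks.transformed(transform)
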