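"""Synthetic mask-set generator with analytic ground truth.

The phantoms emulate what the metrics are designed to measure, without any
imaging data: solid-ellipsoid "lesions" placed at a prescribed fraction
along a synthetic neuraxis (0 = SMA blob, 1 = brainstem blob), in a grid
that mirrors a 1 mm isotropic T1 space.

Solid ellipsoids are used because their position covariance has a closed
form: a uniformly filled ellipsoid with semi-axes a >= b >= c has
covariance R diag(a^2, b^2, c^2) / 5 R^T, which makes every shape metric
(MCI, CAI, CPI, CSI) analytically checkable.  Likewise the programmed
axial fraction of each lesion centre is the ground truth for its NCI.

Timepoint series are produced by giving each lesion a
``present_from_timepoint``; lesions appearing later can bridge earlier
ones, exercising the longitudinal merging rule.

What these phantoms do *not* emulate: realistic lesion shapes (real
lesions are not ellipsoids), partial-volume probabilistic masks, scanner
noise, or registration error.  They validate the geometry and the metric
algebra, not segmentation robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError
from .mask_io import MaskSet, VoxelMask, validate_mask_set

#: Radius (mm) of the spherical SMA / brainstem anatomy blobs.
ANATOMY_BLOB_RADIUS_MM = 4.0


@dataclass(frozen=True)
class LesionSpec:
    """One synthetic ellipsoidal lesion.

    Attributes
    ----------
    axial_fraction : float
        Position of the lesion centre along the synthetic neuraxis:
        0 at the SMA blob centre, 1 at the brainstem blob centre.
    offset_mm : tuple of 3 floats
        Additional displacement of the centre (mm), typically orthogonal
        to the axis.
    semi_axes_mm : tuple of 3 floats
        Ellipsoid semi-axes a >= b >= c > 0 (mm).
    rotation : 3x3 array
        Orthonormal rotation applied to the ellipsoid axes.
    present_from_timepoint : int
        First timepoint (0-based) at which the lesion exists.
    """

    axial_fraction: float
    offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    present_from_timepoint: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes_mm
        if not (a >= b >= c > 0):
            raise ValueError(
                f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes_mm}"
            )
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "rotation", R)

    def analytic_covariance(self) -> np.ndarray:
        """Position covariance of the solid ellipsoid: R diag(a^2,b^2,c^2)/5 R^T."""
        a, b, c = self.semi_axes_mm
        return self.rotation @ np.diag([a**2 / 5, b**2 / 5, c**2 / 5]) @ self.rotation.T


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sma_centre: tuple[float, float, float] = (64.0, 64.0, 110.0)
    bs_centre: tuple[float, float, float] = (64.0, 64.0, 20.0)
    lesions: tuple[LesionSpec, ...] = ()
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    @property
    def n_timepoints(self) -> int:
        if not self.lesions:
            return 1
        return max(l.present_from_timepoint for l in self.lesions) + 1

    def lesion_centre_mm(self, lesion: LesionSpec) -> np.ndarray:
        sma = np.asarray(self.sma_centre, dtype=float)
        bs = np.asarray(self.bs_centre, dtype=float)
        return sma + lesion.axial_fraction * (bs - sma) + np.asarray(lesion.offset_mm)


def _voxel_centres_in_box(
    spec: PhantomSpec, lo_mm: np.ndarray, hi_mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices and their centre positions (mm) inside a world-aligned box."""
    vs = np.asarray(spec.voxel_size, dtype=float)
    lo_idx = np.maximum(np.floor(lo_mm / vs).astype(int), 0)
    hi_idx = np.minimum(np.ceil(hi_mm / vs).astype(int) + 1, spec.grid_shape)
    if np.any(lo_idx >= hi_idx):
        return np.empty((0, 3), dtype=int), np.empty((0, 3))
    grids = np.meshgrid(
        *[np.arange(lo_idx[d], hi_idx[d]) for d in range(3)], indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1)
    return idx, idx * vs


def rasterize_ellipsoid(lesion: LesionSpec, spec: PhantomSpec) -> VoxelMask:
    """Binary mask of the voxels whose centre lies inside the lesion ellipsoid.

    Raises :class:`GeometryError` when the ellipsoid's bounding sphere
    does not fit inside the grid.
    """
    centre = spec.lesion_centre_mm(lesion)
    a = lesion.semi_axes_mm[0]
    extent_mm = np.asarray(spec.grid_shape) * np.asarray(spec.voxel_size)
    if np.any(centre - a < 0) or np.any(centre + a > extent_mm):
        raise GeometryError(
            f"ellipsoid at {centre} with semi-axis {a} mm exceeds grid extent {extent_mm}"
        )
    idx, pos = _voxel_centres_in_box(spec, centre - a, centre + a)
    local = (pos - centre) @ lesion.rotation  # coords in ellipsoid frame
    scaled = local / np.asarray(lesion.semi_axes_mm)
    inside = (scaled**2).sum(axis=1) <= 1.0
    data = np.zeros(spec.grid_shape, dtype=np.uint8)
    data[tuple(idx[inside].T)] = 1
    return VoxelMask(data=data, affine=spec.affine, space_tag="phantom")


def _rasterize_sphere(centre_mm: Sequence[float], radius: float, spec: PhantomSpec) -> np.ndarray:
    centre = np.asarray(centre_mm, dtype=float)
    idx, pos = _voxel_centres_in_box(spec, centre - radius, centre + radius)
    inside = ((pos - centre) ** 2).sum(axis=1) <= radius**2
    data = np.zeros(spec.grid_shape, dtype=np.uint8)
    data[tuple(idx[inside].T)] = 1
    return data


def generate_phantom(spec: PhantomSpec) -> tuple[list[MaskSet], pd.DataFrame]:
    """Render a phantom subject: one validated MaskSet per timepoint plus
    a ground-truth table.

    The SMA and brainstem are spheres of radius ``ANATOMY_BLOB_RADIUS_MM``
    at their programmed centres; at timepoint t the lesion mask is the
    union of all lesions with ``present_from_timepoint <= t``.  The
    ground-truth table records, per lesion, the programmed centre,
    axial fraction, analytic covariance eigenvalues, and onset timepoint.
    Overlaps between lesions are allowed (merging is itself a behaviour
    under test).
    """
    sma_data = _rasterize_sphere(spec.sma_centre, ANATOMY_BLOB_RADIUS_MM, spec)
    bs_data = _rasterize_sphere(spec.bs_centre, ANATOMY_BLOB_RADIUS_MM, spec)
    if sma_data.sum() == 0 or bs_data.sum() == 0:
        raise GeometryError("anatomy blob falls outside the grid")
    sma = VoxelMask(data=sma_data, affine=spec.affine, space_tag="phantom")
    bs = VoxelMask(data=bs_data, affine=spec.affine, space_tag="phantom")

    lesion_masks = [rasterize_ellipsoid(l, spec) for l in spec.lesions]
    mask_sets: list[MaskSet] = []
    for t in range(spec.n_timepoints):
        data = np.zeros(spec.grid_shape, dtype=np.uint8)
        for lesion, mask in zip(spec.lesions, lesion_masks):
            if lesion.present_from_timepoint <= t:
                data |= mask.data
        lesion_mask = VoxelMask(data=data, affine=spec.affine, space_tag="phantom")
        mask_sets.append(validate_mask_set(lesion_mask, sma, bs))

    rows = []
    for i, lesion in enumerate(spec.lesions):
        eig = np.sort(np.linalg.eigvalsh(lesion.analytic_covariance()))[::-1]
        centre = spec.lesion_centre_mm(lesion)
        rows.append(
            {
                "lesion_index": i,
                "centre_x_mm": centre[0],
                "centre_y_mm": centre[1],
                "centre_z_mm": centre[2],
                "axial_fraction": lesion.axial_fraction,
                "u1_mm2": eig[0],
                "u2_mm2": eig[1],
                "u3_mm2": eig[2],
                "n_voxels": int(lesion_masks[i].n_foreground),
                "present_from_timepoint": lesion.present_from_timepoint,
                "seed": spec.seed,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "lesion_index", "centre_x_mm", "centre_y_mm", "centre_z_mm",
            "axial_fraction", "u1_mm2", "u2_mm2", "u3_mm2", "n_voxels",
            "present_from_timepoint", "seed",
        ],
    )
    return mask_sets, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_cohort(
    n_subjects: int,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    n_lesions_range: tuple[int, int] = (1, 5),
    axial_fraction_range: tuple[float, float] = (0.05, 1.1),
    semi_axis_range_mm: tuple[float, float] = (2.0, 10.0),
    offset_radius_mm: float = 12.0,
) -> list[tuple[PhantomSpec, list[MaskSet], pd.DataFrame]]:
    """Reproducible cohort of single-timepoint phantom subjects.

    Each subject gets 1-5 lesions with random sizes, orientations and
    positions spanning the axial range, so the cohort exercises the full
    metric space (caudality from rostral to caudal, anisotropy from
    needle to sphere).  The same ``seed`` always yields byte-identical
    masks.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    extent = np.asarray(grid_shape, dtype=float)  # 1 mm voxels
    sma_centre = (extent[0] / 2, extent[1] / 2, extent[2] - 14.0)
    bs_centre = (extent[0] / 2, extent[1] / 2, 20.0)
    cohort = []
    for _ in range(n_subjects):
        n_lesions = int(rng.integers(n_lesions_range[0], n_lesions_range[1] + 1))
        lesions = []
        for _ in range(n_lesions):
            axes = np.sort(rng.uniform(*semi_axis_range_mm, size=3))[::-1]
            offset = rng.uniform(-offset_radius_mm, offset_radius_mm, size=2)
            lesions.append(
                LesionSpec(
                    axial_fraction=float(rng.uniform(*axial_fraction_range)),
                    offset_mm=(float(offset[0]), float(offset[1]), 0.0),
                    semi_axes_mm=tuple(float(x) for x in axes),
                    rotation=random_rotation(rng),
                )
            )
        spec = PhantomSpec(
            grid_shape=grid_shape,
            voxel_size=(1.0, 1.0, 1.0),
            sma_centre=sma_centre,
            bs_centre=bs_centre,
            lesions=tuple(lesions),
            seed=seed,
        )
        mask_sets, truth = generate_phantom(spec)
        cohort.append((spec, mask_sets, truth))
    return cohort
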