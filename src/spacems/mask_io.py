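"""Volumetric mask I/O and the shared-space geometric contract.

All downstream metrics operate on the world-millimetre positions of
foreground voxels.  This module owns the two conventions that make those
positions well defined:

* a voxel index addresses the voxel *centre*, and its world position is the
  image of the integer index ``(i, j, k, 1)`` under the NIfTI affine
  (0-based indices, no half-voxel shift);
* when a file carries both a valid sform and qform, the sform wins.

Masks are binary; probabilistic inputs are binarized with a strict
``value > threshold`` rule (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    AnatomyError,
    DimensionalityError,
    GeometryError,
    MaskIOError,
    SpaceMismatchError,
)

#: Maximum elementwise affine disagreement (mm) for two masks to count as
#: sharing one space.
AFFINE_TOLERANCE_MM = 1e-3


@dataclass(frozen=True)
class VoxelMask:
    """A binary 3-D mask together with its voxel-to-world affine.

    Attributes
    ----------
    data : numpy.ndarray
        3-D uint8 array of {0, 1}.
    affine : numpy.ndarray
        4x4 matrix mapping 0-based voxel indices (voxel centres) to world
        coordinates in millimetres.
    space_tag : str
        Free-text label of the space the mask lives in (e.g. ``"native-3DT1"``,
        ``"MNI"``, ``"phantom"``).
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "unspecified"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"mask data must be 3-D, got {data.ndim}-D shape {data.shape}"
            )
        values = np.unique(data)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"mask data must be binary, found values {values[:10]}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GeometryError("affine upper-left 3x3 block is singular")
        object.__setattr__(self, "data", data.astype(np.uint8, copy=False))
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        """Number of foreground (lesional) voxels."""
        return int(self.data.sum())


@dataclass(frozen=True)
class MaskSet:
    """Lesion + SMA + brainstem masks validated to share one space."""

    lesion: VoxelMask
    sma: VoxelMask
    brainstem: VoxelMask
    space_tag: str = field(default="unspecified")


def load_mask(
    path: str | Path,
    binarize_threshold: float = 0.5,
    space_tag: str = "unspecified",
) -> VoxelMask:
    """Load a NIfTI volume as a binary mask.

    Voxels with value strictly greater than ``binarize_threshold`` become
    foreground.  A 4-D volume with a singleton fourth axis is squeezed; any
    other non-3-D shape raises :class:`DimensionalityError`.

    Parameters
    ----------
    path :
        NIfTI-1/2 file (``.nii`` or ``.nii.gz``).
    binarize_threshold :
        Strict lower bound for foreground membership.
    space_tag :
        Label recorded on the returned mask; the file itself carries no
        such notion.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise MaskIOError(f"cannot read NIfTI file {path}: {exc}") from exc

    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )

    affine = _select_affine(img, path)
    binary = (data > binarize_threshold).astype(np.uint8)
    return VoxelMask(data=binary, affine=affine, space_tag=space_tag)


def _select_affine(img: "nib.Nifti1Image", path: Path) -> np.ndarray:
    """sform if valid, else qform, else error. Non-NIfTI images fall back
    to whatever affine nibabel derived."""
    header = img.header
    get_sform = getattr(header, "get_sform", None)
    if get_sform is None:
        if img.affine is None:
            raise GeometryError(f"{path}: image carries no affine")
        return np.asarray(img.affine, dtype=float)
    sform, scode = header.get_sform(coded=True)
    if scode != 0 and sform is not None:
        return np.asarray(sform, dtype=float)
    qform, qcode = header.get_qform(coded=True)
    if qcode != 0 and qform is not None:
        return np.asarray(qform, dtype=float)
    raise GeometryError(f"{path}: neither sform nor qform is set")


def save_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as NIfTI-1 so that ``load_mask`` round-trips it exactly
    (data bit-exact, affine within 1e-6)."""
    path = Path(path)
    if not path.parent.exists():
        raise MaskIOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_sform(mask.affine, code=1)
    img.header.set_qform(mask.affine, code=1)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise MaskIOError(f"cannot write {path}: {exc}") from exc


def validate_mask_set(
    lesion: VoxelMask, sma: VoxelMask, brainstem: VoxelMask
) -> MaskSet:
    """Check that the three masks share one space and that the anatomical
    reference masks are nonempty.

    Affines must agree elementwise within ``AFFINE_TOLERANCE_MM`` and grid
    shapes must match; otherwise :class:`SpaceMismatchError` names the
    offending pair.  Empty SMA or brainstem raises :class:`AnatomyError`
    (an empty lesion mask is legitimate — a subject may have no lesions).
    """
    named = {"lesion": lesion, "sma": sma, "brainstem": brainstem}
    pairs = [("lesion", "sma"), ("lesion", "brainstem"), ("sma", "brainstem")]
    for a, b in pairs:
        ma, mb = named[a], named[b]
        if ma.shape != mb.shape:
            raise SpaceMismatchError(
                f"grid shape mismatch between {a} {ma.shape} and {b} {mb.shape}"
            )
        diff = np.abs(ma.affine - mb.affine).max()
        if diff > AFFINE_TOLERANCE_MM:
            raise SpaceMismatchError(
                f"affine mismatch between {a} and {b}: max |delta| = {diff:.6g} mm "
                f"exceeds {AFFINE_TOLERANCE_MM} mm"
            )
    for name in ("sma", "brainstem"):
        if named[name].n_foreground == 0:
            raise AnatomyError(f"{name} mask is empty")
    tags = {m.space_tag for m in named.values() if m.space_tag != "unspecified"}
    tag = tags.pop() if len(tags) == 1 else lesion.space_tag
    return MaskSet(lesion=lesion, sma=sma, brainstem=brainstem, space_tag=tag)


def voxel_positions_mm(mask: VoxelMask) -> np.ndarray:
    """World-coordinate positions (mm) of all foreground voxels.

    Returns an ``(N, 3)`` array, one row per foreground voxel, in raster
    order: the first index varies slowest, the last fastest (C order of
    ``numpy.argwhere``).  Empty masks yield an empty ``(0, 3)`` array.
    """
    idx = np.argwhere(mask.data > 0)
    return apply_affine(mask.affine, idx)


def apply_affine(affine: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Map ``(N, 3)`` voxel indices to ``(N, 3)`` world positions."""
    indices = np.atleast_2d(np.asarray(indices, dtype=float))
    if indices.size == 0:
        return np.empty((0, 3))
    return indices @ affine[:3, :3].T + affine[:3, 3]
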