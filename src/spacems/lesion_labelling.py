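"""Individual-lesion definition and longitudinal identity tracking.

A lesion is a connected component of the binary lesion mask.  Connectivity
is parameterised by the number of orthogonal hops allowed between
neighbours: 1 hop = 6-neighbourhood (faces), 2 = 18 (faces + edges),
3 = 26 (faces + edges + corners).  The default is the full
26-neighbourhood, i.e. two foreground voxels are neighbours whenever every
index differs by at most one.

Across timepoints, lesion identity is defined on the voxelwise union of
all timepoint masks (the all-timepoints merged image): components are
labelled once on the union and each timepoint mask inherits the union
label at every foreground voxel.  Two lesions that are separate early on
but later merge therefore carry a single shared ID at *all* timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError, LesionLookupError, SpaceMismatchError
from .mask_io import AFFINE_TOLERANCE_MM, VoxelMask, apply_affine


@dataclass(frozen=True)
class LesionLabelMap:
    """Integer-labelled lesion map: 0 = background, 1..n_lesions = lesions."""

    labels: np.ndarray
    affine: np.ndarray
    n_lesions: int

    def lesion_ids(self) -> np.ndarray:
        """Sorted array of lesion IDs actually present in the map."""
        present = np.unique(self.labels)
        return present[present > 0]

    def lesion_sizes(self) -> dict[int, int]:
        """Voxel count per present lesion ID."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass(frozen=True)
class LongitudinalLabels:
    """Merged-image labels plus per-timepoint maps sharing the merged ID space.

    ``merged`` labels the union of all timepoint masks; each entry of
    ``per_timepoint`` restricts those labels to one timepoint's foreground.
    A lesion ID may be absent from early timepoints (lesion not yet
    present).
    """

    merged: LesionLabelMap
    per_timepoint: tuple[LesionLabelMap, ...]


def _structure(connectivity_hops: int) -> np.ndarray:
    if connectivity_hops not in (1, 2, 3):
        raise ValueError(f"connectivity_hops must be 1, 2 or 3, got {connectivity_hops}")
    return ndimage.generate_binary_structure(3, connectivity_hops)


def label_lesions(mask: VoxelMask, connectivity_hops: int = 3) -> LesionLabelMap:
    """Label connected components of a binary mask.

    Two foreground voxels are neighbours iff their index difference has
    Chebyshev norm 1 and Manhattan norm <= ``connectivity_hops``; the
    default 3 gives the 26-neighbourhood.  IDs are assigned 1..L in
    ascending raster order of each component's first voxel, so identical
    input always yields byte-identical output.
    """
    structure = _structure(connectivity_hops)
    raw, n = ndimage.label(mask.data, structure=structure)
    labels = _canonical_relabel(raw, n)
    return LesionLabelMap(labels=labels, affine=mask.affine, n_lesions=n)


def _canonical_relabel(raw: np.ndarray, n: int) -> np.ndarray:
    """Renumber labels by ascending raster position of each component's
    first voxel."""
    if n == 0:
        return raw.astype(np.int32)
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier raster positions overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")  # old label-1 -> rank
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1, dtype=np.int32)
    return remap[raw]


def merge_timepoints(
    masks: Sequence[VoxelMask], connectivity_hops: int = 3
) -> LongitudinalLabels:
    """Build longitudinally consistent lesion labels from timepoint masks.

    Labels the voxelwise union of all masks, then projects the union
    labels onto each timepoint's foreground.  All masks must share a grid
    and affine (within the mask-set tolerance).
    """
    if len(masks) == 0:
        raise EmptyInputError("merge_timepoints requires at least one mask")
    ref = masks[0]
    for t, m in enumerate(masks[1:], start=1):
        if m.shape != ref.shape:
            raise SpaceMismatchError(
                f"timepoint {t} grid shape {m.shape} differs from timepoint 0 {ref.shape}"
            )
        if np.abs(m.affine - ref.affine).max() > AFFINE_TOLERANCE_MM:
            raise SpaceMismatchError(
                f"timepoint {t} affine differs from timepoint 0 beyond "
                f"{AFFINE_TOLERANCE_MM} mm"
            )
    union = np.zeros(ref.shape, dtype=np.uint8)
    for m in masks:
        union |= m.data
    merged = label_lesions(
        VoxelMask(data=union, affine=ref.affine, space_tag=ref.space_tag),
        connectivity_hops=connectivity_hops,
    )
    per_tp = tuple(
        LesionLabelMap(
            labels=np.where(m.data > 0, merged.labels, 0).astype(np.int32),
            affine=ref.affine,
            n_lesions=merged.n_lesions,
        )
        for m in masks
    )
    return LongitudinalLabels(merged=merged, per_timepoint=per_tp)


def lesion_voxel_positions(labels: LesionLabelMap, lesion_id: int) -> np.ndarray:
    """World positions (mm) of one lesion's voxels, in raster order."""
    if lesion_id < 1 or lesion_id > labels.n_lesions:
        raise LesionLookupError(
            f"lesion_id {lesion_id} outside valid range 1..{labels.n_lesions}"
        )
    idx = np.argwhere(labels.labels == lesion_id)
    if idx.size == 0:
        raise LesionLookupError(
            f"lesion_id {lesion_id} not present in this label map"
        )
    return apply_affine(labels.affine, idx)
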