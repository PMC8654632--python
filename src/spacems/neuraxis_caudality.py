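"""Neuraxis construction and the neuraxis caudality index (NCI).

The neuraxis approximates the cranio-caudal axis of the central nervous
system as the line joining the centre of mass of the unified bilateral
supplementary motor areas (SMA) to the centre of mass of the brainstem.
For a voxel set with centre of mass r_mask, its caudality index is the
normalised scalar projection onto that axis:

    NCI = (r_mask - r_SMA) . (r_BS - r_SMA) / ||r_BS - r_SMA||^2

so NCI = 0 at the SMA level and NCI = 1 at the brainstem level.  The
division by the squared SMA-brainstem distance normalises by head size.
NCI is unbounded in theory but anatomically expected to fall roughly in
[0, 1.5]; values outside that band trigger a logged warning, not an
error.

The "maximum lesion NCI" is the NCI of the lowermost individual lesion,
operationalised as the lesion whose centre of mass projects farthest
along the axis (largest per-lesion NCI) — a definition invariant to head
orientation in the scanner, unlike a raw world-z minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance_core import centre_of_mass
from .errors import AnatomyError, DegenerateNeuraxisError, EmptyInputError
from .lesion_labelling import LesionLabelMap, lesion_voxel_positions
from .mask_io import VoxelMask, voxel_positions_mm

logger = logging.getLogger(__name__)

#: Anatomically plausible NCI band; values outside it are warned about.
PRACTICAL_NCI_RANGE = (0.0, 1.5)

#: SMA-brainstem distances below this (mm) define a degenerate neuraxis.
MIN_NEURAXIS_LENGTH_MM = 1e-6


@dataclass(frozen=True)
class Neuraxis:
    """The SMA-to-brainstem axis: endpoints, unit direction, and length (mm)."""

    r_sma: np.ndarray
    r_bs: np.ndarray
    direction: np.ndarray  # unit vector from SMA CoM towards brainstem CoM
    length: float


def build_neuraxis(sma: VoxelMask, brainstem: VoxelMask) -> Neuraxis:
    """Construct the neuraxis from SMA and brainstem masks.

    Centres of mass use uniform voxel weights in world millimetres.
    Raises :class:`AnatomyError` on an empty mask and
    :class:`DegenerateNeuraxisError` when the two centres coincide.
    """
    if sma.n_foreground == 0:
        raise AnatomyError("SMA mask is empty; cannot build neuraxis")
    if brainstem.n_foreground == 0:
        raise AnatomyError("brainstem mask is empty; cannot build neuraxis")
    r_sma = centre_of_mass(voxel_positions_mm(sma))
    r_bs = centre_of_mass(voxel_positions_mm(brainstem))
    return neuraxis_from_points(r_sma, r_bs)


def neuraxis_from_points(r_sma: np.ndarray, r_bs: np.ndarray) -> Neuraxis:
    """Neuraxis from two already-computed centres of mass (mm)."""
    r_sma = np.asarray(r_sma, dtype=float)
    r_bs = np.asarray(r_bs, dtype=float)
    delta = r_bs - r_sma
    length = float(np.linalg.norm(delta))
    if length < MIN_NEURAXIS_LENGTH_MM:
        raise DegenerateNeuraxisError(
            f"SMA and brainstem centres of mass coincide (distance {length:.3g} mm)"
        )
    return Neuraxis(r_sma=r_sma, r_bs=r_bs, direction=delta / length, length=length)


def nci(r_mask: np.ndarray, axis: Neuraxis) -> float:
    """Neuraxis caudality index of a single point (a centre of mass, mm)."""
    r_mask = np.asarray(r_mask, dtype=float)
    value = float(
        (r_mask - axis.r_sma) @ (axis.r_bs - axis.r_sma) / axis.length**2
    )
    if not PRACTICAL_NCI_RANGE[0] <= value <= PRACTICAL_NCI_RANGE[1]:
        logger.warning(
            "NCI %.4f outside the anatomically expected range %s",
            value,
            PRACTICAL_NCI_RANGE,
        )
    return value


def whole_mask_nci(lesion: VoxelMask, axis: Neuraxis) -> float:
    """NCI of the whole-brain lesion mask's centre of mass."""
    positions = voxel_positions_mm(lesion)
    if positions.shape[0] == 0:
        raise EmptyInputError("lesion mask is empty; whole-mask NCI undefined")
    return nci(centre_of_mass(positions), axis)


def lesion_nci_table(
    labels: LesionLabelMap, axis: Neuraxis, min_voxels: int = 1
) -> pd.DataFrame:
    """Per-lesion NCI table with columns lesion_id, nci, n_voxels.

    Rows are sorted by lesion_id.  Lesions smaller than ``min_voxels``
    are dropped (default keeps everything).  Only lesions present in the
    map appear — with longitudinal labels an ID can be absent at a given
    timepoint.
    """
    rows = []
    for lesion_id in labels.lesion_ids():
        positions = lesion_voxel_positions(labels, int(lesion_id))
        if positions.shape[0] < min_voxels:
            continue
        rows.append(
            {
                "lesion_id": int(lesion_id),
                "nci": nci(centre_of_mass(positions), axis),
                "n_voxels": positions.shape[0],
            }
        )
    return pd.DataFrame(rows, columns=["lesion_id", "nci", "n_voxels"])


def max_lesion_nci(
    labels: LesionLabelMap, axis: Neuraxis, min_voxels: int = 1
) -> tuple[float, int]:
    """NCI of the lowermost lesion and that lesion's ID.

    Ties on NCI are broken towards the smallest lesion ID so the output
    is deterministic.
    """
    table = lesion_nci_table(labels, axis, min_voxels=min_voxels)
    if table.empty:
        raise EmptyInputError("label map contains no lesions")
    # idxmax on the nci column returns the first (lowest lesion_id) maximum
    best = table.loc[table["nci"].idxmax()]
    return float(best["nci"]), int(best["lesion_id"])
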