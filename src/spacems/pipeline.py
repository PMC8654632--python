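"""End-to-end per-subject computation and tidy metric output.

``compute_subject`` runs the full chain — load and validate masks, build
longitudinally consistent lesion labels on the all-timepoints merged
image, construct the neuraxis, and emit one whole-brain record per
timepoint (plus per-lesion records on request).  ``write_metrics``
serialises records to CSV with a fixed column order and a sidecar JSON
carrying version, options, and input digests, so runs are auditable and
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .covariance_core import covariance_tensor, shape_metrics
from .errors import SpaceMSError
from .lesion_labelling import (
    LesionLabelMap,
    LongitudinalLabels,
    lesion_voxel_positions,
    merge_timepoints,
)
from .mask_io import MaskSet, VoxelMask, load_mask, validate_mask_set, voxel_positions_mm
from .neuraxis_caudality import (
    Neuraxis,
    build_neuraxis,
    lesion_nci_table,
    max_lesion_nci,
    nci,
    whole_mask_nci,
)

#: Column order of the metrics CSV; fixed so outputs are diffable.
CSV_COLUMNS = [
    "subject_id", "timepoint", "scope", "lesion_id", "n_voxels",
    "nci", "max_lesion_nci", "mci_mm2", "cai", "cpi", "csi",
    "degenerate_flag", "space_tag",
]


@dataclass(frozen=True)
class SpaceMSRecord:
    """One row of metrics: a subject-timepoint (whole brain) or one lesion.

    Whole-brain rows carry ``max_lesion_nci`` and no ``lesion_id``;
    lesion rows carry ``lesion_id`` and no ``max_lesion_nci``.  Undefined
    metrics (degenerate or empty masks) are NaN.
    """

    subject_id: str
    timepoint: int
    scope: str  # "whole_brain" | "lesion"
    lesion_id: int | None
    n_voxels: int
    nci: float
    max_lesion_nci: float | None
    mci_mm2: float
    cai: float
    cpi: float
    csi: float
    degenerate_flag: bool
    space_tag: str


def _metrics_for_positions(positions) -> tuple[float, float, float, float, bool]:
    """(mci, cai, cpi, csi, degenerate) for a nonempty position set."""
    summary = covariance_tensor(positions)
    m = shape_metrics(summary)
    return m.mci, m.cai, m.cpi, m.csi, m.degenerate_flag


def compute_subject(
    lesion_paths: Sequence[str | Path],
    sma_path: str | Path,
    brainstem_path: str | Path,
    subject_id: str = "subject",
    per_lesion: bool = False,
    connectivity_hops: int = 3,
    min_lesion_voxels: int = 1,
    space_tag: str = "native",
    binarize_threshold: float = 0.5,
) -> list[SpaceMSRecord]:
    """Compute metrics for one subject across all timepoints from files.

    Parameters mirror the CLI.  ``lesion_paths`` is ordered by timepoint;
    the all-timepoints merged labels are always built so lesion IDs are
    stable across reruns regardless of which metrics are requested.
    """
    lesion_masks = [
        load_mask(p, binarize_threshold=binarize_threshold, space_tag=space_tag)
        for p in lesion_paths
    ]
    sma = load_mask(sma_path, binarize_threshold=binarize_threshold, space_tag=space_tag)
    brainstem = load_mask(
        brainstem_path, binarize_threshold=binarize_threshold, space_tag=space_tag
    )
    mask_sets = [validate_mask_set(m, sma, brainstem) for m in lesion_masks]
    return compute_subject_from_masks(
        mask_sets,
        subject_id=subject_id,
        per_lesion=per_lesion,
        connectivity_hops=connectivity_hops,
        min_lesion_voxels=min_lesion_voxels,
    )


def compute_subject_from_masks(
    mask_sets: Sequence[MaskSet],
    subject_id: str = "subject",
    per_lesion: bool = False,
    connectivity_hops: int = 3,
    min_lesion_voxels: int = 1,
) -> list[SpaceMSRecord]:
    """Same as :func:`compute_subject` but from already-validated mask sets
    (one per timepoint, shared SMA/brainstem)."""
    if len(mask_sets) == 0:
        raise SpaceMSError(f"subject {subject_id}: at least one timepoint is required")
    try:
        axis = build_neuraxis(mask_sets[0].sma, mask_sets[0].brainstem)
        longitudinal = merge_timepoints(
            [ms.lesion for ms in mask_sets], connectivity_hops=connectivity_hops
        )
    except SpaceMSError as exc:
        raise type(exc)(f"subject {subject_id}: {exc}") from exc

    records: list[SpaceMSRecord] = []
    for t, ms in enumerate(mask_sets):
        try:
            records.extend(
                _timepoint_records(
                    ms, longitudinal.per_timepoint[t], axis, subject_id, t,
                    per_lesion, min_lesion_voxels,
                )
            )
        except SpaceMSError as exc:
            raise type(exc)(f"subject {subject_id}, timepoint {t}: {exc}") from exc
    return records


def _timepoint_records(
    ms: MaskSet,
    labels: LesionLabelMap,
    axis: Neuraxis,
    subject_id: str,
    timepoint: int,
    per_lesion: bool,
    min_lesion_voxels: int,
) -> list[SpaceMSRecord]:
    records = []
    n_vox = ms.lesion.n_foreground
    if n_vox == 0:
        # no lesions at this timepoint: keep the row, flag everything undefined
        records.append(
            SpaceMSRecord(
                subject_id=subject_id, timepoint=timepoint, scope="whole_brain",
                lesion_id=None, n_voxels=0, nci=math.nan, max_lesion_nci=math.nan,
                mci_mm2=math.nan, cai=math.nan, cpi=math.nan, csi=math.nan,
                degenerate_flag=True, space_tag=ms.space_tag,
            )
        )
        return records

    positions = voxel_positions_mm(ms.lesion)
    mci_v, cai_v, cpi_v, csi_v, degenerate = _metrics_for_positions(positions)
    wb_nci = whole_mask_nci(ms.lesion, axis)
    ml_nci, _ = max_lesion_nci(labels, axis, min_voxels=min_lesion_voxels)
    records.append(
        SpaceMSRecord(
            subject_id=subject_id, timepoint=timepoint, scope="whole_brain",
            lesion_id=None, n_voxels=n_vox, nci=wb_nci, max_lesion_nci=ml_nci,
            mci_mm2=mci_v, cai=cai_v, cpi=cpi_v, csi=csi_v,
            degenerate_flag=degenerate, space_tag=ms.space_tag,
        )
    )
    if per_lesion:
        table = lesion_nci_table(labels, axis, min_voxels=min_lesion_voxels)
        for row in table.itertuples(index=False):
            lpos = lesion_voxel_positions(labels, int(row.lesion_id))
            lm, lc, lp, ls, ldeg = _metrics_for_positions(lpos)
            records.append(
                SpaceMSRecord(
                    subject_id=subject_id, timepoint=timepoint, scope="lesion",
                    lesion_id=int(row.lesion_id), n_voxels=int(row.n_voxels),
                    nci=float(row.nci), max_lesion_nci=None,
                    mci_mm2=lm, cai=lc, cpi=lp, csi=ls,
                    degenerate_flag=ldeg, space_tag=ms.space_tag,
                )
            )
    return records


def records_to_frame(records: Sequence[SpaceMSRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame in the fixed CSV column order."""
    frame = pd.DataFrame([asdict(r) for r in records], columns=CSV_COLUMNS)
    return frame


def write_metrics(
    records: Sequence[SpaceMSRecord],
    path: str | Path,
    options: dict | None = None,
    input_paths: Sequence[str | Path] = (),
) -> None:
    """Write records as CSV plus a ``<name>.meta.json`` sidecar.

    Undefined metrics serialise as empty cells.  The sidecar records the
    package version, the options used, and a SHA-256 digest per input
    file, so any output can be traced to its exact inputs.
    """
    path = Path(path)
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.12g", na_rep="")
    sidecar = {
        "software": "spacems",
        "version": __version__,
        "options": options or {},
        "inputs": {
            str(p): _sha256(p) for p in input_paths
        },
        "n_records": len(records),
    }
    sidecar_path = path.with_suffix(".meta.json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
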