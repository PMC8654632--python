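"""Spatial covariance tensor of lesional-voxel positions and its shape metrics.

Given the world-millimetre positions r of the foreground voxels, the
centred covariance tensor

    C = (1/N) * sum_i (r_i - rbar)(r_i - rbar)^T        [mm^2]

summarises how the voxels spread in space.  Writing u1 >= u2 >= u3 >= 0
for its eigenvalues, four rotation-invariant scalars describe the
magnitude and shape of that spread:

* MCI  = (u1 + u2 + u3) / 3                 — mean covariance index,
  total spatial variability in mm^2, range [0, inf);
* CAI  = sqrt(3/2) * ||u - ubar|| / ||u||   — anisotropy index, the
  fractional-anisotropy formula applied to the covariance eigenvalues,
  1 when a single direction dominates (prolate / needle-like spread);
* CPI  = 2 (u2 - u3) / (u1 + u2 + u3)       — planarity index, 1 when the
  spread is confined to a plane (oblate / pancake-like);
* CSI  = 3 u3 / (u1 + u2 + u3)              — sphericity index, 1 when
  the spread is equal in all three directions.

CAI, CPI and CSI all lie in [0, 1] and are undefined (NaN, with a
degeneracy flag) when the trace is zero — a single voxel has no spread
and the formulas are 0/0.

Voxels are weighted uniformly; population normalisation (1/N) is the
default, with 1/(N-1) and the uncentred second moment E[r r^T] available
behind explicit options for audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EmptyInputError

#: Relative tolerance below which a slightly negative eigenvalue is treated
#: as floating-point noise and clamped to zero.
EIGENVALUE_CLAMP_REL = 1e-9


@dataclass(frozen=True)
class CovarianceSummary:
    """Centre of mass, covariance tensor, and ordered eigenvalues (mm^2)."""

    com: np.ndarray
    tensor: np.ndarray
    eigenvalues: tuple[float, float, float]  # u1 >= u2 >= u3 >= 0
    n_voxels: int

    @property
    def mean_eigenvalue(self) -> float:
        """ubar = (u1 + u2 + u3) / 3, identical to MCI."""
        return sum(self.eigenvalues) / 3.0


@dataclass(frozen=True)
class ShapeMetrics:
    """MCI/CAI/CPI/CSI bundle; NaN shape indices when degenerate."""

    mci: float
    cai: float
    cpi: float
    csi: float
    degenerate_flag: bool


def centre_of_mass(positions: np.ndarray) -> np.ndarray:
    """Uniform-weight mean position (mm) of a set of 3-D points."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        raise EmptyInputError("centre_of_mass needs at least one position")
    return positions.mean(axis=0)


def covariance_tensor(
    positions: np.ndarray,
    centred: bool = True,
    ddof: int = 0,
) -> CovarianceSummary:
    """Covariance tensor of 3-D positions with eigen-decomposition.

    Parameters
    ----------
    positions :
        ``(N, 3)`` array of world positions in mm, N >= 1.
    centred :
        Subtract the centre of mass before forming the second moment
        (default).  ``False`` gives the raw second moment E[r r^T], which
        depends on the coordinate origin and is provided for audit only.
    ddof :
        Delta degrees of freedom of the normalisation: 0 (population,
        default) divides by N, 1 divides by N-1.  With one position and
        ``ddof=1`` the tensor is defined as zero.

    Eigenvalues are sorted descending and tiny negatives (>= -1e-9 * u1)
    from the symmetric eigensolver are clamped to zero; anything more
    negative signals corrupt input and raises.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    if n == 0:
        raise EmptyInputError("covariance_tensor needs at least one position")
    com = positions.mean(axis=0)
    centredpos = positions - com if centred else positions
    denom = n - ddof
    if denom <= 0:
        tensor = np.zeros((3, 3))
    else:
        tensor = centredpos.T @ centredpos / denom
    tensor = (tensor + tensor.T) / 2.0  # enforce exact symmetry
    eigvals = np.linalg.eigvalsh(tensor)[::-1]  # descending
    u1 = eigvals[0]
    floor = -EIGENVALUE_CLAMP_REL * max(u1, 0.0)
    if eigvals[-1] < floor - 1e-300:
        raise DomainError(
            f"covariance eigenvalue {eigvals[-1]:.3e} is negative beyond "
            f"numerical tolerance (u1 = {u1:.3e})"
        )
    eigvals = np.clip(eigvals, 0.0, None)
    return CovarianceSummary(
        com=com,
        tensor=tensor,
        eigenvalues=(float(eigvals[0]), float(eigvals[1]), float(eigvals[2])),
        n_voxels=n,
    )


def _check_eigenvalues(u1: float, u2: float, u3: float) -> None:
    if u3 < 0 or u2 < 0 or u1 < 0:
        raise DomainError(f"eigenvalues must be nonnegative, got {(u1, u2, u3)}")
    if not (u1 >= u2 >= u3):
        raise DomainError(f"eigenvalues must be sorted descending, got {(u1, u2, u3)}")


def mci(u1: float, u2: float, u3: float) -> float:
    """Mean covariance index (u1+u2+u3)/3, mm^2. Range [0, inf)."""
    _check_eigenvalues(u1, u2, u3)
    return (u1 + u2 + u3) / 3.0


def cai(u1: float, u2: float, u3: float) -> float:
    """Covariance anisotropy index in [0, 1]; NaN when all eigenvalues are 0.

    The fractional-anisotropy formula
    sqrt(3/2) * sqrt(sum (u_i - ubar)^2) / sqrt(sum u_i^2).
    """
    _check_eigenvalues(u1, u2, u3)
    norm_sq = u1 * u1 + u2 * u2 + u3 * u3
    if norm_sq == 0.0:
        return math.nan
    ubar = (u1 + u2 + u3) / 3.0
    dev_sq = (u1 - ubar) ** 2 + (u2 - ubar) ** 2 + (u3 - ubar) ** 2
    return min(math.sqrt(1.5 * dev_sq / norm_sq), 1.0)


def cpi(u1: float, u2: float, u3: float) -> float:
    """Covariance planarity index 2(u2-u3)/(u1+u2+u3) in [0, 1]; NaN at zero trace."""
    _check_eigenvalues(u1, u2, u3)
    trace = u1 + u2 + u3
    if trace == 0.0:
        return math.nan
    return 2.0 * (u2 - u3) / trace


def csi(u1: float, u2: float, u3: float) -> float:
    """Covariance sphericity index 3*u3/(u1+u2+u3) in [0, 1]; NaN at zero trace."""
    _check_eigenvalues(u1, u2, u3)
    trace = u1 + u2 + u3
    if trace == 0.0:
        return math.nan
    return 3.0 * u3 / trace


def shape_metrics(summary: CovarianceSummary) -> ShapeMetrics:
    """Bundle MCI/CAI/CPI/CSI from a covariance summary.

    A zero-trace tensor (single voxel, or numerically collapsed input) is
    flagged degenerate: MCI is 0 and the three shape indices are NaN.
    """
    u1, u2, u3 = summary.eigenvalues
    degenerate = (u1 + u2 + u3) == 0.0
    return ShapeMetrics(
        mci=mci(u1, u2, u3),
        cai=cai(u1, u2, u3),
        cpi=cpi(u1, u2, u3),
        csi=csi(u1, u2, u3),
        degenerate_flag=degenerate,
    )
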