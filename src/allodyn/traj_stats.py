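"""Trajectory fluctuation and correlation statistics.

All statistics are Cα-level and require a superposed (rigid-body
fitted) trajectory; :func:`superpose` performs the least-squares
Kabsch fit against either the first frame or the iteratively refined
mean structure.

* :func:`rmsd_series` — per-frame root-mean-square deviation from a
  reference frame (convergence diagnostic).
* :func:`rmsf` — per-residue root-mean-square fluctuation about the
  trajectory mean.
* :func:`dccm` — the dynamic cross-correlation map
  ``C_ij = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)`` with
  ``Δr = r − <r>``: +1 for fully correlated residue motions, −1 for
  fully anticorrelated, 0 for uncorrelated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structio import CoarseStructure, Trajectory

logger = logging.getLogger("allodyn.traj_stats")

__all__ = ["CorrelationMap", "superpose", "rmsd_series", "rmsf", "dccm"]


@dataclass
class CorrelationMap:
    """Symmetric N×N dynamic cross-correlation matrix in [−1, 1]."""

    matrix: np.ndarray
    structure_ref: CoarseStructure

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation map must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation map diagonal must be 1")


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid fit of ``mobile`` onto ``target``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    P = mobile - mc
    Q = target - tc
    U, s, Vt = np.linalg.svd(P.T @ Q)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        logger.warning("degenerate (collinear) frame: translated only")
        return mobile - mc + tc
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return P @ R + tc


def superpose(traj: Trajectory, reference: str = "first-frame") -> Trajectory:
    """Rigid-body fit every frame onto a common reference.

    ``reference`` is ``"first-frame"`` or ``"mean"``; the mean reference
    is refined by iterative mean-fitting until the mean structure moves
    by less than 1e-6 Å (at most 20 iterations).
    """
    if reference not in ("first-frame", "mean"):
        raise ValueError(f"unknown reference {reference!r}")
    frames = traj.frames
    ref = frames[0]
    fitted = np.array([_kabsch(f, ref) for f in frames])
    if reference == "mean":
        for _ in range(20):
            new_ref = fitted.mean(axis=0)
            shift = np.abs(new_ref - ref).max()
            ref = new_ref
            fitted = np.array([_kabsch(f, ref) for f in frames])
            if shift < 1e-6:
                break
    return Trajectory(fitted, traj.structure_ref, aligned=True)


def _require_aligned(traj: Trajectory) -> None:
    if not traj.aligned:
        raise ValueError("trajectory must be superposed first (see superpose)")


def rmsd_series(traj: Trajectory, reference_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (Å) relative to one frame of an aligned trajectory."""
    _require_aligned(traj)
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    diff = traj.frames - traj.frames[reference_frame]
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def rmsf(traj: Trajectory) -> np.ndarray:
    """Per-residue RMSF (Å) about the trajectory mean structure."""
    _require_aligned(traj)
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    dev = traj.frames - traj.frames.mean(axis=0)
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def dccm(traj: Trajectory) -> CorrelationMap:
    """Dynamic cross-correlation map of an aligned trajectory.

    Raises on residues with zero positional variance (their correlation
    is undefined), naming the first offending residue.
    """
    _require_aligned(traj)
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    dev = traj.frames - traj.frames.mean(axis=0)
    cov = np.einsum("fia,fja->ij", dev, dev) / traj.n_frames
    var = np.diag(cov)
    if np.any(var <= 0):
        bad = int(np.argmax(var <= 0))
        label = traj.structure_ref.labels[bad]
        raise FloatingPointError(f"residue {label} has zero variance")
    corr = cov / np.sqrt(np.outer(var, var))
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMap(corr, traj.structure_ref)
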