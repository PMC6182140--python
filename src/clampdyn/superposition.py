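"""Rigid-body superposition (Kabsch) of trajectory frames.

Removing global rotation and translation of the clamp is the first step of
the ring-tracking pipeline: every geometric quantity downstream (chain
centres, DNA centre, ring-plane PCA) is only meaningful in the clamp's own
frame of reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures_io import AtomSelection, Trajectory

__all__ = ["RigidFit", "GeometryError", "kabsch_fit", "apply_fit", "superpose_trajectory"]


class GeometryError(ValueError):
    """Degenerate point configuration for a rigid fit."""


@dataclass
class RigidFit:
    """Proper rotation + translation mapping moving points onto reference.

    ``x_aligned = x_mov @ rotation.T + translation``; ``rmsd`` is the
    residual root-mean-square deviation in Å after the fit.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation must be proper orthogonal (det={det})")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def kabsch_fit(ref_coords: np.ndarray, mov_coords: np.ndarray) -> RigidFit:
    """Least-squares proper rotation/translation of mov onto ref.

    SVD solution of the orthogonal Procrustes problem with the reflection
    branch corrected to det(R) = +1, so mirrored inputs yield the best
    *proper* rotation rather than an improper one.

    Raises
    ------
    GeometryError
        Fewer than 3 point pairs, or points collinear (covariance rank < 2).
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mov must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 point pairs for a rigid fit, got {n}")

    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    P = ref - ref_c
    Q = mov - mov_c
    H = Q.T @ P
    U, S, Vt = np.linalg.svd(H)
    # rank check on the centred point clouds, not H (H can be rank-deficient
    # for perfectly planar but valid configurations only in the 3rd s.v.)
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, float(np.abs(P).max()))) < 2:
        raise GeometryError("reference points are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mov_c
    aligned = Q @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - P) ** 2, axis=1))))
    return RigidFit(rotation=R, translation=t, rmsd=rmsd)


def apply_fit(coords: np.ndarray, fit: RigidFit) -> np.ndarray:
    """Apply a rigid fit to an (n, 3) coordinate array."""
    return np.asarray(coords, dtype=float) @ fit.rotation.T + fit.translation


def superpose_trajectory(
    traj: Trajectory,
    fit_selection: AtomSelection,
    ref_frame: int = 0,
) -> Trajectory:
    """Superpose every frame onto ``ref_frame`` using the fit-selection atoms.

    The rigid transform computed on the fit selection (typically the clamp
    Cα atoms) is applied to *all* atoms of the frame, DNA included, so that
    internal motion of the DNA relative to the clamp is preserved.
    """
    if not (0 <= ref_frame < traj.n_frames):
        raise IndexError(
            f"ref_frame {ref_frame} out of range for {traj.n_frames} frames"
        )
    if len(fit_selection) < 3:
        raise GeometryError("fit selection must contain at least 3 atoms")
    idx = fit_selection.indices
    ref = traj.coords[ref_frame, idx]
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        try:
            fit = kabsch_fit(ref, traj.coords[f, idx])
        except GeometryError as exc:
            raise GeometryError(f"frame {f}: {exc}") from None
        out[f] = apply_fit(traj.coords[f], fit)
    return Trajectory(atoms=traj.atoms, coords=out, times=traj.times)
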