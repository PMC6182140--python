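"""Track the DNA position inside the clamp ring by chain-centre PCA.

The procedure, applied to an already-superposed trajectory:

1. compute the centre of each of the three clamp chains in every frame;
2. compute the centre of the DNA segment lying inside the ring;
3. run a principal component analysis on the pooled chain centres — the
   first two components span the ring plane;
4. project the per-frame DNA centre onto those two components.

The resulting 2D track starts near (0, 0) when the DNA axis threads the
ring symmetrically and drifts as the DNA settles against the inner wall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structures_io import AtomSelection, Trajectory, select_atoms

__all__ = [
    "RingBasis",
    "RingProjection",
    "chain_centres",
    "dna_segment_centre",
    "ring_plane_pca",
    "project_dna",
    "drift_summary",
    "track_pipeline",
]


@dataclass
class RingBasis:
    """Orthonormal ring-plane basis from chain-centre PCA.

    origin : grand mean of the pooled chain centres (Å).
    components : rows are unit vectors, ordered by descending eigenvalue;
        component 3 is the ring axis (cross product of 1 and 2).
    eigenvalues : variances (Å²) along each component, descending.
    """

    origin: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        G = self.components @ self.components.T
        if not np.allclose(G, np.eye(3), atol=1e-9):
            raise ValueError("components must be orthonormal")
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < -1e-12) or np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be non-negative and descending")


@dataclass
class RingProjection:
    """Per-frame 2D DNA-centre track plus time-averaged chain positions."""

    frames: np.ndarray
    xy: np.ndarray
    chain_xy: dict[str, np.ndarray]

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.xy, axis=1)


def chain_centres(
    traj: Trajectory,
    chain_ids: Sequence[str] = ("A", "B", "C"),
    atom_scope: str = "atomname in {CA}",
) -> np.ndarray:
    """Per-frame unweighted centroids of each clamp chain.

    Returns an array of shape (n_frames, n_chains, 3).  ``atom_scope`` is a
    selection expression restricting which atoms define the centre
    (default: Cα trace).
    """
    sels = []
    for cid in chain_ids:
        sel = select_atoms(traj, f"chain={cid} AND {atom_scope}")
        if len(sel) == 0:
            raise ValueError(f"chain {cid!r}: no atoms match scope {atom_scope!r}")
        sels.append(sel.indices)
    out = np.empty((traj.n_frames, len(chain_ids), 3))
    for k, idx in enumerate(sels):
        out[:, k, :] = traj.coords[:, idx, :].mean(axis=1)
    return out


def dna_segment_centre(traj: Trajectory, bp_selection: AtomSelection) -> np.ndarray:
    """Per-frame centroid of the in-ring DNA segment (both strands pooled).

    The selection should resolve the heavy atoms of the base pairs lying
    inside the ring (e.g. ``chain=F AND resnum in 17-21`` combined with the
    complementary stretch on the other strand).
    """
    if len(bp_selection) == 0:
        raise ValueError("DNA segment selection is empty")
    chains = {traj.atoms[i].chain_id for i in bp_selection.indices}
    if len(chains) < 2:
        raise ValueError(
            f"DNA segment selection covers only strand(s) {sorted(chains)}; "
            "both strands are required"
        )
    return traj.coords[:, bp_selection.indices, :].mean(axis=1)


def _pool(chain_centre_series: np.ndarray) -> np.ndarray:
    arr = np.asarray(chain_centre_series, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("chain centre series must have shape (n_frames, n_chains, 3)")
    return arr.reshape(-1, 3)


def ring_plane_pca(chain_centre_series: np.ndarray) -> RingBasis:
    """PCA over the pooled per-frame chain centres.

    All centres from all frames are pooled (3·n_frames points), mean
    centred, and the covariance eigen-decomposed.  Components are ordered
    by descending eigenvalue with a deterministic sign convention:
    component 1 points so the first chain's time-averaged centre projects
    to positive x, component 2 so the second chain projects to positive y,
    and component 3 = component1 × component2 (right-handed).
    """
    arr = np.asarray(chain_centre_series, dtype=float)
    pooled = _pool(arr)
    origin = pooled.mean(axis=0)
    X = pooled - origin
    if np.allclose(X, 0.0, atol=1e-12):
        raise ValueError("degenerate geometry: all chain centres coincide")
    n = pooled.shape[0]
    ddof = 1 if n > 1 else 0
    cov = X.T @ X / max(n - ddof, 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals, kind="stable")[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T  # rows

    mean_centres = arr.mean(axis=0)  # (n_chains, 3) time averages
    if (mean_centres[0] - origin) @ comps[0] < 0:
        comps[0] = -comps[0]
    if (mean_centres[1] - origin) @ comps[1] < 0:
        comps[1] = -comps[1]
    comps[2] = np.cross(comps[0], comps[1])
    return RingBasis(origin=origin, components=comps, eigenvalues=evals)


def project_dna(
    dna_centre_series: np.ndarray,
    basis: RingBasis,
    chain_centre_series: np.ndarray | None = None,
    chain_ids: Sequence[str] = ("A", "B", "C"),
) -> RingProjection:
    """Project per-frame DNA centres onto the first two basis components."""
    centres = np.asarray(dna_centre_series, dtype=float)
    if centres.ndim != 2 or centres.shape[1] != 3 or centres.shape[0] == 0:
        raise ValueError("dna centre series must be a non-empty (n_frames, 3) array")
    plane = basis.components[:2]
    xy = (centres - basis.origin) @ plane.T
    chain_xy: dict[str, np.ndarray] = {}
    if chain_centre_series is not None:
        means = np.asarray(chain_centre_series, dtype=float).mean(axis=0)
        for cid, c in zip(chain_ids, means):
            chain_xy[cid] = (c - basis.origin) @ plane.T
    return RingProjection(frames=np.arange(centres.shape[0]), xy=xy, chain_xy=chain_xy)


def drift_summary(projection: RingProjection, final_fraction: float = 0.2) -> dict:
    """Summarise the 2D track: radii, final-window mean, nearest chain.

    The final window is the trailing ``final_fraction`` of frames (at least
    one frame).  If the final mean sits at the origin the track is reported
    as ``"centred"`` with no nearest chain.
    """
    if not 0 < final_fraction <= 1:
        raise ValueError("final_fraction must be in (0, 1]")
    radii = projection.radii()
    n = len(radii)
    w = max(1, int(round(final_fraction * n)))
    final_mean = projection.xy[n - w:].mean(axis=0)
    final_r = float(np.linalg.norm(final_mean))
    nearest = None
    if final_r > 1e-9 and projection.chain_xy:
        nearest = min(
            projection.chain_xy,
            key=lambda cid: float(np.linalg.norm(projection.chain_xy[cid] - final_mean)),
        )
    return {
        "radii": radii,
        "final_window_frames": w,
        "final_mean_xy": final_mean,
        "final_radius": final_r,
        "nearest_chain": nearest,
        "status": "centred" if nearest is None else "drifted",
    }


def track_pipeline(
    traj: Trajectory,
    clamp_chain_ids: Sequence[str] = ("A", "B", "C"),
    dna_selection_spec: str = "chain=F AND resnum in 17-21",
    dna_selection_spec_2: str | None = "chain=G AND resnum in 20-24",
    atom_scope: str = "atomname in {CA}",
) -> tuple[RingBasis, RingProjection, pd.DataFrame]:
    """Convenience wrapper: centres → PCA → projection → tidy table.

    Assumes the trajectory is already superposed.  Returns the basis, the
    projection and a per-frame DataFrame (frame, time_ns?, x_A, y_A, r_A).
    """
    from .structures_io import AtomSelection

    centres = chain_centres(traj, clamp_chain_ids, atom_scope)
    sel1 = select_atoms(traj, dna_selection_spec)
    idx = list(sel1.indices)
    spec = dna_selection_spec
    if dna_selection_spec_2:
        sel2 = select_atoms(traj, dna_selection_spec_2)
        idx = sorted(set(idx) | set(sel2.indices))
        spec = f"({dna_selection_spec}) OR ({dna_selection_spec_2})"
    dna_sel = AtomSelection(indices=np.array(idx, dtype=int), spec=spec)
    dna_centres = dna_segment_centre(traj, dna_sel)
    basis = ring_plane_pca(centres)
    proj = project_dna(dna_centres, basis, centres, clamp_chain_ids)
    table = pd.DataFrame(
        {
            "frame": proj.frames,
            "x_A": proj.xy[:, 0],
            "y_A": proj.xy[:, 1],
            "r_A": proj.radii(),
        }
    )
    if traj.times is not None:
        table.insert(1, "time_ns", traj.times)
    return basis, proj, table
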