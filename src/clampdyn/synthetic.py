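"""Ground-truth synthetic inputs: clamp-ring + DNA trajectories and
fast-exchange CSP titrations.

The trajectory generator builds a pseudo-atomic model of a trimeric
ring-shaped clamp threaded by an ideal B-form duplex: three rigid
Cα-trace chains arranged with C3 symmetry about the z axis, and two
phosphate-trace DNA strands (chains F and G) with 3.4 Å helical rise and
36° twist per base pair.  The DNA axis can be displaced laterally
(drift schedule) and tilted frame by frame; optional isotropic Gaussian
noise and a global rigid tumble complete the picture.  Every stochastic
choice is seeded and the exact per-frame ground truth is returned (and
written) alongside the coordinates, so downstream estimators can be
scored against what was actually programmed.

The titration generator produces per-residue (δH, δN) tables following
the 1:1 depletion isotherm at a known Kd, with dilution bookkeeping,
designated intermediate-exchange ("disappearing") residues and Gaussian
shift noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nmr_titration import (
    ABSENT_BROADENED,
    TitrationPoint,
    TitrationSeries,
    binding_isotherm,
    dilution_track,
)
from .structures_io import AtomLabel, Trajectory

__all__ = [
    "RingDnaParams",
    "TitrationParams",
    "seeded_rng",
    "make_ring_dna_trajectory",
    "make_titration_dataset",
    "drift_to_chain_schedule",
]

RISE_A = 3.4  # helical rise per bp, Å
TWIST_DEG = 36.0  # helical twist per bp
P_RADIUS_A = 9.4  # radial distance of backbone P from the helix axis, Å


def seeded_rng(seed: int) -> np.random.Generator:
    """Seeded PCG64 generator; all package randomness flows through this."""
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    return np.random.default_rng(int(seed))


@dataclass
class RingDnaParams:
    """Geometry and noise of the synthetic clamp-ring/DNA trajectory.

    drift_schedule: per-frame (x, y) target offset of the DNA axis in the
    ring plane, Å; tilt_schedule: per-frame tilt of the DNA axis from the
    ring normal, degrees.  Schedules default to all-zero.
    """

    n_frames: int = 50
    frame_dt: float = 0.1  # ns
    ring_radius: float = 35.0  # Å, clamp Cα arc radius
    chain_ids: tuple[str, ...] = ("A", "B", "C")
    atoms_per_chain: int = 30
    dna_bp: int = 40
    strand_phase_deg: float = 180.0  # inter-strand P phase (see docs/methods.md)
    drift_schedule: np.ndarray | None = None
    tilt_schedule: np.ndarray | None = None
    noise_sigma: float = 0.0  # Å, isotropic per atom per frame
    global_tumble: bool = False
    donor_radius: float | None = None  # Å; place Lys NZ probes if set
    donors_per_chain: int = 2
    seed: int = 0

    def resolved_schedules(self) -> tuple[np.ndarray, np.ndarray]:
        drift = (
            np.zeros((self.n_frames, 2))
            if self.drift_schedule is None
            else np.asarray(self.drift_schedule, dtype=float)
        )
        tilt = (
            np.zeros(self.n_frames)
            if self.tilt_schedule is None
            else np.asarray(self.tilt_schedule, dtype=float)
        )
        if drift.shape != (self.n_frames, 2):
            raise ValueError(
                f"drift_schedule must have shape ({self.n_frames}, 2), got {drift.shape}"
            )
        if tilt.shape != (self.n_frames,):
            raise ValueError(
                f"tilt_schedule must have length {self.n_frames}, got {tilt.shape}"
            )
        return drift, tilt


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _clamp_chain_atoms(params: RingDnaParams):
    """Static (frame-independent) clamp pseudo-atoms: labels + coordinates."""
    labels: list[AtomLabel] = []
    coords: list[np.ndarray] = []
    sector = 2 * np.pi / len(params.chain_ids)
    arc = 0.92 * sector  # leave a gap between chains
    for k, cid in enumerate(params.chain_ids):
        theta0 = k * sector
        for j in range(params.atoms_per_chain):
            frac = (j + 0.5) / params.atoms_per_chain - 0.5
            th = theta0 + frac * arc
            # two z-layers so the ring slab has finite thickness
            z = 2.0 if j % 2 else -2.0
            labels.append(AtomLabel(cid, "GLY", j + 1, "CA", "C"))
            coords.append(
                np.array(
                    [params.ring_radius * np.cos(th), params.ring_radius * np.sin(th), z]
                )
            )
        if params.donor_radius is not None:
            for d in range(params.donors_per_chain):
                frac = (d + 0.5) / params.donors_per_chain - 0.5
                th = theta0 + frac * arc * 0.8
                labels.append(
                    AtomLabel(cid, "LYS", params.atoms_per_chain + 1 + d, "NZ", "N")
                )
                coords.append(
                    np.array(
                        [
                            params.donor_radius * np.cos(th),
                            params.donor_radius * np.sin(th),
                            0.0,
                        ]
                    )
                )
    return labels, np.array(coords)


def _dna_atoms(params: RingDnaParams):
    """Ideal duplex P trace along +z, centred so the in-ring segment
    (residues 17–21 on F, paired 20–24 on G) straddles z = 0.

    Strand F nucleotide i sits at angle 36°·i and height 3.4·(i − centre);
    strand G's paired phosphate sits at the same height, phase-shifted by
    ``strand_phase_deg``.  Pairing is F_i : G_(n+1−i).
    """
    n = params.dna_bp
    centre_bp = 19.0  # midpoint of F 17–21
    phase = np.deg2rad(params.strand_phase_deg)
    labels: list[AtomLabel] = []
    coords: list[np.ndarray] = []
    for i in range(1, n + 1):
        th = np.deg2rad(TWIST_DEG) * i
        z = RISE_A * (i - centre_bp)
        labels.append(AtomLabel("F", "DA", i, "P", "P"))
        coords.append(np.array([P_RADIUS_A * np.cos(th), P_RADIUS_A * np.sin(th), z]))
    for i in range(1, n + 1):  # G residue j = n+1−i pairs with F_i
        th = np.deg2rad(TWIST_DEG) * i + phase
        z = RISE_A * (i - centre_bp)
        j = n + 1 - i
        labels.append(AtomLabel("G", "DT", j, "P", "P"))
        coords.append(np.array([P_RADIUS_A * np.cos(th), P_RADIUS_A * np.sin(th), z]))
    return labels, np.array(coords)


def make_ring_dna_trajectory(params: RingDnaParams) -> tuple[Trajectory, dict]:
    """Build the synthetic trajectory and its ground-truth record.

    Returns (trajectory, truth).  ``truth`` holds, per frame, the exact
    programmed DNA-axis offset in the ring plane (before noise), the tilt,
    and — if tumbling — the applied global rotations/translations; plus the
    seed and all parameters.  The truth record is sufficient to predict
    every downstream tracking quantity without re-reading coordinates.
    """
    drift, tilt = params.resolved_schedules()
    # independent streams: toggling the tumble must not change the noise
    rng = np.random.default_rng([int(params.seed), 0])
    rng_tumble = np.random.default_rng([int(params.seed), 1])

    clamp_labels, clamp_xyz = _clamp_chain_atoms(params)
    dna_labels, dna_xyz0 = _dna_atoms(params)
    labels = clamp_labels + dna_labels
    n_atoms = len(labels)

    coords = np.empty((params.n_frames, n_atoms, 3))
    tumbles = []
    for f in range(params.n_frames):
        dna = dna_xyz0.copy()
        if tilt[f] != 0.0:
            # tilt about the in-plane axis perpendicular to the drift direction
            d = drift[f]
            axis = np.array([-d[1], d[0], 0.0]) if np.linalg.norm(d) > 1e-12 else np.array([1.0, 0.0, 0.0])
            dna = dna @ _rotation_about(axis, np.deg2rad(tilt[f])).T
        dna[:, 0] += drift[f, 0]
        dna[:, 1] += drift[f, 1]
        frame = np.vstack([clamp_xyz, dna])
        if params.noise_sigma > 0:
            frame = frame + rng.normal(0.0, params.noise_sigma, frame.shape)
        if params.global_tumble:
            ax = rng_tumble.normal(size=3)
            ang = rng_tumble.uniform(0, 2 * np.pi)
            R = _rotation_about(ax, ang)
            t = rng_tumble.uniform(-20, 20, size=3)
            frame = frame @ R.T + t
            tumbles.append({"rotation": R.tolist(), "translation": t.tolist()})
        coords[f] = frame

    times = np.arange(params.n_frames) * params.frame_dt if params.frame_dt > 0 else None
    traj = Trajectory(atoms=labels, coords=coords, times=times)
    truth = {
        "seed": params.seed,
        "n_frames": params.n_frames,
        "frame_dt_ns": params.frame_dt,
        "ring_radius_A": params.ring_radius,
        "noise_sigma_A": params.noise_sigma,
        "drift_xy_A": drift.tolist(),
        "tilt_deg": tilt.tolist(),
        "global_tumble": params.global_tumble,
        "tumbles": tumbles,
        "chain_ids": list(params.chain_ids),
        "dna_bp": params.dna_bp,
        "inring_selection": {"F": [17, 21], "G": [20, 24]},
    }
    return traj, truth


def drift_to_chain_schedule(
    n_frames: int,
    magnitude: float,
    chain_index: int = 2,
    n_chains: int = 3,
    start_frame: int = 1,
) -> np.ndarray:
    """Linear drift schedule toward a given chain's direction in the ring plane.

    Chain k of a C3 ring sits at angle k·120°(+half sector offset matching
    the generator layout); the offset ramps linearly from ``start_frame``
    to ``magnitude`` Å at the final frame, with zero offset before.
    """
    theta = chain_index * 2 * np.pi / n_chains
    direction = np.array([np.cos(theta), np.sin(theta)])
    drift = np.zeros((n_frames, 2))
    if n_frames > start_frame:
        ramp = np.linspace(0.0, 1.0, n_frames - start_frame)
        drift[start_frame:] = magnitude * ramp[:, None] * direction
    return drift


@dataclass
class TitrationParams:
    """Conditions of the synthetic fast-exchange CSP titration.

    Defaults mirror a typical clamp/peptide NMR titration: 100 μM receptor,
    8 additions reaching a 6.4-fold molar excess of ligand, ~7% cumulative
    receptor dilution, shift noise of 0.002 ppm.
    """

    n_residues: int = 20
    Kd_true: float = 35.0  # μM
    receptor_initial: float = 100.0  # μM
    ratios: tuple[float, ...] = (0.2, 0.4, 0.8, 1.6, 2.4, 3.2, 4.8, 6.4)
    ddmax_range: tuple[float, float] = (0.02, 0.15)  # ppm
    disappearing: tuple = ()  # residue ids
    disappearance_ratio: float = 0.5
    noise_ppm: float = 0.0
    alpha: float = 0.2
    initial_volume: float = 400.0  # μL
    stock_concentration: float = 9520.0  # μM ligand stock
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios)
        if np.any(np.diff(r) <= 0):
            raise ValueError("ratios must be strictly increasing")
        if self.disappearing and self.disappearance_ratio >= max(self.ratios):
            raise ValueError("disappearance ratio must be below the final ratio")


def make_titration_dataset(params: TitrationParams) -> tuple[TitrationSeries, dict]:
    """Synthetic titration with exact depletion/dilution bookkeeping.

    Ligand-stock volumes are chosen so the *moles* of ligand per point hit
    the requested ligand:receptor(initial) ratios; receptor dilution then
    follows mass balance exactly, as in a real stepwise titration.
    """
    rng = seeded_rng(params.seed)
    moles_receptor = params.receptor_initial * params.initial_volume  # pmol-scale units
    cum_vols = np.asarray(params.ratios) * moles_receptor / params.stock_concentration
    add_vols = np.diff(np.concatenate([[0.0], cum_vols]))
    conc = dilution_track(
        params.receptor_initial,
        params.initial_volume,
        params.stock_concentration,
        add_vols,
    )

    residues = [f"R{i+1}" for i in range(params.n_residues)]
    ddmax = rng.uniform(*params.ddmax_range, size=params.n_residues)
    phi = rng.uniform(0, np.pi / 2, size=params.n_residues)  # split of Δδ into H/N
    free_h = rng.uniform(7.0, 9.5, size=params.n_residues)
    free_n = rng.uniform(105.0, 130.0, size=params.n_residues)

    points: list[TitrationPoint] = []
    for k in range(len(conc)):
        R = float(conc["receptor_total"].iloc[k])
        L = float(conc["ligand_total"].iloc[k])
        f = binding_isotherm(R, L, params.Kd_true) if L > 0 else 0.0
        ratio = L / R
        shifts, status = {}, {}
        for i, res in enumerate(residues):
            if res in params.disappearing and k > 0 and ratio >= params.disappearance_ratio:
                status[res] = ABSENT_BROADENED
                continue
            dh = f * ddmax[i] * np.cos(phi[i])
            dn = f * ddmax[i] * np.sin(phi[i]) / params.alpha
            h = free_h[i] + dh
            n = free_n[i] + dn
            if params.noise_ppm > 0:
                h += rng.normal(0.0, params.noise_ppm)
                n += rng.normal(0.0, params.noise_ppm / params.alpha)
            shifts[res] = (float(h), float(n))
        points.append(
            TitrationPoint(ligand_total=L, receptor_total=R, shifts=shifts, status=status)
        )

    truth = {
        "seed": params.seed,
        "Kd_true_uM": params.Kd_true,
        "alpha": params.alpha,
        "ddmax_ppm": {res: float(d) for res, d in zip(residues, ddmax)},
        "disappearing": list(params.disappearing),
        "noise_ppm": params.noise_ppm,
        "ratios": list(params.ratios),
        "receptor_initial_uM": params.receptor_initial,
        "final_dilution_fraction": float(
            1.0 - conc["receptor_total"].iloc[-1] / params.receptor_initial
        ),
    }
    return TitrationSeries(points=points), truth


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
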