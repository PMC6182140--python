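import numpy as np
import pytest

from clampdyn.structures_io import AtomLabel, Trajectory


def make_traj(rows, times=None):
    """Build a Trajectory from [(chain, resname, resnum, atomname, element, coords_per_frame)]."""
    labels = [AtomLabel(*r[:5]) for r in rows]
    n_frames = len(rows[0][5])
    coords = np.array([[r[5][f] for r in rows] for f in range(n_frames)], dtype=float)
    return Trajectory(atoms=labels, coords=coords, times=times)


@pytest.fixture
def centred_ring_traj():
    from clampdyn.synthetic import RingDnaParams, make_ring_dna_trajectory

    params = RingDnaParams(n_frames=8, noise_sigma=0.0, seed=11)
    traj, truth = make_ring_dna_trajectory(params)
    return traj, truth
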