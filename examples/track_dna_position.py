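"""Track the lateral position of DNA inside a trimeric sliding clamp.

Builds a synthetic trajectory in which the duplex starts on the ring axis
and drifts 5 Å toward chain C, removes global motion by superposing the
clamp Cα atoms, and projects the in-ring DNA centre onto the plane spanned
by the first two principal components of the pooled chain centres.
"""

import numpy as np

from clampdyn.ring_tracking import drift_summary, track_pipeline
from clampdyn.structures_io import select_atoms
from clampdyn.superposition import superpose_trajectory
from clampdyn.synthetic import (
    RingDnaParams,
    drift_to_chain_schedule,
    make_ring_dna_trajectory,
)

n_frames = 50
drift = drift_to_chain_schedule(n_frames, magnitude=5.0, chain_index=2)
params = RingDnaParams(
    n_frames=n_frames,
    drift_schedule=drift,
    noise_sigma=0.3,  # Å of thermal jitter per atom
    global_tumble=True,  # the raw frames tumble; superposition removes it
    seed=42,
)
traj, truth = make_ring_dna_trajectory(params)

clamp_ca = select_atoms(traj, "atomname in {CA}")
superposed = superpose_trajectory(traj, clamp_ca, ref_frame=0)
basis, projection, table = track_pipeline(superposed)
summary = drift_summary(projection)

print(f"frame 0 position : ({projection.xy[0,0]:+.2f}, {projection.xy[0,1]:+.2f}) Å")
print(f"final position   : ({projection.xy[-1,0]:+.2f}, {projection.xy[-1,1]:+.2f}) Å")
print(f"final radius     : {summary['final_radius']:.2f} Å "
      f"(programmed drift {np.linalg.norm(truth['drift_xy_A'][-1]):.2f} Å)")
print(f"nearest chain    : {summary['nearest_chain']}")
# The DNA starts at the ring centre (0,0) and settles ~5 Å off-centre
# toward chain C — the projection recovers the programmed drift despite
# the 0.3 Å noise and the global tumbling of the raw coordinates.
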