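import numpy as np
import pytest

from clampdyn.ring_tracking import (
    RingBasis,
    chain_centres,
    dna_segment_centre,
    drift_summary,
    project_dna,
    ring_plane_pca,
    track_pipeline,
)
from clampdyn.structures_io import AtomSelection, Trajectory, select_atoms
from clampdyn.superposition import superpose_trajectory
from clampdyn.synthetic import (
    RingDnaParams,
    _rotation_about,
    drift_to_chain_schedule,
    make_ring_dna_trajectory,
)

from conftest import make_traj


def triangle_centres(n_frames=1, z=0.0):
    """Static equilateral triangle in the z-plane, shape (n_frames, 3, 3)."""
    pts = np.array(
        [[np.cos(a), np.sin(a), z] for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)]
    )
    return np.tile(pts, (n_frames, 1, 1))


class TestChainCentres:
    def test_single_atom_per_chain_is_that_atom(self):
        rows = [
            (c, "GLY", 1, "CA", "C", [(x, float(k), 0.0), (x, float(k), 1.0)])
            for k, (c, x) in enumerate([("A", 1.0), ("B", 2.0), ("C", 3.0)])
        ]
        traj = make_traj(rows)
        cc = chain_centres(traj)
        assert np.allclose(cc[0], [[1, 0, 0], [2, 1, 0], [3, 2, 0]])
        assert np.allclose(cc[1, :, 2], 1.0)

    def test_c3_symmetry(self, centred_ring_traj):
        traj, truth = centred_ring_traj
        cc = chain_centres(traj)[0]
        d = [np.linalg.norm(cc[i] - cc[(i + 1) % 3]) for i in range(3)]
        assert np.ptp(d) < 1e-9
        assert np.linalg.norm(cc.mean(axis=0)[:2]) < 1e-9  # mean on the ring axis

    def test_missing_chain_errors(self, centred_ring_traj):
        traj, _ = centred_ring_traj
        with pytest.raises(ValueError, match="'Z'"):
            chain_centres(traj, chain_ids=("A", "B", "Z"))


class TestDnaCentre:
    def test_symmetric_base_pair_centres_at_origin(self, centred_ring_traj):
        traj, _ = centred_ring_traj
        sel1 = select_atoms(traj, "chain=F AND resnum in 19-19")
        sel2 = select_atoms(traj, "chain=G AND resnum in 22-22")
        idx = np.sort(np.concatenate([sel1.indices, sel2.indices]))
        centre = dna_segment_centre(traj, AtomSelection(indices=idx))[0]
        assert np.linalg.norm(centre[:2]) < 1e-9  # antipodal P pair

    def test_in_ring_segment_within_slab(self, centred_ring_traj):
        traj, _ = centred_ring_traj
        sel1 = select_atoms(traj, "chain=F AND resnum in 17-21")
        sel2 = select_atoms(traj, "chain=G AND resnum in 20-24")
        idx = np.sort(np.concatenate([sel1.indices, sel2.indices]))
        centre = dna_segment_centre(traj, AtomSelection(indices=idx))
        assert np.all(np.abs(centre[:, 2]) < 12.0)

    def test_single_strand_selection_errors(self, centred_ring_traj):
        traj, _ = centred_ring_traj
        sel = select_atoms(traj, "chain=F AND resnum in 17-21")
        with pytest.raises(ValueError, match="both strands"):
            dna_segment_centre(traj, sel)

    def test_out_of_range_selection_is_empty(self, centred_ring_traj):
        traj, _ = centred_ring_traj
        with pytest.warns(UserWarning):
            sel = select_atoms(traj, "chain=F AND resnum in 50-60")
        with pytest.raises(ValueError, match="empty"):
            dna_segment_centre(traj, sel)


class TestRingPlanePCA:
    def test_planar_triangle_spans_plane(self):
        basis = ring_plane_pca(triangle_centres(n_frames=4))
        assert abs(basis.components[0][2]) < 1e-9
        assert abs(basis.components[1][2]) < 1e-9
        assert basis.eigenvalues[2] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.abs(basis.components[2]), [0, 0, 1], atol=1e-9)

    def test_single_frame_three_points(self):
        basis = ring_plane_pca(triangle_centres(n_frames=1))
        assert basis.eigenvalues[2] == 0.0

    def test_rotation_invariance_of_projected_distances(self):
        cc = triangle_centres(n_frames=2)
        R = _rotation_about(np.array([1.0, 1.0, 0.3]), 0.8)
        cc_rot = cc @ R.T
        def proj_dists(c):
            b = ring_plane_pca(c)
            xy = (c.mean(axis=0) - b.origin) @ b.components[:2].T
            return sorted(
                np.linalg.norm(xy[i] - xy[j]) for i in range(3) for j in range(i)
            )
        assert np.allclose(proj_dists(cc), proj_dists(cc_rot), atol=1e-9)

    def test_sign_convention_deterministic(self, centred_ring_traj):
        traj, _ = centred_ring_traj
        cc = chain_centres(traj)
        basis = ring_plane_pca(cc)
        means = cc.mean(axis=0)
        assert (means[0] - basis.origin) @ basis.components[0] > 0
        assert (means[1] - basis.origin) @ basis.components[1] > 0
        assert np.allclose(
            basis.components[2],
            np.cross(basis.components[0], basis.components[1]),
        )

    def test_coincident_centres_error(self):
        cc = np.ones((3, 3, 3))
        with pytest.raises(ValueError, match="degenerate"):
            ring_plane_pca(cc)

    def test_pca_bookkeeping_identity(self):
        """Sum of squared in-plane projections of the pooled centres equals
        (λ1+λ2)·(N−1) with N = 3·n_frames pooled points."""
        rng = np.random.default_rng(12)
        cc = triangle_centres(n_frames=10) * 20 + rng.normal(0, 1.0, (10, 3, 3))
        basis = ring_plane_pca(cc)
        pooled = cc.reshape(-1, 3) - basis.origin
        ss = np.sum((pooled @ basis.components[:2].T) ** 2)
        n = pooled.shape[0]
        assert ss == pytest.approx((basis.eigenvalues[0] + basis.eigenvalues[1]) * (n - 1))


class TestProjection:
    def test_origin_projects_to_zero_and_unit_displacement(self):
        cc = triangle_centres(n_frames=3)
        basis = ring_plane_pca(cc)
        dna = np.tile(basis.origin, (3, 1))
        proj = project_dna(dna, basis, cc)
        assert np.allclose(proj.xy, 0.0, atol=1e-12)
        d = 2.5
        proj2 = project_dna(dna + d * basis.components[0], basis)
        assert np.allclose(proj2.xy, [[d, 0.0]] * 3, atol=1e-12)

    def test_programmed_drift_recovered_toward_chain(self):
        """Final projected position points at the drift target chain with the
        programmed magnitude, at generator noise 0.3 Å."""
        drift_mag = 5.0
        n = 30
        drift = drift_to_chain_schedule(n, drift_mag, chain_index=2)
        params = RingDnaParams(n_frames=n, drift_schedule=drift, noise_sigma=0.3, seed=21)
        traj, truth = make_ring_dna_trajectory(params)
        sup = superpose_trajectory(traj, select_atoms(traj, "atomname in {CA}"))
        basis, proj, _ = track_pipeline(sup)
        final = proj.xy[-1]
        # C3 symmetry makes the in-plane eigenvectors an arbitrary rotation of
        # the lab axes, so compare rotation-invariant quantities: magnitude,
        # and direction relative to the *projected* chain-C position.
        assert np.linalg.norm(final) == pytest.approx(drift_mag, abs=1.0)
        chain_c = proj.chain_xy["C"]
        cosang = final @ chain_c / (np.linalg.norm(final) * np.linalg.norm(chain_c))
        assert cosang > 0.95
        summary = drift_summary(proj)
        assert summary["nearest_chain"] == "C"

    def test_drift_magnitude_parameter_recovery_over_seeds(self):
        """Estimated final displacement within 3σ-scaled tolerance, 20 seeds."""
        drift_mag = 5.0
        n = 12
        drift = np.zeros((n, 2))
        drift[:, 0] = np.linspace(0, drift_mag, n)  # toward chain A (+x)
        errs = []
        for seed in range(20):
            params = RingDnaParams(
                n_frames=n, drift_schedule=drift, noise_sigma=0.3, seed=100 + seed
            )
            traj, _ = make_ring_dna_trajectory(params)
            sup = superpose_trajectory(traj, select_atoms(traj, "atomname in {CA}"))
            _, proj, _ = track_pipeline(sup)
            errs.append(np.linalg.norm(proj.xy[-1]) - drift_mag)
        # DNA centre averages 10 P atoms: σ_centre ≈ 0.3/sqrt(10) ≈ 0.095 Å
        assert np.all(np.abs(errs) < 3 * 0.3 / np.sqrt(10) + 0.05)

    def test_pipeline_invariant_to_global_tumble(self):
        """With vs without global tumbling: identical projections to 1e-6 Å."""
        n = 6
        drift = drift_to_chain_schedule(n, 3.0, chain_index=1)
        base = dict(n_frames=n, drift_schedule=drift, noise_sigma=0.2)
        out = {}
        for tumble in (False, True):
            params = RingDnaParams(global_tumble=tumble, seed=33, **base)
            traj, _ = make_ring_dna_trajectory(params)
            sup = superpose_trajectory(traj, select_atoms(traj, "atomname in {CA}"))
            _, proj, _ = track_pipeline(sup)
            out[tumble] = proj.xy
        # same seed => identical thermal noise; tumble applied after noise
        assert np.abs(out[True] - out[False]).max() < 1e-6


class TestDriftSummary:
    def test_constant_origin_reports_centred(self):
        cc = triangle_centres(n_frames=5)
        basis = ring_plane_pca(cc)
        proj = project_dna(np.tile(basis.origin, (5, 1)), basis, cc)
        s = drift_summary(proj)
        assert np.allclose(s["radii"], 0.0)
        assert s["status"] == "centred"
        assert s["nearest_chain"] is None

    def test_two_frame_final_window_is_last_frame(self):
        cc = triangle_centres(n_frames=2)
        basis = ring_plane_pca(cc)
        dna = np.array([basis.origin, basis.origin + 4.0 * basis.components[0]])
        proj = project_dna(dna, basis, cc)
        s = drift_summary(proj)
        assert s["final_window_frames"] == 1
        assert s["final_radius"] == pytest.approx(4.0)
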