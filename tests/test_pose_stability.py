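"""Pose-stability scoring: superposition, RMSD, H-bonds, Pose/PersScore."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from vsfunnel.pose_stability import (
    HBondCriteria,
    PoseStabilityResult,
    Topology,
    TrajectorySet,
    detect_hbonds,
    kabsch_superpose,
    ligand_rmsd_series,
    pers_score,
    pose_score,
    rmsd,
    select_stable_pose,
)
from vsfunnel.synthetic_data import TrajectorySpec, gen_trajectory_set


def _random_coords(n, seed=0):
    return np.random.default_rng(seed).normal(size=(n, 3))


class TestKabsch:
    def test_identity_on_equal_coords(self):
        ref = _random_coords(10)
        (R, t), fitted = kabsch_superpose(ref, ref.copy())
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        assert rmsd(fitted, ref) <= 1e-12

    def test_rigid_motion_recovered_exactly(self):
        ref = _random_coords(12, seed=1)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([3.0, -2.0, 7.0])
        _, fitted = kabsch_superpose(ref, mobile)
        assert rmsd(fitted, ref) <= 1e-10

    def test_proper_rotation_det_plus_one(self):
        ref = _random_coords(8, seed=2)
        mobile = _random_coords(8, seed=3)
        (R, _), _ = kabsch_superpose(ref, mobile)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_partial_mask_fit_matches_quaternion_oracle(self):
        """Fit 3 atoms; the 4th is displaced.  Compare the fitted RMSD with
        an independent quaternion-based superposition (scipy align_vectors)."""
        ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [1.0, 1.0, 1.0]])
        mobile = ref.copy()
        mobile[3] += np.array([1.0, 0.0, 0.0])
        rot = Rotation.from_euler("xyz", [10, 25, -40], degrees=True).as_matrix()
        mobile = mobile @ rot.T + np.array([0.3, -1.2, 2.0])
        mask = np.array([True, True, True, False])
        _, fitted = kabsch_superpose(ref, mobile, mask)
        ours = rmsd(fitted, ref)

        # oracle: quaternion best fit of the 3 masked atoms
        mr = ref[mask] - ref[mask].mean(axis=0)
        mm = mobile[mask] - mobile[mask].mean(axis=0)
        R_q, _ = Rotation.align_vectors(mr, mm)
        oracle_all = (mobile - mobile[mask].mean(axis=0)) @ R_q.as_matrix().T + ref[mask].mean(axis=0)
        assert ours == pytest.approx(rmsd(oracle_all, ref), abs=1e-6)

    def test_collinear_mask_rejected(self):
        ref = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(ref, ref + 1.0, np.array([True, True, True, False]))


class TestRmsdSeries:
    def test_reference_trajectory_is_zero(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=2, n_frames=20,
                                               jitter_sd=0.0, seed=1))
        for i in range(2):
            _, series = ligand_rmsd_series(ts, i)
            np.testing.assert_allclose(series, 0.0, atol=1e-10)

    def test_global_rigid_motion_aligned_away(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=1, n_frames=10,
                                               jitter_sd=0.0, seed=2))
        rot = Rotation.from_euler("y", 35, degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 1.0])
        ts.replicates[0] = ts.replicates[0] @ rot.T + shift
        _, series = ligand_rmsd_series(ts, 0)
        np.testing.assert_allclose(series, 0.0, atol=1e-8)

    def test_uniform_unit_displacement_gives_rmsd_one(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=1, n_frames=5,
                                               jitter_sd=0.0, seed=3))
        lig = ts.topology.ligand_heavy
        ts.replicates[0][:, lig, :] += np.array([1.0, 0.0, 0.0])
        _, series = ligand_rmsd_series(ts, 0)
        np.testing.assert_allclose(series, 1.0, atol=1e-10)


class TestPoseScore:
    def test_constant_rmsd_mean(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=3, n_frames=8,
                                               jitter_sd=0.0, seed=4))
        for rep in ts.replicates:
            rep[:, ts.topology.ligand_heavy, :] += np.array([1.0, 0.0, 0.0])
        assert pose_score(ts) == pytest.approx(1.0, abs=1e-10)

    def test_mean_over_replicates(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=2, n_frames=8,
                                               jitter_sd=0.0, seed=5))
        ts.replicates[0][:, ts.topology.ligand_heavy, :] += np.array([0.5, 0, 0])
        ts.replicates[1][:, ts.topology.ligand_heavy, :] += np.array([1.5, 0, 0])
        assert pose_score(ts) == pytest.approx(1.0, abs=1e-10)

    def test_stable_below_drifting_across_seeds(self):
        """Constructed stable poses always beat drifting poses, every seed."""
        for seed in range(20):
            stable = pose_score(gen_trajectory_set(
                TrajectorySpec(motion="stable", n_replicates=2, n_frames=40, seed=seed)))
            drifting = pose_score(gen_trajectory_set(
                TrajectorySpec(motion="drifting", n_replicates=2, n_frames=40, seed=seed)))
            assert stable < drifting, f"seed {seed}"

    def test_monotone_in_displacement(self):
        base = gen_trajectory_set(TrajectorySpec(n_replicates=1, n_frames=6,
                                                 jitter_sd=0.0, seed=6))
        scores = []
        for mag in [0.0, 0.5, 1.0, 2.0]:
            ts = gen_trajectory_set(TrajectorySpec(n_replicates=1, n_frames=6,
                                                   jitter_sd=0.0, seed=6))
            ts.replicates[0][:, ts.topology.ligand_heavy, :] += np.array([mag, 0, 0])
            scores.append(pose_score(ts))
        assert scores == sorted(scores)


def _hbond_frame(dist, angle_deg):
    """Donor at origin, H at 1 A along x; acceptor placed at the requested
    donor-acceptor distance such that the D-H-A angle equals angle_deg."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    # place A on the x-y plane at H + s*(cos(phi), sin(phi), 0)
    phi = np.pi - np.radians(angle_deg)
    # distance from H chosen so |A - D| = dist
    # law of cosines in triangle D-H-A with DH=1, angle at H = angle_deg
    s = np.cos(np.radians(angle_deg)) + np.sqrt(
        dist**2 - np.sin(np.radians(angle_deg)) ** 2
    )
    a = h + s * np.array([np.cos(phi), np.sin(phi), 0.0])
    coords = np.vstack([d, h, a])
    top = Topology(
        names=("D", "H", "A"),
        elements=("N", "H", "O"),
        protein=np.array([True, False, False]),
        ligand_heavy=np.array([False, False, True]),
        donor=np.array([True, False, False]),
        acceptor=np.array([False, False, True]),
        donor_h={0: 1},
    )
    return coords, top


class TestHBonds:
    def test_clear_bond_detected(self):
        coords, top = _hbond_frame(2.8, 175.0)
        assert detect_hbonds(coords, top) == {(0, 1, 2)}

    def test_long_distance_not_detected(self):
        coords, top = _hbond_frame(5.0, 175.0)
        assert detect_hbonds(coords, top) == set()

    def test_boundary_inclusive(self):
        coords, top = _hbond_frame(3.5, 120.0)
        assert detect_hbonds(coords, top) == {(0, 1, 2)}
        # verify constructed geometry is really on the boundary
        assert np.linalg.norm(coords[2] - coords[0]) == pytest.approx(3.5, abs=1e-9)
        v1, v2 = coords[0] - coords[1], coords[2] - coords[1]
        ang = np.degrees(np.arccos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)))
        assert ang == pytest.approx(120.0, abs=1e-7)

    def test_tight_angle_cutoff_excludes(self):
        coords, top = _hbond_frame(2.8, 130.0)
        assert detect_hbonds(coords, top, HBondCriteria(3.5, 150.0)) == set()

    def test_donor_without_hydrogen_rejected(self):
        coords, top = _hbond_frame(2.8, 175.0)
        top.donor_h.clear()
        with pytest.raises(ValueError, match="no attached hydrogen"):
            detect_hbonds(coords, top)


class TestPersScore:
    def test_full_occupancy_is_one(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=2, jitter_sd=0.0,
                                               occupancies=(1.0,), seed=7))
        assert pers_score(ts) == 1.0

    def test_half_occupancy_two_bonds(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=2, jitter_sd=0.0,
                                               occupancies=(1.0, 0.0), seed=8))
        assert pers_score(ts) == 0.5

    def test_scheduled_030_exact(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=3, jitter_sd=0.0,
                                               occupancies=(0.3,), seed=9))
        assert pers_score(ts) == 0.3

    def test_no_initial_bonds_rejected(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=1, jitter_sd=0.0, seed=10))
        ts.reference[ts.topology.acceptor] += 10.0  # break the reference bond
        with pytest.raises(ValueError, match="no protein-ligand"):
            pers_score(ts)

    def test_window_longer_than_trajectory_rejected(self):
        ts = gen_trajectory_set(TrajectorySpec(n_replicates=1, n_frames=10,
                                               jitter_sd=0.0, seed=11))
        with pytest.raises(ValueError, match="window"):
            pers_score(ts, final_window=5.0)

    @settings(max_examples=15, deadline=None)
    @given(
        occ=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=3),
        seed=st.integers(0, 1000),
    )
    def test_always_in_unit_interval(self, occ, seed):
        ts = gen_trajectory_set(
            TrajectorySpec(n_replicates=1, n_frames=40, jitter_sd=0.0,
                           occupancies=tuple(occ), seed=seed)
        )
        assert 0.0 <= pers_score(ts) <= 1.0

    def test_invariant_to_global_rigid_motion(self):
        spec = TrajectorySpec(n_replicates=1, jitter_sd=0.0, occupancies=(0.3,), seed=12)
        ts = gen_trajectory_set(spec)
        base = pers_score(ts)
        rot = Rotation.from_euler("x", 70, degrees=True).as_matrix()
        ts2 = gen_trajectory_set(spec)
        ts2.reference = ts2.reference @ rot.T + 4.0
        ts2.replicates = [r @ rot.T + 4.0 for r in ts2.replicates]
        assert pers_score(ts2) == base
        # pose_score is likewise rigid-motion invariant
        assert pose_score(ts2) == pytest.approx(pose_score(ts), abs=1e-8)


class TestSelection:
    def _result(self, pose, pers):
        return PoseStabilityResult(label="", pose_score=pose, pers_score=pers,
                                   rmsd_series=[], initial_hbonds=[])

    def test_lower_pose_score_wins(self):
        best, _ = select_stable_pose(
            [("A", self._result(0.8, 0.9)), ("B", self._result(2.5, 0.2))]
        )
        assert best == "A"

    def test_single_candidate(self):
        best, _ = select_stable_pose([("only", self._result(1.0, 0.5))])
        assert best == "only"

    def test_pers_breaks_pose_ties(self):
        best, _ = select_stable_pose(
            [("low", self._result(1.0, 0.4)), ("high", self._result(1.0, 0.7))]
        )
        assert best == "high"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_stable_pose([])


class TestFileRoundTrip:
    def test_pdb_round_trip_preserves_scores(self, tmp_path):
        from vsfunnel.pose_stability import load_trajectory_set
        from vsfunnel.synthetic_data import write_trajectory_files

        spec = TrajectorySpec(n_replicates=2, n_frames=30, jitter_sd=0.0,
                              occupancies=(0.5,), seed=13)
        ts = gen_trajectory_set(spec)
        paths = write_trajectory_files(ts, tmp_path, dt_ns=spec.dt_ns)
        back = load_trajectory_set(
            paths["topology"], paths["replicates"], paths["reference"],
            paths["roles"], dt_ns=spec.dt_ns,
        )
        # PDB stores 3 decimals; scores agree to that precision
        assert pose_score(back) == pytest.approx(pose_score(ts), abs=1e-2)
        assert pers_score(back) == pers_score(ts)
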