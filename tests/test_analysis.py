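"""Analysis operators against independent brute-force oracles."""

import numpy as np
import pytest

from sumd.constants import KB
from sumd.analysis import (
    HBondCriteria,
    detect_contacts,
    detect_hbonds,
    energy_landscape,
    persistency,
    rmsd,
    superpose,
    water_occupancy,
)
from sumd.engine import Frame, Trajectory, ValidationError


def _quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's quaternion method for the optimal
    rigid superposition RMSD."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    n = mobile.shape[0]
    msd = (np.sum(m ** 2) + np.sum(r ** 2) - 2 * lam) / n
    return np.sqrt(max(msd, 0.0))


class TestSuperpose:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(8, 3))
        rot, trans, val = superpose(pts, pts)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0.0, atol=1e-10)
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation
        pts = rng.normal(size=(10, 3))
        true_rot = Rotation.from_euler("zyx", [0.4, -1.2, 2.5]).as_matrix()
        true_trans = np.array([3.0, -7.0, 1.5])
        moved = pts @ true_rot.T + true_trans
        rot, trans, val = superpose(moved, pts)
        assert val < 1e-10
        assert np.allclose(rot @ true_rot, np.eye(3), atol=1e-8)
        assert np.allclose(moved @ rot.T + trans, pts, atol=1e-8)

    def test_rotation_is_proper(self, rng):
        for _ in range(10):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            rot, _, _ = superpose(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quaternion_oracle_on_random_clouds(self, rng):
        for _ in range(25):
            a = rng.normal(size=(10, 3)) * 5
            b = rng.normal(size=(10, 3)) * 5
            _, _, val = superpose(a, b)
            assert val == pytest.approx(_quaternion_superpose_rmsd(a, b),
                                        abs=1e-9)

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValidationError, match="degenerate|collinear"):
            superpose(line, line + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            superpose(np.zeros((2, 3)), np.ones((2, 3)))


class TestRmsd:
    def test_identical_is_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        assert rmsd(pts, pts) == 0.0

    def test_single_displaced_particle_no_fit(self):
        a = np.zeros((1, 3))
        b = np.array([[2.0, 0.0, 0.0]])
        assert rmsd(a, b) == pytest.approx(2.0)

    def test_two_point_hand_computation(self):
        a = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        b = np.array([[0.0, 3.0, 0.0], [1.0, 0.0, 4.0]])
        # deviations 3 and 4: sqrt((9 + 16)/2)
        assert rmsd(a, b) == pytest.approx(np.sqrt(12.5))

    def test_symmetric_with_fit(self, rng):
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        assert rmsd(a, b, fit=True) == pytest.approx(rmsd(b, a, fit=True),
                                                     abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestDetectContacts:
    def test_strict_boundary_semantics(self):
        coords = np.array([[0.0, 0, 0], [3.49, 0, 0], [7.0, 0, 0]])
        assert detect_contacts(coords, [0], [1]) == {(0, 1)}
        coords[1, 0] = 3.50
        assert detect_contacts(coords, [0], [1]) == set()

    def test_empty_group_gives_empty_set(self, rng):
        coords = rng.normal(size=(5, 3))
        assert detect_contacts(coords, [], [0, 1]) == set()

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValidationError):
            detect_contacts(np.zeros((3, 3)), [0, 1], [1, 2])

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(-8, 8, size=(100, 3))
        a, b = list(range(50)), list(range(50, 100))
        expected = {(i, j) for i in a for j in b
                    if np.linalg.norm(coords[i] - coords[j]) < 3.5}
        assert detect_contacts(coords, a, b) == expected


class TestDetectHbonds:
    def test_ideal_collinear_geometry(self):
        # D at origin, H 1 A along x, A 2.9 A from D: angle 180 deg
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        found = detect_hbonds(coords, {1: 0}, [2])
        assert found == [(0, 1, 2)]

    def test_distance_failure(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.6, 0, 0]])
        assert detect_hbonds(coords, {1: 0}, [2]) == []

    def test_angle_failure(self):
        # D-A 3.0 A but the D-H...A angle is ~100 deg
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        angle = np.radians(100.0)
        a = h + 3.0 * np.array([np.cos(angle), np.sin(angle), 0.0])
        coords = np.vstack([d, h, a])
        assert np.linalg.norm(a - d) <= 3.5  # fails on angle, not distance
        assert detect_hbonds(coords, {1: 0}, [2]) == []

    def test_boundary_values_included(self):
        # exactly 3.5 A and exactly 120 deg both pass (<=, >=)
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        # H->D points along -x, so an acceptor 60 deg from +x makes
        # the D-H...A angle exactly 120 deg
        direction = np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 0])
        a_at = h + direction * 2.8
        coords = np.vstack([d, h, a_at])
        crit = HBondCriteria(distance=float(np.linalg.norm(a_at - d)),
                             angle=120.0)
        assert detect_hbonds(coords, {1: 0}, [2], crit) == [(0, 1, 2)]

    def test_hydrogen_without_donor_rejected(self):
        with pytest.raises(ValidationError):
            detect_hbonds(np.zeros((2, 3)), {0: 5}, [1])


class TestPersistency:
    @staticmethod
    def _traj(coord_list):
        return Trajectory(frames=[Frame(time=float(t), coords=c)
                                  for t, c in enumerate(coord_list)])

    def test_always_present_is_100_percent(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        traj = self._traj([coords, coords + 0.1])
        table = persistency([traj], lambda c: {1})
        assert table.loc[0, "percent"] == 100.0

    def test_one_of_four_merged_frames_is_25_percent(self):
        c = np.zeros((2, 3))
        t1 = self._traj([c, c])
        t2 = self._traj([c, c])
        calls = iter([set(), {7}, set(), set()])
        table = persistency([t1, t2], lambda coords: next(calls))
        assert table.loc[0, "id"] == 7
        assert table.loc[0, "percent"] == 25.0
        assert table.loc[0, "n_frames_total"] == 4

    def test_matches_brute_force_recount(self, rng):
        # random synthetic interaction schedule keyed by frame content
        n_frames, n_ids = 40, 6
        schedule = rng.random((n_frames, n_ids)) < 0.3
        coords_list = [np.full((2, 3), float(i)) for i in range(n_frames)]

        def extractor(coords):
            i = int(coords[0, 0])
            return set(np.flatnonzero(schedule[i]))

        traj = self._traj(coords_list)
        table = persistency([traj], extractor).set_index("id")
        for rid in range(n_ids):
            expected = 100.0 * schedule[:, rid].sum() / n_frames
            if expected == 0:
                assert rid not in table.index
            else:
                assert table.loc[rid, "percent"] == pytest.approx(expected)

    def test_invariant_to_replica_order_and_concatenation(self, rng):
        n_ids = 4
        schedules = [rng.random((5, n_ids)) < 0.4 for _ in range(3)]

        def make_traj(schedule, offset):
            coords = [np.full((2, 3), float(offset + i))
                      for i in range(len(schedule))]
            return self._traj(coords)

        full = np.vstack(schedules)

        def extractor(coords):
            i = int(coords[0, 0])
            return set(np.flatnonzero(full[i]))

        trajs = [make_traj(s, off) for s, off in
                 zip(schedules, [0, 5, 10])]
        t_fwd = persistency(trajs, extractor).set_index("id")["percent"]
        t_rev = persistency(trajs[::-1], extractor).set_index("id")["percent"]
        merged = self._traj([np.full((2, 3), float(i)) for i in range(15)])
        t_cat = persistency([merged], extractor).set_index("id")["percent"]
        assert t_fwd.equals(t_rev)
        assert t_fwd.equals(t_cat)

    def test_topology_mismatch_rejected(self):
        t1 = self._traj([np.zeros((2, 3))])
        t2 = self._traj([np.zeros((3, 3))])
        with pytest.raises(ValidationError):
            persistency([t1, t2], lambda c: set())


class TestWaterOccupancy:
    @staticmethod
    def _traj_from_solvent(positions_per_frame):
        frames = []
        for t, pos in enumerate(positions_per_frame):
            frames.append(Frame(time=float(t), coords=np.asarray(pos)))
        return Trajectory(frames=frames)

    def test_fixed_bead_fills_exactly_one_voxel(self):
        pos = [[[0.5, 0.5, 0.5]]] * 5
        traj = self._traj_from_solvent(pos)
        grid = water_occupancy([traj], [0], ([0, 0, 0], [3, 3, 3]),
                               spacing=1.0)
        assert grid.occupancy[0, 0, 0] == 1.0
        assert grid.occupancy.sum() == 1.0

    def test_half_presence_gives_half_occupancy(self):
        inside = [[0.5, 0.5, 0.5]]
        outside = [[10.0, 10.0, 10.0]]
        traj = self._traj_from_solvent([inside, outside, inside, outside])
        grid = water_occupancy([traj], [0], ([0, 0, 0], [3, 3, 3]))
        assert grid.occupancy[0, 0, 0] == 0.5

    def test_matches_brute_force_frame_loop(self, rng):
        n_frames, n_sol = 30, 8
        frames = rng.uniform(0, 6, size=(n_frames, n_sol, 3))
        traj = self._traj_from_solvent(list(frames))
        lo, hi, spacing = np.zeros(3), np.full(3, 6.0), 1.0
        grid = water_occupancy([traj], list(range(n_sol)), (lo, hi), spacing)
        dims = grid.occupancy.shape
        expected = np.zeros(dims)
        for f in range(n_frames):
            seen = set()
            for s in range(n_sol):
                idx = tuple(np.floor((frames[f, s] - lo) / spacing).astype(int))
                if all(0 <= idx[d] < dims[d] for d in range(3)):
                    seen.add(idx)
            for idx in seen:
                expected[idx] += 1
        assert np.allclose(grid.occupancy, expected / n_frames)

    def test_hit_accounting_identity(self, rng):
        # sum over voxels of occupancy*total equals the deduplicated
        # per-voxel hit count by construction
        n_frames, n_sol = 10, 5
        frames = rng.uniform(0, 4, size=(n_frames, n_sol, 3))
        traj = self._traj_from_solvent(list(frames))
        grid = water_occupancy([traj], list(range(n_sol)),
                               (np.zeros(3), np.full(3, 4.0)), 1.0)
        hits = grid.occupancy * grid.n_frames
        assert np.allclose(hits, np.round(hits))

    def test_zero_size_region_rejected(self):
        traj = self._traj_from_solvent([[[0.0, 0, 0]]])
        with pytest.raises(ValidationError):
            water_occupancy([traj], [0], ([0, 0, 0], [0, 1, 1]))

    def test_dx_export_has_grid_header(self):
        traj = self._traj_from_solvent([[[0.5, 0.5, 0.5]]])
        grid = water_occupancy([traj], [0], ([0, 0, 0], [2, 2, 2]))
        text = grid.to_dx()
        assert "gridpositions counts 2 2 2" in text
        assert "origin" in text


class TestEnergyLandscape:
    def test_single_bin_depth_zero(self):
        lmap = energy_landscape([0.1, 0.2, 0.3], [0.1, 0.2, 0.3],
                                [-1.0, -2.0, -3.0])
        occupied = lmap.count > 0
        assert occupied.sum() == 1
        assert lmap.count[occupied][0] == 3
        assert lmap.depth[occupied][0] == pytest.approx(0.0)

    def test_two_equal_bins_depth_is_kbt_ln2(self):
        temperature = 300.0
        lmap = energy_landscape([0.5, 0.5, 1.5, 1.5], [0.5] * 4,
                                [0.0] * 4, temperature=temperature)
        depths = lmap.depth[lmap.count > 0]
        assert len(depths) == 2
        assert depths[0] == pytest.approx(depths[1])
        assert depths[0] == pytest.approx(KB * temperature * np.log(2))

    def test_mean_energy_is_member_average(self):
        lmap = energy_landscape([0.2, 0.8, 1.5], [0.5, 0.5, 0.5],
                                [-2.0, -4.0, -10.0])
        occupied = np.argwhere(lmap.count > 0)
        means = sorted(lmap.mean_energy[tuple(i)] for i in occupied)
        assert means == pytest.approx([-10.0, -3.0])

    def test_empty_bins_flagged_not_zero(self):
        lmap = energy_landscape([0.5, 2.5], [0.5, 0.5], [-1.0, -1.0])
        empty = lmap.count == 0
        assert np.all(np.isnan(lmap.mean_energy[empty]))
        assert np.all(np.isnan(lmap.depth[empty]))

    def test_counts_sum_to_total(self, rng):
        cv1 = rng.uniform(0, 10, 200)
        cv2 = rng.uniform(0, 5, 200)
        e = rng.normal(size=200)
        lmap = energy_landscape(cv1, cv2, e)
        assert lmap.count.sum() == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            energy_landscape([1.0, 2.0], [1.0], [0.0, 0.0])
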