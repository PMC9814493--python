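import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import piezotraj as pt
from piezotraj.fluct import SelectionSpec


def _random_rigid(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=5.0, size=3)
    return R, t


class TestSuperpose:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        R, t, rmsd = pt.superpose(x, x)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_recovers_zero_rmsd(self, rng):
        x = rng.normal(size=(15, 3))
        R0, t0 = _random_rigid(rng)
        _, _, rmsd = pt.superpose(x @ R0.T + t0, x)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_proper_rotation(self, rng):
        x = rng.normal(size=(8, 3))
        y = rng.normal(size=(8, 3))
        R, _, _ = pt.superpose(x, y)
        assert np.linalg.det(R) == pytest.approx(1.0, rel=1e-9)

    def test_four_point_displacement_matches_numeric_oracle(self):
        ref = np.array(
            [[0.0, 0, 0], [2.0, 0, 0], [0.0, 2.0, 0], [0.0, 0, 2.0]]
        )
        mob = ref.copy()
        mob[0, 0] -= 1.0   # one atom displaced by 1 Å
        _, _, rmsd = pt.superpose(mob, ref)

        # independent oracle: minimise RMSD over Euler angles + translation
        def objective(params):
            Rm = Rotation.from_euler("xyz", params[:3]).as_matrix()
            moved = mob @ Rm.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12,
                              "maxiter": 20_000}).fun
            for x0 in (
                np.zeros(6),
                np.array([0.3, -0.2, 0.1, 0.5, -0.5, 0.25]),
                np.array([-0.4, 0.6, -0.3, 0.0, 0.3, -0.2]),
            )
        )
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_too_few_or_collinear_atoms(self):
        with pytest.raises(ValueError):
            pt.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            pt.superpose(line, line)

    def test_invariance_to_rigid_motion_of_mobile(self, rng):
        x = rng.normal(size=(20, 3))
        y = x + rng.normal(scale=0.3, size=x.shape)
        _, _, rmsd0 = pt.superpose(y, x)
        for _ in range(5):
            R0, t0 = _random_rigid(rng)
            _, _, rmsd = pt.superpose(y @ R0.T + t0, x)
            assert rmsd == pytest.approx(rmsd0, abs=1e-8)


def _toy_traj_from_frames(frames):
    n_atoms = frames[0].shape[0]
    atoms = [
        pt.AtomRecord(i, name, "C", 12.011, 0, "ALA", "A")
        for i, name in enumerate(["N", "CA", "C", "O", "CB"][:n_atoms])
    ]
    topo = pt.Topology(atoms=atoms, residues=[pt.Residue("ALA", 1, "A")])
    return pt.Trajectory(topo, np.array(frames), 100.0)


class TestRMSDTimeseries:
    def test_copies_of_reference_are_zero(self, rng):
        base = rng.normal(size=(5, 3))
        traj = _toy_traj_from_frames([base] * 12)
        series, mean, block_sd = pt.rmsd_timeseries(
            traj, base, SelectionSpec(1, 1), n_blocks=4
        )
        np.testing.assert_allclose(series, 0.0, atol=1e-9)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copies_are_zero(self, rng):
        base = rng.normal(size=(5, 3))
        frames = []
        for _ in range(10):
            R0, t0 = _random_rigid(rng)
            frames.append(base @ R0.T + t0)
        traj = _toy_traj_from_frames(frames)
        series, mean, _ = pt.rmsd_timeseries(traj, base, SelectionSpec(1, 1))
        np.testing.assert_allclose(series, 0.0, atol=1e-8)

    def test_two_conformer_series_matches_per_frame_values(self, rng):
        base = rng.normal(size=(5, 3))
        other = base + rng.normal(scale=0.5, size=base.shape)
        traj = _toy_traj_from_frames([base, other] * 5)
        series, mean, _ = pt.rmsd_timeseries(traj, base, SelectionSpec(1, 1))
        _, _, expected_other = pt.superpose(other, base)
        np.testing.assert_allclose(series[0::2], 0.0, atol=1e-9)
        np.testing.assert_allclose(series[1::2], expected_other, atol=1e-9)
        assert mean == pytest.approx(expected_other / 2, abs=1e-9)


def _three_residue_traj(rng, n_frames=20, amplitude=0.5):
    """Three one-atom... rather three residues of 2 heavy atoms each; the CA
    of residue 2 oscillates along x."""
    atoms = []
    residues = []
    for ri, (name, ss) in enumerate(
        [("ALA", "helix"), ("GLY", "sheet"), ("SER", "loop")]
    ):
        residues.append(pt.Residue(name, ri + 1, "A", secondary_structure=ss))
        for an in ("N", "CA"):
            atoms.append(
                pt.AtomRecord(len(atoms), an, "N" if an == "N" else "C",
                              14.0, ri, name, "A")
            )
    topo = pt.Topology(atoms=atoms, residues=residues)
    base = rng.normal(scale=3.0, size=(6, 3))
    frames = []
    for f in range(n_frames):
        x = base.copy()
        x[3, 0] += amplitude * (1 if f % 2 == 0 else -1)
        frames.append(x)
    return pt.Trajectory(topo, np.array(frames), 100.0)


class TestRMSF:
    def test_static_trajectory_is_zero(self, rng):
        traj = _three_residue_traj(rng, amplitude=0.0)
        table = pt.rmsf_per_residue(traj)
        np.testing.assert_allclose(table.per_residue["rmsf"], 0.0, atol=1e-9)

    def test_oscillating_atom_rmsf_equals_amplitude(self, rng):
        # one atom at the centroid of a rigid shell oscillates ±d along x:
        # its two-point RMSF is d (the fit absorbs only an O(1/N) share)
        d = 0.5
        n_shell = 49
        shell = rng.normal(size=(n_shell, 3))
        shell = 10.0 * shell / np.linalg.norm(shell, axis=1)[:, None]
        shell -= shell.mean(axis=0)
        atoms = []
        residues = []
        for i in range(n_shell + 1):
            residues.append(pt.Residue("GLY", i + 1, "A"))
            atoms.append(pt.AtomRecord(i, "CA", "C", 12.011, i, "GLY", "A"))
        topo = pt.Topology(atoms=atoms, residues=residues)
        frames = []
        for f in range(20):
            x = np.vstack([shell, [0.0, 0.0, 0.0]])
            x[-1, 0] += d * (1 if f % 2 == 0 else -1)
            frames.append(x)
        traj = pt.Trajectory(topo, np.array(frames), 100.0)
        table = pt.rmsf_per_residue(traj)
        row = table.per_residue.set_index("author_number").loc[n_shell + 1]
        assert row["rmsf"] == pytest.approx(d, rel=0.03)

    def test_domain_average_is_mean_of_members(self, rng):
        traj = _three_residue_traj(rng)
        table = pt.rmsf_per_residue(traj)
        for _, row in table.domain_averages.iterrows():
            members = table.per_residue[table.per_residue["ss"] == row["ss"]]
            assert row["mean_rmsf"] == pytest.approx(members["rmsf"].mean())

    def test_global_rigid_motion_invariance(self, rng):
        traj = _three_residue_traj(rng)
        base = pt.rmsf_per_residue(traj).per_residue["rmsf"].to_numpy()
        R0, t0 = _random_rigid(rng)
        moved = pt.Trajectory(
            traj.topology, traj.coords @ R0.T + t0, traj.frame_interval
        )
        out = pt.rmsf_per_residue(moved).per_residue["rmsf"].to_numpy()
        np.testing.assert_allclose(out, base, atol=1e-9)

    def test_tail_exclusion_from_domain_averages(self, rng):
        traj = _three_residue_traj(rng)
        full = pt.rmsf_per_residue(traj)
        trimmed = pt.rmsf_per_residue(traj, exclude_from_domains=(2,))
        assert "sheet" in set(full.domain_averages["ss"])
        assert "sheet" not in set(trimmed.domain_averages["ss"])


class TestCorePairDistances:
    def test_pair_count_combinatorics(self, toy_trajectory):
        table = pt.core_pair_distances(toy_trajectory)
        n = len(toy_trajectory.topology.hydrophobic_core)
        assert table.shape[1] == n * (n - 1) // 2

    def test_scripted_distances(self, toy_system):
        topo, trajs, truth = toy_system
        traj = trajs[pt.ConditionLabel(308.0, 1.0)]
        table = pt.core_pair_distances(traj)
        col = table["L5-V6"]
        assert col.iloc[0] == pytest.approx(truth["contact_distance_close"])
        assert col.iloc[-1] == pytest.approx(truth["contact_distance_far"])
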