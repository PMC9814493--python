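import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import piezotraj as pt
from piezotraj import hbonds


class TestFrameCriterion:
    # acceptor O at origin, antecedent C along +x; H along -x at distance r
    def _triple(self, r, theta_deg):
        th = np.deg2rad(theta_deg)
        h = r * np.array([np.cos(th), np.sin(th), 0.0])
        return h, np.zeros(3), np.array([1.23, 0.0, 0.0])

    @pytest.mark.parametrize(
        "r,theta,expected",
        [
            (2.0, 150.0, True),    # both criteria met
            (2.5, 150.0, False),   # distance fails at the 2.4 Å cutoff
            (2.0, 95.0, False),    # angle fails at the 100 degree minimum
            (2.4, 100.0, True),    # boundary values count as bonded
        ],
    )
    def test_criterion_boundaries(self, r, theta, expected):
        bonded, r_out, theta_out = pt.frame_hbond(*self._triple(r, theta))
        assert bonded is expected
        assert r_out == pytest.approx(r)
        assert theta_out == pytest.approx(theta)

    def test_geometry_returned_even_when_unbonded(self):
        bonded, r, theta = pt.frame_hbond(*self._triple(5.0, 170.0))
        assert not bonded
        assert r == pytest.approx(5.0)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pt.frame_hbond(np.zeros(3), np.zeros(3), np.array([1.0, 0, 0]))


class TestMergedSeries:
    def test_alternating_equivalent_hydrogens_merge_to_one_event(
        self, toy_system, toy_trajectory
    ):
        topo, _, _ = toy_system
        cand = {c.label: c for c in hbonds.enumerate_candidates(topo)}["K2-D3"]
        merged = hbonds.merged_series(toy_trajectory, cand)
        assert merged.occupancy == 1.0
        events, record = pt.extract_events(merged)
        assert record.n_events == 1
        members = hbonds.member_occupancies(toy_trajectory, cand)
        assert members.max() == 0.5

    def test_singleton_groups_equal_plain_detection(self, toy_system, toy_trajectory):
        topo, _, _ = toy_system
        cand = {c.label: c for c in hbonds.enumerate_candidates(topo)}["R1-G4"]
        merged = hbonds.merged_series(toy_trajectory, cand)
        # only HE is ever scripted near the acceptor: OR adds nothing
        members = hbonds.member_occupancies(toy_trajectory, cand)
        assert members.sum() == pytest.approx(merged.occupancy)

    def test_merged_occupancy_bounds_members(self, toy_system, toy_trajectory):
        topo, _, _ = toy_system
        for cand in hbonds.enumerate_candidates(topo):
            merged = hbonds.merged_series(toy_trajectory, cand)
            members = hbonds.member_occupancies(toy_trajectory, cand)
            assert merged.occupancy >= members.max() - 1e-12

    def test_occupancy_monotone_in_thresholds(self, toy_system, toy_trajectory):
        topo, _, _ = toy_system
        cand = {c.label: c for c in hbonds.enumerate_candidates(topo)}["R1-G4"]
        occ = lambda rc, tm: hbonds.merged_series(
            toy_trajectory, cand, r_cut=rc, theta_min=tm
        ).occupancy
        assert occ(2.4, 100.0) >= occ(1.9, 100.0)
        assert occ(2.4, 100.0) >= occ(2.4, 170.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_or_merge_vs_bruteforce_member_oracle(self, data):
        n_members = data.draw(st.integers(1, 4))
        n_frames = data.draw(st.integers(1, 30))
        members = np.array(
            [
                data.draw(
                    st.lists(st.booleans(), min_size=n_frames, max_size=n_frames)
                )
                for _ in range(n_members)
            ]
        )
        merged = members.any(axis=0)
        # brute-force per-member occupancies
        assert merged.mean() >= max(m.mean() for m in members)
        assert merged.mean() <= sum(m.mean() for m in members) + 1e-12


class TestEvents:
    def _series(self, bits, interval=100.0):
        return pt.BondedSeries(np.array(bits, bool), interval)

    def test_run_length_arithmetic(self):
        events, record = pt.extract_events(self._series([1, 1, 1, 0, 1]))
        assert [e.lifetime for e in events] == pytest.approx([0.3, 0.1])
        assert record.effective_occupancy == pytest.approx(0.8)
        assert record.n_events == 2

    def test_all_false_gives_no_events(self):
        events, record = pt.extract_events(self._series([0, 0, 0]))
        assert events == []
        assert record.effective_occupancy == 0.0

    def test_constant_bond_is_single_long_event(self):
        events, record = pt.extract_events(self._series([1] * 10_000))
        assert record.n_events == 1
        assert events[0].lifetime == pytest.approx(1000.0)   # ns
        assert record.lifetime_bin_counts == (0, 0, 1)       # (100, inf) bin

    def test_gap_tolerance_bridges_single_gaps(self):
        series = self._series([1, 1, 0, 1, 1])
        assert pt.extract_events(series)[1].n_events == 2
        events, record = pt.extract_events(series, gap_tolerance=1)
        assert record.n_events == 1
        assert events[0].lifetime == pytest.approx(0.5)
        # occupancy still counts only bonded frames
        assert record.effective_occupancy == pytest.approx(0.8)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        bits=st.lists(st.booleans(), min_size=1, max_size=200),
        interval=st.sampled_from([10.0, 100.0, 250.0]),
    )
    def test_lifetime_sum_equals_occupancy_times_duration(self, bits, interval):
        series = self._series(bits, interval)
        events, record = pt.extract_events(series)
        total_ns = sum(e.lifetime for e in events)
        window_ns = len(bits) * interval / 1000.0
        assert total_ns == pytest.approx(
            record.effective_occupancy * window_ns, abs=1e-9
        )


class TestLifetimeHistogram:
    def _events(self, lifetimes_ns):
        return [pt.Event(0, 0, lt) for lt in lifetimes_ns]

    def test_one_event_per_bin(self):
        counts = pt.lifetime_histogram(self._events([0.3, 7.0, 150.0]))
        assert counts == (1, 1, 1)

    def test_empty_event_list(self):
        assert pt.lifetime_histogram([]) == (0, 0, 0)

    def test_right_closed_boundary(self):
        # 6 ns falls in the short bin (0, 6]; 100 ns in (6, 100]
        assert pt.lifetime_histogram(self._events([6.0])) == (1, 0, 0)
        assert pt.lifetime_histogram(self._events([100.0])) == (0, 1, 0)

    def test_water_bins_highlight_under_4ns(self):
        counts = pt.lifetime_histogram(
            self._events([3.9, 4.0, 4.1]), hbonds.WATER_LIFETIME_BINS_NS
        )
        assert counts == (2, 1, 0)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pt.lifetime_histogram([], ((0.0, 6.0), (5.0, 100.0)))


class TestWaterBridges:
    def test_scripted_bridge_identity(self, toy_system):
        topo, trajs, truth = toy_system
        traj = trajs[pt.ConditionLabel(308.0, 1.0)]
        series = pt.water_bridge_series(traj, (0, 3))
        assert series.occupancy == pytest.approx(truth["bridge_occupancy_R1_G4"])

    def test_single_link_is_not_a_bridge(self, toy_system):
        # Lys2/Asp3 have no scripted water nearby: no bridge at all
        topo, trajs, _ = toy_system
        traj = trajs[pt.ConditionLabel(308.0, 1.0)]
        series = pt.water_bridge_series(traj, (1, 2))
        assert series.occupancy == 0.0

    def test_no_waters_errors(self, toy_trajectory):
        topo = toy_trajectory.topology
        dry = pt.Topology(
            atoms=topo.atoms,
            residues=[
                pt.Residue(r.name, r.author_number, r.chain,
                           r.secondary_structure, is_solvent=False)
                for r in topo.residues
            ],
            donor_groups=topo.donor_groups,
            acceptor_groups=topo.acceptor_groups,
            hydrophobic_core=topo.hydrophobic_core,
        )
        traj = pt.Trajectory(dry, toy_trajectory.coords,
                             toy_trajectory.frame_interval)
        with pytest.raises(ValueError, match="no water"):
            pt.water_bridge_series(traj, (0, 3))

    def test_any_water_semantics_spans_water_exchange(self):
        """A bridge event survives the bridging water changing identity."""
        # two waters alternately occupy the same bridging site between a
        # donor-only residue and an acceptor-only residue
        atoms = []
        residues = []

        def add_res(name, num, names_els, solvent=False):
            res_idx = len(residues)
            residues.append(pt.Residue(name, num, "A", is_solvent=solvent))
            for n, el in names_els:
                atoms.append(
                    pt.AtomRecord(len(atoms), n, el,
                                  {"H": 1.008, "N": 14.007, "O": 15.999,
                                   "C": 12.011}[el], res_idx, name, "A")
                )

        add_res("LYS", 1, [("NZ", "N"), ("HZ1", "H")])
        add_res("GLY", 2, [("C", "C"), ("O", "O")])
        add_res("HOH", 3, [("O", "O"), ("H1", "H"), ("H2", "H")], solvent=True)
        add_res("HOH", 4, [("O", "O"), ("H1", "H"), ("H2", "H")], solvent=True)
        topo = pt.Topology(atoms=atoms, residues=residues)
        topo.donor_groups.append(pt.DonorGroup(0, 0, (1,)))
        topo.acceptor_groups.append(pt.AcceptorGroup(1, (3,), {3: 2}))

        far = np.array([50.0, 50.0, 50.0])
        site = {
            "GLY_C": [1.23, 0.0, 0.0], "GLY_O": [0.0, 0.0, 0.0],
            "W_O": [-2.33, 0.0, 2.83],
        }
        w_o = np.array(site["W_O"])
        u = w_o / np.linalg.norm(w_o)
        w_h1 = 2.0 * u                 # donates to GLY O
        res_h = w_o + 2.0 * u          # LYS hydrogen donating to water O
        coords = np.empty((2, len(atoms), 3))
        for f, bridging_water in enumerate([2, 3]):   # residue indices
            frame = {
                0: res_h + [0, 0, 1.0],   # NZ parked near its H
                1: res_h,
                2: site["GLY_C"], 3: site["GLY_O"],
            }
            for wi, base in ((2, 4), (3, 7)):
                if wi == bridging_water:
                    frame[base] = w_o
                    frame[base + 1] = w_h1
                    frame[base + 2] = w_o + [0.0, 0.96, 0.0]
                else:
                    frame[base] = far
                    frame[base + 1] = far + [0.6, 0.6, 0]
                    frame[base + 2] = far + [-0.6, 0.6, 0]
            for idx, pos in frame.items():
                coords[f, idx] = pos
        traj = pt.Trajectory(topo, coords, 100.0)
        series = pt.water_bridge_series(traj, (0, 1))
        np.testing.assert_array_equal(series.indicator, [True, True])
        _, record = pt.extract_events(series)
        assert record.n_events == 1


class TestHydrophobicContacts:
    def test_contact_threshold(self, toy_system):
        topo, trajs, truth = toy_system
        traj = trajs[pt.ConditionLabel(308.0, 1.0)]
        series, dist = pt.hydrophobic_contact_series(traj, (4, 5))
        assert series.indicator[0]            # 3.4 Å: contact
        assert not series.indicator[-1]       # 5.0 Å: no contact
        assert series.occupancy == truth["contact_occupancy_L5_V6"]

    def test_mass_center_hand_computation(self):
        # two equal-mass atoms at x=0 and x=2: center at x=1
        atoms = [
            pt.AtomRecord(0, "CB", "C", 12.0, 0, "LEU", "A"),
            pt.AtomRecord(1, "CG", "C", 12.0, 0, "LEU", "A"),
        ]
        topo = pt.Topology(atoms=atoms, residues=[pt.Residue("LEU", 1, "A")])
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 2.0
        traj = pt.Trajectory(topo, coords, 100.0)
        center = hbonds._mass_center_series(traj, [0, 1])
        np.testing.assert_allclose(center[0], [1.0, 0.0, 0.0])

    def test_weighted_center_three_atom_oracle(self):
        atoms = [
            pt.AtomRecord(0, "CB", "C", 12.0, 0, "X", "A"),
            pt.AtomRecord(1, "OG", "O", 16.0, 0, "X", "A"),
            pt.AtomRecord(2, "CG", "C", 12.0, 0, "X", "A"),
        ]
        topo = pt.Topology(atoms=atoms, residues=[pt.Residue("X", 1, "A")])
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]]])
        traj = pt.Trajectory(topo, coords, 100.0)
        center = hbonds._mass_center_series(traj, [0, 1, 2])
        # (12*0 + 16*1 + 12*3) / 40 = 1.3
        assert center[0, 0] == pytest.approx(1.3)

    def test_water_bridged_contact(self, toy_system):
        topo, trajs, truth = toy_system
        traj = trajs[pt.ConditionLabel(308.0, 1.0)]
        series = pt.water_bridged_contact_series(traj, (4, 5))
        assert series.occupancy == truth["bridged_contact_occupancy_L5_V6"]

    def test_empty_selection_errors(self, toy_trajectory):
        with pytest.raises(ValueError):
            pt.hydrophobic_contact_series(toy_trajectory, (0, 5))
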