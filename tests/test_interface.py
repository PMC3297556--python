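"""Hydrogen-bond and contact detection, checked against brute-force oracles."""

import numpy as np
import pytest

from tcrdyn.interface import (
    AtomRef,
    HBondCriteria,
    HBondSeries,
    assign_donors_acceptors,
    contacts_in_frame,
    greek_atom_label,
    hbond_series,
    hbonds_in_frame,
    salt_bridge_flag,
)
from tcrdyn.model_io import AtomRecord, Selection, Topology, Trajectory, infer_h_attachment
from tcrdyn.synthetic import HBondSchedule, gen_hbond_system

from .conftest import random_rotation
from .oracles import bruteforce_hbond_series, random_hbond_world


def _topology(specs):
    """specs: list of (name, element, res_name, res_seq, chain)."""
    atoms = [
        AtomRecord(serial=i + 1, name=n, element=e, res_name=rn, res_seq=rs, chain_id=c)
        for i, (n, e, rn, rs, c) in enumerate(specs)
    ]
    return Topology(atoms=atoms)


class TestCriteria:
    def test_defaults(self):
        c = HBondCriteria()
        assert c.d_max == 3.5
        assert c.theta_min == 150.0

    @pytest.mark.parametrize("kwargs", [{"d_max": 0.0}, {"d_max": -1.0},
                                        {"theta_min": 0.0}, {"theta_min": 181.0}])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            HBondCriteria(**kwargs)


class TestAssignDonorsAcceptors:
    def test_backbone_amide_is_donor(self):
        top = _topology([("N", "N", "ALA", 1, "A"), ("H", "H", "ALA", 1, "A")])
        top.h_attachment = {1: 0}
        donors, _ = assign_donors_acceptors(top)
        assert donors == [(0, [1])]

    def test_gln_sidechain_oe1_is_acceptor(self):
        top = _topology([("OE1", "O", "GLN", 7, "A")])
        _, acceptors = assign_donors_acceptors(top)
        assert acceptors == [0]

    def test_proline_backbone_n_never_donor(self):
        top = _topology([("N", "N", "PRO", 2, "A"), ("H", "H", "PRO", 2, "A")])
        top.h_attachment = {1: 0}
        donors, _ = assign_donors_acceptors(top)
        assert donors == []
        # ...even in hydrogen-free potential-donor mode
        top2 = _topology([("N", "N", "PRO", 2, "A")])
        donors2, _ = assign_donors_acceptors(top2, include_potential_donors=True)
        assert donors2 == []

    def test_backbone_o_is_acceptor_carbon_is_not(self):
        top = _topology([("O", "O", "GLY", 1, "A"), ("C", "C", "GLY", 1, "A")])
        _, acceptors = assign_donors_acceptors(top)
        assert acceptors == [0]

    def test_his_both_ring_nitrogens_acceptors(self):
        top = _topology([("ND1", "N", "HIS", 29, "A"), ("NE2", "N", "HIS", 29, "A")])
        _, acceptors = assign_donors_acceptors(top)
        assert acceptors == [0, 1]


def _dha_frame(distance, angle_deg):
    """Donor N at origin, H at (1,0,0), acceptor at `distance` from donor
    making `angle_deg` at the hydrogen."""
    u = np.array([np.cos(np.radians(180 - angle_deg)), np.sin(np.radians(180 - angle_deg)), 0.0])
    h = np.array([1.0, 0.0, 0.0])
    b = 2 * np.dot(h, u)
    c = 1 - distance**2
    r = (-b + np.sqrt(b * b - 4 * c)) / 2
    acceptor = h + r * u
    return np.array([[0.0, 0, 0], h, acceptor])


class TestHbondsInFrame:
    def setup_method(self):
        self.donors = [(0, [1])]
        self.acceptors = [2]
        self.criteria = HBondCriteria()

    def _detect(self, distance, angle):
        frame = _dha_frame(distance, angle)
        return hbonds_in_frame(frame, self.donors, self.acceptors, self.criteria)

    def test_inside_both_cutoffs_formed(self):
        assert self._detect(2.9, 165.0) == {(0, 1, 2)}

    def test_each_cutoff_binds_independently(self):
        assert self._detect(3.6, 180.0) == set()  # distance fails
        assert self._detect(2.9, 149.0) == set()  # angle fails

    def test_boundaries_inclusive(self):
        assert self._detect(3.5, 150.0) == {(0, 1, 2)}

    def test_monotone_in_criteria(self):
        # tightening the criteria never adds a bond
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.uniform(2.0, 5.0)
            a = rng.uniform(120.0, 180.0)
            frame = _dha_frame(d, a)
            loose = hbonds_in_frame(frame, self.donors, self.acceptors, HBondCriteria(3.5, 150.0))
            tight = hbonds_in_frame(frame, self.donors, self.acceptors, HBondCriteria(3.2, 160.0))
            assert tight <= loose

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        frame = _dha_frame(3.1, 158.0)
        base = hbonds_in_frame(frame, self.donors, self.acceptors, self.criteria)
        for _ in range(10):
            R = random_rotation(rng)
            moved = frame @ R.T + rng.standard_normal(3) * 20
            assert hbonds_in_frame(moved, self.donors, self.acceptors, self.criteria) == base

    def test_distance_only_mode_waives_angle(self):
        frame = _dha_frame(3.0, 120.0)  # angle would fail
        got = hbonds_in_frame(frame, [(0, [])], self.acceptors, self.criteria, distance_only=True)
        assert got == {(0, None, 2)}


class TestHbondSeries:
    def test_scripted_schedule_is_reproduced(self):
        schedule = HBondSchedule.from_frames(1, 101, range(60), 100)
        traj = gen_hbond_system([schedule], 100)
        series = hbond_series(traj, Selection.make(chains=["A"]), Selection.make(chains=["B"]))
        assert len(series) == 1
        np.testing.assert_array_equal(series[0].formed, np.array(schedule.formed))
        assert series[0].n_formed == 60

    def test_two_independent_schedules(self):
        s1 = HBondSchedule.from_frames(1, 101, range(0, 30), 80)
        s2 = HBondSchedule.from_frames(2, 102, range(40, 80), 80)
        traj = gen_hbond_system([s1, s2], 80)
        series = hbond_series(traj, Selection.make(chains=["A"]), Selection.make(chains=["B"]))
        assert len(series) == 2
        by_donor = {s.donor.res_seq: s for s in series}
        np.testing.assert_array_equal(by_donor[1].formed, np.array(s1.formed))
        np.testing.assert_array_equal(by_donor[2].formed, np.array(s2.formed))

    def test_all_off_schedule_reports_nothing(self):
        schedule = HBondSchedule.from_frames(1, 101, [], 50)
        traj = gen_hbond_system([schedule], 50)
        series = hbond_series(traj, Selection.make(chains=["A"]), Selection.make(chains=["B"]))
        assert series == []

    def test_far_apart_groups_empty(self):
        specs = [("N", "N", "GLY", 1, "A"), ("H", "H", "GLY", 1, "A"),
                 ("O", "O", "GLY", 2, "B")]
        top = _topology(specs)
        coords = np.array([[[0.0, 0, 0], [1, 0, 0], [50, 0, 0]]])
        traj = Trajectory(top, coords)
        top.h_attachment = infer_h_attachment(top, coords[0])
        series = hbond_series(traj, Selection.make(chains=["A"]), Selection.make(chains=["B"]))
        assert series == []

    def test_overlapping_groups_error(self):
        traj = gen_hbond_system([HBondSchedule.from_frames(1, 101, [0], 2)], 2)
        everything = Selection.make()
        with pytest.raises(ValueError, match="disjoint"):
            hbond_series(traj, everything, Selection.make(chains=["B"]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_oracle_on_random_system(self, seed):
        traj, sel_a, sel_b = random_hbond_world(seed, n_heavy=40, n_frames=12)
        series = hbond_series(traj, sel_a, sel_b, merge_equivalent=False)
        got = {
            (s.donor.index, s.acceptor.index): s.formed.copy() for s in series
        }
        expected = bruteforce_hbond_series(traj, sel_a, sel_b)
        assert set(got) == set(expected)
        for key in expected:
            np.testing.assert_array_equal(got[key], expected[key])

    def test_equivalent_atom_merging(self):
        # Arg NH1/NH2 donating to the same acceptor in different frames merges
        specs = [
            ("NH1", "N", "ARG", 62, "A"), ("HH1", "H", "ARG", 62, "A"),
            ("NH2", "N", "ARG", 62, "A"), ("HH2", "H", "ARG", 62, "A"),
            ("OD1", "O", "ASP", 56, "B"),
        ]
        top = _topology(specs)
        far = np.array([8.0, 0, 0])
        # frame 0: NH1 bonds; frame 1: NH2 bonds; frame 2: neither
        fr0 = np.array([[0.0, 0, 0], [1, 0, 0], far, far + [1, 0, 0], [2.9, 0, 0]])
        fr1 = np.array([far, far + [1, 0, 0], [0.0, 0, 0], [1, 0, 0], [2.9, 0, 0]])
        fr2 = np.array([far, far + [1, 0, 0], -far, -far + [1, 0, 0], [30.0, 0, 0]])
        traj = Trajectory(top, np.stack([fr0, fr1, fr2]))
        top.h_attachment = {1: 0, 3: 2}
        series = hbond_series(traj, Selection.make(chains=["A"]), Selection.make(chains=["B"]))
        assert len(series) == 1
        s = series[0]
        assert s.donor.atom_name == "NH1/2"
        assert s.acceptor.atom_name == "OD1/2"
        np.testing.assert_array_equal(s.formed, [True, True, False])
        assert s.donor.label() == "Arg62^Nη1/2^"


class TestContacts:
    def _two_residue_frame(self, gap):
        specs = [("CA", "C", "ALA", 1, "A"), ("CB", "C", "ALA", 1, "A"),
                 ("CA", "C", "ALA", 2, "B")]
        top = _topology(specs)
        frame = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5 + gap, 0, 0]])
        return top, frame

    def test_contact_inside_cutoff(self):
        top, frame = self._two_residue_frame(3.8)
        got = contacts_in_frame(frame, top, np.array([0, 1]), np.array([2]), cutoff=4.0)
        assert (("A", 1, ""), ("B", 2, "")) in got
        assert got[(("A", 1, ""), ("B", 2, ""))] == pytest.approx(3.8)

    def test_no_contact_outside_cutoff(self):
        top, frame = self._two_residue_frame(4.2)
        got = contacts_in_frame(frame, top, np.array([0, 1]), np.array([2]), cutoff=4.0)
        assert got == {}

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(12)
        n = 30
        specs = [("CA", "C", "ALA", i + 1, "A" if i < 15 else "B") for i in range(n)]
        top = _topology(specs)
        frame = rng.uniform(0, 15, size=(n, 3))
        ga, gb = np.arange(15), np.arange(15, 30)
        got = set(contacts_in_frame(frame, top, ga, gb, cutoff=4.0))
        expected = set()
        for i in ga:
            for j in gb:
                if np.linalg.norm(frame[i] - frame[j]) <= 4.0:
                    expected.add((top.residue_of(int(i)), top.residue_of(int(j))))
        assert got == expected


class TestSaltBridge:
    def _series(self, d_res, d_atom, a_res, a_atom):
        return HBondSeries(
            donor=AtomRef("A", 62, d_res, d_atom),
            acceptor=AtomRef("B", 56, a_res, a_atom),
            formed=np.array([True]),
        )

    def test_arg_to_asp(self):
        assert salt_bridge_flag(self._series("ARG", "NH1", "ASP", "OD1"))
        assert salt_bridge_flag(self._series("ARG", "NH1/2", "ASP", "OD1/2"))

    def test_lys_to_glu(self):
        assert salt_bridge_flag(self._series("LYS", "NZ", "GLU", "OE2"))

    def test_backbone_pair_is_not(self):
        assert not salt_bridge_flag(self._series("GLY", "N", "ALA", "O"))

    def test_symmetric_direction(self):
        assert salt_bridge_flag(self._series("ASP", "OD2", "ARG", "NH2"))


def test_greek_atom_labels():
    assert greek_atom_label("OD1") == "Oδ1"
    assert greek_atom_label("NE2") == "Nε2"
    assert greek_atom_label("NH1/2") == "Nη1/2"
    assert greek_atom_label("OG") == "Oγ"
    assert greek_atom_label("NZ") == "Nζ"
    assert greek_atom_label("CA") == "CA"  # no remoteness rendering for plain names
    assert greek_atom_label("O") == "O"
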