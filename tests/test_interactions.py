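"""Interaction fingerprints: distance criteria, hydrogen-bond geometry,
aromatic sub-classification and water mediation."""

import numpy as np
import pytest

from ppicontacts import chem
from ppicontacts.contacts import ChainPair, find_proximal_pairs
from ppicontacts.fixtures import (
    amino_aromatic_fixture,
    atom_pair_fixture,
    disulphide,
    generate_fixture,
    hbond_fixture,
    ring_pair,
    water_bridge_fixture,
)
from ppicontacts.geometry import newell_normal, unit
from ppicontacts.interactions import (
    RingGeometry,
    build_fingerprints,
    classify_aromatic,
    classify_pair,
    detect_amino_aromatic,
    detect_hydrogen_bonds,
    detect_water_mediated,
)

PAIR = ChainPair("A", "B")


def _classify_two_atoms(res_i, atom_i, res_j, atom_j, d):
    s = atom_pair_fixture(res_i, atom_i, res_j, atom_j, d)
    (p,) = find_proximal_pairs(s, PAIR)
    return classify_pair(
        p, chem.lookup(res_i, atom_i), chem.lookup(res_j, atom_j)
    )


# Table of distance-criterion types: fixture atoms, flag, threshold
DISTANCE_CRITERIA = [
    ("CYS", "SG", "CYS", "SG", "disulphide", 2.08),
    ("LEU", "CD1", "LEU", "CD1", "hydrophobic", 5.0),
    ("LYS", "NZ", "GLU", "OE1", "ionic", 6.0),
    ("LYS", "NZ", "PHE", "CG", "pi_cation", 6.0),
    ("MET", "SD", "PHE", "CG", "aromatic_sulphur", 5.3),
    ("ALA", "CB", "ALA", "CB", "vdw", 1.88 + 1.88 + 0.5),
    ("ALA", "CB", "ALA", "CB", "vdw_clash", 1.88 + 1.88),
    ("ALA", "CB", "ALA", "CB", "covalent", 0.77 + 0.77),
]


class TestDistanceCriteria:
    @pytest.mark.parametrize("ri,ai,rj,aj,flag,threshold", DISTANCE_CRITERIA)
    def test_flag_flips_exactly_at_threshold(self, ri, ai, rj, aj, flag, threshold):
        eps = 5e-3
        below = _classify_two_atoms(ri, ai, rj, aj, threshold - eps)
        above = _classify_two_atoms(ri, ai, rj, aj, threshold + eps)
        assert getattr(below, flag), f"{flag} should be set below {threshold}"
        assert not getattr(above, flag), f"{flag} should be clear above {threshold}"

    def test_covalent_subset_of_clash_subset_of_vdw(self):
        for d in np.arange(1.0, 6.0, 0.25):
            fp = _classify_two_atoms("ALA", "CB", "ALA", "CB", float(d))
            assert (not fp.covalent) or fp.vdw_clash
            assert (not fp.vdw_clash) or fp.vdw

    def test_symmetry_of_asymmetric_capability_pairs(self):
        # cationic/anionic and sulphur/aromatic on either side of the pair
        a = _classify_two_atoms("GLU", "OE1", "LYS", "NZ", 5.5)
        b = _classify_two_atoms("LYS", "NZ", "GLU", "OE1", 5.5)
        assert a.ionic and b.ionic
        c = _classify_two_atoms("PHE", "CG", "MET", "SD", 5.0)
        assert c.aromatic_sulphur

    def test_disulphide_requires_cysteine_sulphurs(self):
        fp = _classify_two_atoms("MET", "SD", "MET", "SD", 2.0)
        assert not fp.disulphide

    def test_disulphide_preset(self):
        cls = build_fingerprints(disulphide(2.0), PAIR)
        ss = [c for c in cls if c.fingerprint.disulphide]
        assert len(ss) == 1
        assert ss[0].pair.distance == pytest.approx(2.0)
        # the covalent-range pair also carries the nested vdW flags
        assert ss[0].fingerprint.covalent
        assert ss[0].fingerprint.vdw_clash and ss[0].fingerprint.vdw


class TestHydrogenBonds:
    def test_canonical_backbone_bond_detected_main_main(self):
        s, realized = hbond_fixture(2.9, 160.0, theta_DAAA=120.0)
        assert realized["d_HA"] < 2.5 and realized["theta_HAAA"] > 90.0
        bonds = detect_hydrogen_bonds(s, PAIR)
        assert len(bonds) == 1
        hb = bonds[0]
        assert (hb.atom_don, hb.atom_acc, hb.subtype) == ("N", "O", "main-main")
        assert hb.geometry.d_DA == pytest.approx(2.9, abs=1e-6)

    def test_donor_acceptor_distance_gates(self):
        s, _ = hbond_fixture(3.95, 160.0, theta_DAAA=120.0)
        assert detect_hydrogen_bonds(s, PAIR) == []

    def test_hydrogen_acceptor_distance_gates(self):
        s, realized = hbond_fixture(3.3, 120.0, theta_DAAA=120.0)
        assert realized["d_DA"] < 3.9 and realized["theta_DHA"] > 90.0
        assert realized["d_HA"] > 2.5  # the only failing criterion
        assert detect_hydrogen_bonds(s, PAIR) == []

    def test_donor_hydrogen_acceptor_angle_gates(self):
        s, realized = hbond_fixture(2.4, 85.0, theta_DAAA=120.0)
        assert realized["d_DA"] < 3.9 and realized["d_HA"] < 2.5
        assert realized["theta_DAAA"] > 90.0 and realized["theta_HAAA"] > 90.0
        assert realized["theta_DHA"] < 90.0  # the only failing criterion
        assert detect_hydrogen_bonds(s, PAIR) == []

    def test_donor_acceptor_antecedent_angle_gates(self):
        s, realized = hbond_fixture(2.9, 160.0, theta_DAAA=-85.0)
        assert realized["d_HA"] < 2.5 and realized["theta_DHA"] > 90.0
        assert realized["theta_DAAA"] < 90.0 < realized["theta_HAAA"]
        assert detect_hydrogen_bonds(s, PAIR) == []

    def test_hydrogen_acceptor_antecedent_angle_gates(self):
        s, realized = hbond_fixture(2.9, 160.0, theta_HAAA=85.0)
        assert realized["d_HA"] < 2.5 and realized["theta_DHA"] > 90.0
        assert realized["theta_HAAA"] < 90.0 < realized["theta_DAAA"]
        assert detect_hydrogen_bonds(s, PAIR) == []

    def test_short_ionic_pair_is_also_a_hydrogen_bond_candidate(self):
        # a salt bridge within hydrogen-bond range carries both characters
        s, _ = hbond_fixture(2.9, 160.0, theta_DAAA=120.0)
        cls = build_fingerprints(s, PAIR)
        hb = [c for c in cls if c.fingerprint.hbond]
        assert hb and hb[0].fingerprint.vdw  # simultaneous character

    def test_flip_ambiguous_recovers_misassigned_amide(self):
        # ASN amide modelled with OD1 facing the acceptor: only the flipped
        # orientation (ND2 at OD1's position) can donate
        asn = ("A", 1, "ASN", {
            "CA": (-1.8, -2.2, 0.0), "N": (-3.0, -2.8, 0.0), "C": (-1.9, -3.2, 1.1),
            "O": (-2.5, -3.0, 2.1), "CB": (-1.0, -1.2, 0.0), "CG": (0.0, 0.0, 0.0),
            "OD1": (1.23, 0.2, 0.0), "ND2": (-0.6, 1.2, 0.0),
        })
        acc = np.array([1.23, 0.2, 0.0]) + 2.8 * unit(np.array([1.23, 0.2, 0.0]))
        aa = acc + 1.23 * np.array([0.2, 1.0, 0.0])
        gly = ("B", 2, "GLY", {
            "N": tuple(aa + (1.2, 1.0, 0.3)), "CA": tuple(aa + (0.1, 1.4, 0.1)),
            "C": tuple(aa), "O": tuple(acc),
        })
        s = generate_fixture([asn, gly])
        assert detect_hydrogen_bonds(s, PAIR, flip_ambiguous=False) == []
        flipped = detect_hydrogen_bonds(s, PAIR, flip_ambiguous=True)
        assert len(flipped) == 1
        assert flipped[0].atom_don == "ND2" and flipped[0].flipped

    def test_rotor_donor_serine_hydroxyl(self):
        # SER OG donating to a backbone O: some rotor position must pass
        og = np.array([0.0, 0.0, 0.0])
        ser = ("A", 1, "SER", {
            "N": (-3.6, 1.0, 0.2), "CA": (-2.6, 0.0, 0.0), "C": (-3.0, -1.2, 0.8),
            "O": (-4.1, -1.3, 1.3), "CB": (-1.3, 0.7, 0.0), "OG": tuple(og),
        })
        acc = np.array([2.8, 0.0, 0.0])
        aa = acc + np.array([0.8, 1.0, 0.0])
        gly = ("B", 2, "GLY", {
            "N": tuple(aa + (1.3, 0.9, 0.0)), "CA": tuple(aa + (0.2, 1.4, 0.0)),
            "C": tuple(aa), "O": tuple(acc),
        })
        bonds = detect_hydrogen_bonds(generate_fixture([ser, gly]), PAIR)
        assert any(b.atom_don == "OG" and b.subtype == "main-side" for b in bonds)


class TestAminoAromatic:
    def test_donor_above_ring_detected(self):
        s = amino_aromatic_fixture(3.2, 5.0)
        assert len(detect_amino_aromatic(s, PAIR)) >= 1

    def test_in_plane_donor_rejected(self):
        s = amino_aromatic_fixture(3.2, 85.0)
        assert detect_amino_aromatic(s, PAIR) == []

    def test_normal_angle_gate_near_twenty_degrees(self):
        assert detect_amino_aromatic(amino_aromatic_fixture(3.2, 15.0), PAIR)
        assert detect_amino_aromatic(amino_aromatic_fixture(3.2, 25.0), PAIR) == []

    def test_distance_gate(self):
        assert detect_amino_aromatic(amino_aromatic_fixture(4.0, 5.0), PAIR) == []

    def test_no_ring_no_bond(self):
        # ALA presents no aromatic acceptor
        spec = [("B", 3, "ALA", {"N": (0.0, 3.0, 0.0), "CA": (1.4, 3.0, 0.0),
                                 "C": (2.0, 4.4, 0.0), "O": (3.2, 4.5, 0.0),
                                 "CB": (1.8, 2.0, 1.0)})]
        s = generate_fixture(spec)
        assert detect_amino_aromatic(s, ChainPair("B", "C")) == []


class TestWaterMediation:
    def test_bridging_water_reported(self):
        bridges = detect_water_mediated(water_bridge_fixture(True), PAIR)
        assert [(b.atom_i, b.atom_j) for b in bridges] == [("OG", "O")]

    def test_single_sided_water_not_reported(self):
        assert detect_water_mediated(water_bridge_fixture(False), PAIR) == []

    def test_same_chain_bridge_not_reported(self):
        s = water_bridge_fixture(True)
        # rename chain B to A: the bridge becomes intra-chain
        for ch in s.chains:
            if ch.chain_id == "B":
                ch.chain_id = "A2"
        assert detect_water_mediated(s, ChainPair("A", "B")) == []


class TestAromaticClassification:
    @pytest.mark.parametrize(
        "dihedral,displacement,expected",
        [
            (0.0, 0.0, "face_to_face"),
            (10.0, 40.0, "displaced_face_to_face"),
            (45.0, 0.0, "edge_to_face"),
            (45.0, 40.0, "edge_to_face"),
            (29.0, 10.0, "face_to_face"),
        ],
    )
    def test_subtypes_from_ring_pair_presets(self, dihedral, displacement, expected):
        s = ring_pair(dihedral, displacement)
        subtypes = {
            c.fingerprint.aromatic_subtype
            for c in build_fingerprints(s, PAIR)
            if c.fingerprint.aromatic
        }
        assert subtypes == {expected}

    def test_centroid_distance_gate(self):
        near = RingGeometry(np.zeros(3), np.array([0.0, 0.0, 1.0]), ())
        far = RingGeometry(np.array([0.0, 0.0, 6.0]), np.array([0.0, 0.0, 1.0]), ())
        assert classify_aromatic(near, far) is None
        close = RingGeometry(np.array([0.0, 0.0, 3.8]), np.array([0.0, 0.0, 1.0]), ())
        assert classify_aromatic(near, close) == "face_to_face"

    def test_newell_equals_cross_product_for_planar_ring(self):
        from ppicontacts.fixtures import _hexagon

        ring = _hexagon(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 0.5]))
        newell = newell_normal(ring)
        cross = unit(np.cross(ring[1] - ring[0], ring[2] - ring[0]))
        assert min(np.linalg.norm(newell - cross), np.linalg.norm(newell + cross)) < 1e-9

    def test_newell_defined_for_perturbed_ring(self):
        from ppicontacts.fixtures import _hexagon

        rng = np.random.default_rng(0)
        ring = _hexagon(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        ring = ring + rng.normal(0, 0.02, ring.shape)
        n = newell_normal(ring)
        assert np.linalg.norm(n) == pytest.approx(1.0)
        assert abs(n @ np.array([0.0, 0.0, 1.0])) > 0.99

    def test_degenerate_ring_raises(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(6)])
        with pytest.raises(ValueError):
            newell_normal(line)


class TestMerge:
    def test_pair_meeting_no_criterion_is_proximal_only(self):
        # two backbone carbonyl oxygens at 6.0 Å: no criterion applies
        fp = _classify_two_atoms("GLY", "O", "GLY", "O", 6.0)
        assert fp.proximal_only and not fp.in_contact

    def test_in_contact_iff_any_flag(self):
        s = disulphide(2.0)
        for c in build_fingerprints(s, PAIR):
            assert c.fingerprint.in_contact == (not c.fingerprint.proximal_only)

    def test_rigid_motion_invariance_of_fingerprints(self):
        from ppicontacts.geometry import rotation_about_axis

        s1 = disulphide(2.0)
        s2 = disulphide(2.0)
        rot = rotation_about_axis(np.array([3.0, 1.0, 2.0]), 61.0)
        for _, atom in s2.iter_atoms():
            atom.coord = rot @ atom.coord + np.array([4.0, -7.0, 2.0])
        f1 = {(c.pair.res_i.id, c.pair.atom_i.name, c.pair.res_j.id, c.pair.atom_j.name):
              tuple(c.fingerprint.flags().values()) for c in build_fingerprints(s1, PAIR)}
        f2 = {(c.pair.res_i.id, c.pair.atom_i.name, c.pair.res_j.id, c.pair.atom_j.name):
              tuple(c.fingerprint.flags().values()) for c in build_fingerprints(s2, PAIR)}
        assert f1 == f2
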