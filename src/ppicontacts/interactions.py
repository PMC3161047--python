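"""Physico-chemical classification of proximal atom pairs.

Every inter-chain atom pair inside the 6.05 Å search radius receives a
non-exclusive binary interaction fingerprint over twelve interaction types:
van der Waals contact / clash / covalent (nested by definition), hydrogen
bond, water-mediated hydrogen bond, amino-aromatic hydrogen bond,
hydrophobic, ionic, aromatic (with face-to-face / displaced / edge-to-face
sub-classification), π-cation, disulphide and aromatic-sulphur.  A pair
matching no criterion is retained as merely proximal.

Hydrogen atoms are not taken from the coordinates (they are stripped during
sanitization and rarely resolved anyway); amide and ring N-H hydrogens are
placed from the antecedent geometry, while rotatable hydroxyl, thiol and
ammonium hydrogens are sampled around their rotor axis and a bond is accepted
if any rotor position satisfies all criteria.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import chem
from .contacts import ChainPair, ProximalPair, find_proximal_pairs
from .geometry import acute_angle_deg, angle_deg, newell_normal, rotation_about_axis, unit
from .structure import Residue, Structure

logger = logging.getLogger(__name__)

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

FLAG_NAMES = (
    "vdw",
    "vdw_clash",
    "covalent",
    "hbond",
    "water_mediated_hbond",
    "amino_aromatic_hbond",
    "hydrophobic",
    "ionic",
    "aromatic",
    "pi_cation",
    "disulphide",
    "aromatic_sulphur",
)


@dataclass
class Thresholds:
    """Distance/angle criteria of the interaction classification scheme (Å, °)."""

    proximal: float = 6.05
    vdw_pad: float = 0.5
    hydrophobic: float = 5.0
    ionic: float = 6.0
    aromatic_atom: float = 6.0
    aromatic_centroid: float = 6.0
    pi_cation: float = 6.0
    disulphide: float = 2.08
    aromatic_sulphur: float = 5.3
    hb_d_da: float = 3.9
    hb_d_ha: float = 2.5
    hb_angle: float = 90.0
    amino_aromatic_angle: float = 20.0
    aromatic_dihedral: float = 30.0
    aromatic_displacement: float = 20.0


@dataclass
class InteractionFingerprint:
    vdw: bool = False
    vdw_clash: bool = False
    covalent: bool = False
    hbond: bool = False
    water_mediated_hbond: bool = False
    amino_aromatic_hbond: bool = False
    hydrophobic: bool = False
    ionic: bool = False
    aromatic: bool = False
    pi_cation: bool = False
    disulphide: bool = False
    aromatic_sulphur: bool = False
    hbond_subtype: str | None = None  # main-main | main-side | side-side
    aromatic_subtype: str | None = None  # face_to_face | displaced_face_to_face | edge_to_face

    @property
    def in_contact(self) -> bool:
        """Logical OR over all interaction types."""
        return any(getattr(self, f) for f in FLAG_NAMES)

    @property
    def proximal_only(self) -> bool:
        return not self.in_contact

    def flags(self) -> dict[str, bool]:
        return {f: getattr(self, f) for f in FLAG_NAMES}


@dataclass
class HBondGeometry:
    d_DA: float
    d_HA: float
    theta_DHA: float
    theta_DAAA: float
    theta_HAAA: float


@dataclass
class RingGeometry:
    centroid: np.ndarray
    normal: np.ndarray
    member_atoms: tuple[str, ...]


@dataclass
class HBond:
    res_don: Residue
    atom_don: str
    res_acc: Residue
    atom_acc: str
    geometry: HBondGeometry
    subtype: str
    flipped: bool = False


@dataclass
class WaterBridge:
    water: Residue
    res_i: Residue
    atom_i: str
    res_j: Residue
    atom_j: str


# ---------------------------------------------------------------------------
# hydrogen placement

_BOND_H = {"N": 1.00, "O": 0.96, "S": 1.34}

# sidechain donors placed on the external bisector of two ring/planar
# antecedents: donor atom -> (antecedent_1, antecedent_2)
_BISECTOR_DONORS = {
    ("HIS", "ND1"): ("CG", "CE1"),
    ("HIS", "NE2"): ("CD2", "CE1"),
    ("TRP", "NE1"): ("CD1", "CE2"),
    ("ARG", "NE"): ("CD", "CZ"),
}

# sp2 amine donors with two in-plane hydrogens: donor -> (stem, plane mate)
_PLANAR_NH2 = {
    ("ARG", "NH1"): ("CZ", "NE"),
    ("ARG", "NH2"): ("CZ", "NE"),
    ("ASN", "ND2"): ("CG", "OD1"),
    ("GLN", "NE2"): ("CD", "OE1"),
}

# rotatable donors: donor -> (stem, dihedral reference); H sampled about the
# stem-donor axis at ROTOR_STEP increments
_ROTOR_DONORS = {
    ("SER", "OG"): ("CB", "CA"),
    ("THR", "OG1"): ("CB", "CA"),
    ("TYR", "OH"): ("CZ", "CE1"),
    ("CYS", "SG"): ("CB", "CA"),
    ("LYS", "NZ"): ("CE", "CD"),
}

ROTOR_STEP = 10.0  # degrees

_ACCEPTOR_ANTECEDENTS = {
    ("*", "O"): ("C",),
    ("*", "OXT"): ("C",),
    ("ASN", "OD1"): ("CG",),
    ("GLN", "OE1"): ("CD",),
    ("ASP", "OD1"): ("CG",),
    ("ASP", "OD2"): ("CG",),
    ("GLU", "OE1"): ("CD",),
    ("GLU", "OE2"): ("CD",),
    ("SER", "OG"): ("CB",),
    ("THR", "OG1"): ("CB",),
    ("TYR", "OH"): ("CZ",),
    ("HIS", "ND1"): ("CG", "CE1"),
    ("CYS", "SG"): ("CB",),
    ("MET", "SD"): ("CG", "CE"),
    ("TRP", "NE1"): ("CD1", "CE2"),
}


def _prev_residue(chain_residues: list[Residue], res: Residue) -> Residue | None:
    idx = None
    for i, r in enumerate(chain_residues):
        if r is res:
            idx = i
            break
    if idx is None or idx == 0:
        return None
    return chain_residues[idx - 1]


def donor_hydrogens(res: Residue, atom_name: str,
                    chain_residues: list[Residue] | None = None) -> list[np.ndarray]:
    """Candidate hydrogen positions for a donor heavy atom.

    Backbone amides and sp2 side-chain nitrogens give fixed positions;
    rotatable hydroxyls/thiols/ammoniums return the full 10°-step rotor
    sweep.  An empty list means the hydrogen could not be placed (missing
    antecedents); the donor is then skipped.
    """
    donor = res.atom(atom_name)
    if donor is None:
        return []
    d = donor.coord
    bl = _BOND_H.get(donor.element, 1.00)
    key = (res.res_name, atom_name)

    if atom_name == "N":  # backbone amide (PRO excluded by capability flags)
        ca = res.atom("CA")
        prev = _prev_residue(chain_residues or [], res) if chain_residues else None
        c_prev = prev.atom("C") if prev is not None else None
        if ca is None or c_prev is None:
            logger.debug("cannot place H on %s %s: missing antecedents", res.res_name, res.id)
            return []
        try:
            h_dir = unit(unit(d - ca.coord) + unit(d - c_prev.coord))
        except ValueError:
            return []
        return [d + bl * h_dir]

    if key in _BISECTOR_DONORS:
        a1, a2 = (res.atom(n) for n in _BISECTOR_DONORS[key])
        if a1 is None or a2 is None:
            return []
        return [d + bl * unit(unit(d - a1.coord) + unit(d - a2.coord))]

    if key in _PLANAR_NH2:
        stem_n, mate_n = _PLANAR_NH2[key]
        stem, mate = res.atom(stem_n), res.atom(mate_n)
        if stem is None or mate is None:
            return []
        axis = unit(np.cross(d - stem.coord, mate.coord - stem.coord))
        base = unit(d - stem.coord)  # bond-extension direction, away from the stem
        # the two in-plane hydrogens sit at ±60° off the extension
        # (equivalently 120° from the stem-N bond, standard sp2 geometry)
        return [
            d + bl * (rotation_about_axis(axis, sign * 60.0) @ base)
            for sign in (+1.0, -1.0)
        ]

    if key in _ROTOR_DONORS:
        stem_n, ref_n = _ROTOR_DONORS[key]
        stem, ref = res.atom(stem_n), res.atom(ref_n)
        if stem is None or ref is None:
            return []
        axis = unit(d - stem.coord)
        # seed H at the tetrahedral angle from the stem bond
        seed_perp = ref.coord - stem.coord
        seed_perp = seed_perp - np.dot(seed_perp, axis) * axis
        if np.linalg.norm(seed_perp) < 1e-9:
            seed_perp = np.cross(axis, [1.0, 0.0, 0.0])
            if np.linalg.norm(seed_perp) < 1e-9:
                seed_perp = np.cross(axis, [0.0, 1.0, 0.0])
        seed_perp = unit(seed_perp)
        # tetrahedral stem-donor-H angle: H at 180° − 109.47° from the
        # stem→donor axis direction
        t = math.radians(180.0 - 109.47)
        h0 = bl * (math.cos(t) * axis + math.sin(t) * seed_perp)
        return [
            d + rotation_about_axis(axis, step) @ h0
            for step in np.arange(0.0, 360.0, ROTOR_STEP)
        ]

    logger.debug("no placement rule for donor %s %s", res.res_name, atom_name)
    return []


def acceptor_antecedents(res: Residue, atom_name: str) -> list[np.ndarray]:
    names = _ACCEPTOR_ANTECEDENTS.get((res.res_name, atom_name))
    if names is None:
        names = _ACCEPTOR_ANTECEDENTS.get(("*", atom_name), ())
    out = []
    for n in names:
        a = res.atom(n)
        if a is not None:
            out.append(a.coord)
    return out


# ---------------------------------------------------------------------------
# distance-criterion classification


def classify_pair(p: ProximalPair, props_i: chem.AtomProperties,
                  props_j: chem.AtomProperties,
                  th: Thresholds | None = None) -> InteractionFingerprint:
    """Distance-criterion flags for one proximal pair (angle-based types and
    the aromatic centroid completion are applied by the full pipeline)."""
    th = th or Thresholds()
    d = p.distance
    fp = InteractionFingerprint()
    fp.vdw = d < props_i.vdw_radius + props_j.vdw_radius + th.vdw_pad
    fp.vdw_clash = d < props_i.vdw_radius + props_j.vdw_radius
    fp.covalent = d < props_i.cov_radius + props_j.cov_radius
    fp.hydrophobic = props_i.hydrophobic and props_j.hydrophobic and d < th.hydrophobic
    fp.ionic = (
        (props_i.cationic and props_j.anionic) or (props_i.anionic and props_j.cationic)
    ) and d < th.ionic
    fp.pi_cation = (
        (props_i.cationic and props_j.aromatic) or (props_i.aromatic and props_j.cationic)
    ) and d < th.pi_cation
    fp.disulphide = (
        p.res_i.res_name == "CYS"
        and p.res_j.res_name == "CYS"
        and p.atom_i.name == "SG"
        and p.atom_j.name == "SG"
        and d < th.disulphide
    )
    sulphur_i = p.atom_i.element == "S"
    sulphur_j = p.atom_j.element == "S"
    fp.aromatic_sulphur = (
        (sulphur_i and props_j.aromatic) or (props_i.aromatic and sulphur_j)
    ) and d < th.aromatic_sulphur
    return fp


# ---------------------------------------------------------------------------
# aromatic rings


def ring_geometry(res: Residue, ring: chem.RingSystem) -> RingGeometry | None:
    coords = []
    for name in ring.atom_names:
        a = res.atom(name)
        if a is None:
            return None
        coords.append(a.coord)
    pts = np.array(coords)
    return RingGeometry(
        centroid=pts.mean(axis=0), normal=newell_normal(pts), member_atoms=ring.atom_names
    )


def classify_aromatic(ring_i: RingGeometry, ring_j: RingGeometry,
                      th: Thresholds | None = None) -> str | None:
    """Sub-classify an aromatic ring pair; None when the centroids are out of
    range.  Edge-to-face above 30° dihedral; otherwise face-to-face within
    20° displacement and displaced face-to-face beyond."""
    th = th or Thresholds()
    sep = ring_j.centroid - ring_i.centroid
    if np.linalg.norm(sep) >= th.aromatic_centroid:
        return None
    dihedral = acute_angle_deg(ring_i.normal, ring_j.normal)
    if dihedral > th.aromatic_dihedral:
        return "edge_to_face"
    displacement = acute_angle_deg(ring_i.normal, sep)
    if displacement <= th.aromatic_displacement:
        return "face_to_face"
    return "displaced_face_to_face"


def _parent_ring(res: Residue, atom_name: str) -> RingGeometry | None:
    for ring in chem.ring_systems(res.res_name):
        if atom_name in ring.atom_names:
            return ring_geometry(res, ring)
    return None


# ---------------------------------------------------------------------------
# hydrogen bonds

_FLIP_SWAPS = {
    "HIS": (("ND1", "CD2"), ("NE2", "CE1")),
    "ASN": (("OD1", "ND2"),),
    "GLN": (("OE1", "NE2"),),
}


def _flip_residue(res: Residue) -> Residue:
    """Alternate side-chain orientation: swap the coordinates of the
    ambiguous electron-density atom pairs, keeping the names."""
    swaps = _FLIP_SWAPS.get(res.res_name, ())
    if not swaps:
        return res
    coords = {a.name: a.coord for a in res.atoms}
    new_atoms = []
    swap_map = {}
    for a, b in swaps:
        if a in coords and b in coords:
            swap_map[a], swap_map[b] = coords[b], coords[a]
    for a in res.atoms:
        if a.name in swap_map:
            new_atoms.append(replace(a, coord=swap_map[a.name].copy()))
        else:
            new_atoms.append(a)
    return replace(res, atoms=new_atoms)


def _residue_variants(res: Residue, flip: bool) -> list[tuple[Residue, bool]]:
    if flip and res.res_name in _FLIP_SWAPS:
        return [(res, False), (_flip_residue(res), True)]
    return [(res, False)]


def _subtype(atom_a: str, atom_b: str) -> str:
    a_main = atom_a in MAIN_CHAIN_ATOMS
    b_main = atom_b in MAIN_CHAIN_ATOMS
    if a_main and b_main:
        return "main-main"
    if a_main or b_main:
        return "main-side"
    return "side-side"


def _check_hbond(don_res: Residue, don_name: str, acc_res: Residue, acc_name: str,
                 chain_residues: list[Residue], th: Thresholds) -> HBondGeometry | None:
    donor = don_res.atom(don_name)
    acceptor = acc_res.atom(acc_name)
    if donor is None or acceptor is None:
        return None
    d_da = float(np.linalg.norm(donor.coord - acceptor.coord))
    if not d_da < th.hb_d_da:
        return None
    antecedents = acceptor_antecedents(acc_res, acc_name)
    for aa in antecedents:
        if not angle_deg(donor.coord, acceptor.coord, aa) > th.hb_angle:
            return None
    best: HBondGeometry | None = None
    for h in donor_hydrogens(don_res, don_name, chain_residues):
        d_ha = float(np.linalg.norm(h - acceptor.coord))
        if not d_ha < th.hb_d_ha:
            continue
        t_dha = angle_deg(donor.coord, h, acceptor.coord)
        if not t_dha > th.hb_angle:
            continue
        t_haaa = [angle_deg(h, acceptor.coord, aa) for aa in antecedents]
        if not all(t > th.hb_angle for t in t_haaa):
            continue
        t_daaa = min(
            (angle_deg(donor.coord, acceptor.coord, aa) for aa in antecedents),
            default=180.0,
        )
        geom = HBondGeometry(d_da, d_ha, t_dha, t_daaa, min(t_haaa, default=180.0))
        if best is None or geom.d_HA < best.d_HA:
            best = geom
    return best


def _polar_atoms(res: Residue, want_donor: bool) -> list[str]:
    out = []
    for a in res.atoms:
        if a.is_hydrogen or not chem.has_entry(res.res_name, a.name):
            continue
        props = chem.lookup(res.res_name, a.name)
        if (want_donor and props.hb_donor) or (not want_donor and props.hb_acceptor):
            out.append(a.name)
    return out


def detect_hydrogen_bonds(s: Structure, pair: ChainPair,
                          flip_ambiguous: bool = False,
                          th: Thresholds | None = None) -> list[HBond]:
    """Direct inter-chain hydrogen bonds between the two chains of ``pair``.

    With ``flip_ambiguous`` the alternative HIS/ASN/GLN side-chain
    orientations (electron-density ambiguity) are also explored and a bond is
    reported if any orientation passes.
    """
    th = th or Thresholds()
    out: list[HBond] = []
    candidates = find_proximal_pairs(s, pair, radius=th.hb_d_da)
    residues_by_chain = {
        cid: (s.chain(cid).residues if s.chain(cid) else [])
        for cid in (pair.chain_i, pair.chain_j)
    }
    seen: set[tuple] = set()

    def _name_options(res: Residue, name: str) -> list[str]:
        # with flipping on, the swap partner occupies this position in the
        # flipped orientation, so it is also a candidate at this distance
        opts = [name]
        if flip_ambiguous:
            for a, b in _FLIP_SWAPS.get(res.res_name, ()):
                if name == a:
                    opts.append(b)
                elif name == b:
                    opts.append(a)
        return [n for n in opts if chem.has_entry(res.res_name, n)]

    for p in candidates:
        for don_res0, don_name0, acc_res0, acc_name0, don_chain in (
            (p.res_i, p.atom_i.name, p.res_j, p.atom_j.name, pair.chain_i),
            (p.res_j, p.atom_j.name, p.res_i, p.atom_i.name, pair.chain_j),
        ):
            if don_res0.res_name not in chem.STANDARD_AA or \
                    acc_res0.res_name not in chem.STANDARD_AA:
                continue
            for don_name, acc_name in itertools.product(
                _name_options(don_res0, don_name0), _name_options(acc_res0, acc_name0)
            ):
                if not chem.lookup(don_res0.res_name, don_name).hb_donor:
                    continue
                if not chem.lookup(acc_res0.res_name, acc_name).hb_acceptor:
                    continue
                key = (don_res0.id, don_name, acc_res0.id, acc_name)
                if key in seen:
                    continue
                for (don_res, don_flip), (acc_res, acc_flip) in itertools.product(
                    _residue_variants(don_res0, flip_ambiguous),
                    _residue_variants(acc_res0, flip_ambiguous),
                ):
                    geom = _check_hbond(
                        don_res, don_name, acc_res, acc_name,
                        residues_by_chain[don_chain], th,
                    )
                    if geom is not None:
                        out.append(
                            HBond(
                                res_don=don_res0, atom_don=don_name,
                                res_acc=acc_res0, atom_acc=acc_name,
                                geometry=geom,
                                subtype=_subtype(don_name, acc_name),
                                flipped=don_flip or acc_flip,
                            )
                        )
                        seen.add(key)
                        break
    return out


def detect_amino_aromatic(s: Structure, pair: ChainPair,
                          th: Thresholds | None = None) -> list[HBond]:
    """Donor N/O-H directed at the π face of a PHE/TYR/TRP ring across the
    interface."""
    th = th or Thresholds()
    out: list[HBond] = []
    chain_ids = (pair.chain_i, pair.chain_j)
    for don_cid, acc_cid in (chain_ids, chain_ids[::-1]):
        don_chain = s.chain(don_cid)
        acc_chain = s.chain(acc_cid)
        if don_chain is None or acc_chain is None:
            continue
        rings = []
        for res in acc_chain.polymer_residues:
            for ring_sys in chem.ring_systems(res.res_name):
                if not chem.lookup(res.res_name, ring_sys.atom_names[0]).aromatic_hb_acceptor:
                    continue
                geom = ring_geometry(res, ring_sys)
                if geom is not None:
                    rings.append((res, geom))
        if not rings:
            continue
        for res in don_chain.polymer_residues:
            for don_name in _polar_atoms(res, want_donor=True):
                donor = res.atom(don_name)
                hydrogens = donor_hydrogens(res, don_name, don_chain.residues)
                if not hydrogens:
                    continue
                for acc_res, ring in rings:
                    for acc_name in ring.member_atoms:
                        acc = acc_res.atom(acc_name)
                        if acc is None:
                            continue
                        d_da = float(np.linalg.norm(donor.coord - acc.coord))
                        if not d_da < th.hb_d_da:
                            continue
                        if not acute_angle_deg(donor.coord - acc.coord, ring.normal) \
                                < th.amino_aromatic_angle:
                            continue
                        for h in hydrogens:
                            d_ha = float(np.linalg.norm(h - acc.coord))
                            if not d_ha < th.hb_d_ha:
                                continue
                            if not acute_angle_deg(donor.coord - h, ring.normal) \
                                    < th.amino_aromatic_angle:
                                continue
                            out.append(
                                HBond(
                                    res_don=res, atom_don=don_name,
                                    res_acc=acc_res, atom_acc=acc_name,
                                    geometry=HBondGeometry(d_da, d_ha, 180.0, 180.0, 180.0),
                                    subtype=_subtype(don_name, acc_name),
                                )
                            )
                            break
    return out


def _water_bonds_to_chain(water_o, chain_residues: list[Residue],
                          th: Thresholds) -> list[tuple[Residue, str]]:
    """Protein atoms of one chain hydrogen-bonded to a water oxygen.

    Water hydrogens are free rotors, so when the water donates its hydrogen
    is placed optimally along O→acceptor; when the protein donates, the water
    oxygen accepts without antecedent-angle criteria.
    """
    out = []
    for res in chain_residues:
        if not res.is_polymer:
            continue
        for name in set(_polar_atoms(res, True)) | set(_polar_atoms(res, False)):
            atom = res.atom(name)
            d = float(np.linalg.norm(atom.coord - water_o))
            if not d < th.hb_d_da:
                continue
            props = chem.lookup(res.res_name, name)
            ok = False
            if props.hb_acceptor:
                # water donates: H on the O->acceptor axis at 0.96 Å
                d_ha = d - _BOND_H["O"]
                if d_ha < th.hb_d_ha:
                    antecedents = acceptor_antecedents(res, name)
                    h = water_o + (atom.coord - water_o) * (_BOND_H["O"] / d)
                    ok = all(
                        angle_deg(water_o, atom.coord, aa) > th.hb_angle
                        and angle_deg(h, atom.coord, aa) > th.hb_angle
                        for aa in antecedents
                    )
            if not ok and props.hb_donor:
                # protein donates; the water oxygen has no antecedent
                for h in donor_hydrogens(res, name, chain_residues):
                    d_ha = float(np.linalg.norm(h - water_o))
                    if d_ha < th.hb_d_ha and angle_deg(atom.coord, h, water_o) > th.hb_angle:
                        ok = True
                        break
            if ok:
                out.append((res, name))
    return out


def detect_water_mediated(s: Structure, pair: ChainPair,
                          th: Thresholds | None = None) -> list[WaterBridge]:
    """Inter-chain residue pairs bridged by a shared structured water.

    A water qualifying here hydrogen-bonds to both chains and so by
    construction engages in more than one hydrogen bond.  Donor-donor,
    acceptor-acceptor and donor-acceptor bridges are all allowed.
    """
    th = th or Thresholds()
    chain_i = s.chain(pair.chain_i)
    chain_j = s.chain(pair.chain_j)
    if chain_i is None or chain_j is None:
        return []
    out: list[WaterBridge] = []
    for res in s.iter_residues():
        if not res.is_water:
            continue
        o = res.atom("O")
        if o is None:
            continue
        bonds_i = _water_bonds_to_chain(o.coord, chain_i.residues, th)
        if not bonds_i:
            continue
        bonds_j = _water_bonds_to_chain(o.coord, chain_j.residues, th)
        for (ri, ai), (rj, aj) in itertools.product(bonds_i, bonds_j):
            out.append(WaterBridge(water=res, res_i=ri, atom_i=ai, res_j=rj, atom_j=aj))
    return out


# ---------------------------------------------------------------------------
# assembly of the full fingerprint table


@dataclass
class ClassifiedPair:
    pair: ProximalPair
    fingerprint: InteractionFingerprint


def _pair_key(p: ProximalPair) -> tuple:
    return (p.res_i.id, p.atom_i.name, p.res_j.id, p.atom_j.name)


def build_fingerprints(s: Structure, pair: ChainPair,
                       th: Thresholds | None = None,
                       flip_ambiguous: bool = False,
                       include_waters: bool = True) -> list[ClassifiedPair]:
    """Classify every proximal atom pair of one chain pair.

    Runs the distance-criterion pass, completes aromatic contacts with the
    ring-centroid condition, merges in hydrogen bonds, amino-aromatic bonds
    and water bridges, and returns the pairs with their merged fingerprints
    (the logical OR over all detections).  Pairs matching nothing remain
    stored with ``proximal_only`` True.
    """
    th = th or Thresholds()
    classified: dict[tuple, ClassifiedPair] = {}
    for p in find_proximal_pairs(s, pair, radius=th.proximal):
        if p.res_i.res_name not in chem.STANDARD_AA or p.res_j.res_name not in chem.STANDARD_AA:
            continue  # unrepaired non-standard residues are not classified
        props_i = chem.lookup(p.res_i.res_name, p.atom_i.name, p.atom_i.element)
        props_j = chem.lookup(p.res_j.res_name, p.atom_j.name, p.atom_j.element)
        fp = classify_pair(p, props_i, props_j, th)
        # aromatic completion: atom-level criterion plus ring-centroid check
        if (props_i.aromatic and props_j.aromatic and p.distance < th.aromatic_atom):
            ring_i = _parent_ring(p.res_i, p.atom_i.name)
            ring_j = _parent_ring(p.res_j, p.atom_j.name)
            if ring_i is not None and ring_j is not None:
                subtype = classify_aromatic(ring_i, ring_j, th)
                if subtype is not None:
                    fp.aromatic = True
                    fp.aromatic_subtype = subtype
        classified[_pair_key(p)] = ClassifiedPair(pair=p, fingerprint=fp)

    def _mark(res_a: Residue, atom_a: str, res_b: Residue, atom_b: str, flag: str,
              subtype: str | None = None):
        # orient onto (chain_i, chain_j)
        if res_a.chain_id == pair.chain_i:
            key = (res_a.id, atom_a, res_b.id, atom_b)
        else:
            key = (res_b.id, atom_b, res_a.id, atom_a)
        cp = classified.get(key)
        if cp is None:
            return  # bridged pair outside the proximal radius: not stored
        setattr(cp.fingerprint, flag, True)
        if flag == "hbond" and subtype is not None:
            cp.fingerprint.hbond_subtype = subtype

    for hb in detect_hydrogen_bonds(s, pair, flip_ambiguous=flip_ambiguous, th=th):
        _mark(hb.res_don, hb.atom_don, hb.res_acc, hb.atom_acc, "hbond", hb.subtype)
    for hb in detect_amino_aromatic(s, pair, th=th):
        _mark(hb.res_don, hb.atom_don, hb.res_acc, hb.atom_acc, "amino_aromatic_hbond")
    if include_waters:
        for wb in detect_water_mediated(s, pair, th=th):
            _mark(wb.res_i, wb.atom_i, wb.res_j, wb.atom_j, "water_mediated_hbond")
    return list(classified.values())
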