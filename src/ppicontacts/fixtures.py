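"""Deterministic synthetic structures for testing and analysis.

Three layers of generator are provided:

* :func:`generate_fixture` — explicit residue/atom/coordinate specifications,
  for fixtures whose exact geometry is the point of the test;
* geometric presets for each interaction type (disulphide pairs, stacked
  aromatic rings at a requested dihedral/displacement, hydrogen-bond
  donor/acceptor arrangements with controlled distances and angles);
* a peptide builder that threads real side-chain geometry (CCD ideal
  coordinates via biotite) onto a NeRF-generated backbone, used for extended
  Ala-X-Ala reference tripeptides and for helix-dimer "coiled-coil" complexes
  that emulate a hydrophobic-core interface.

Everything is deterministic given its arguments (and seed, where one is
taken).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .geometry import (
    kabsch,
    newell_normal,
    place_atom,
    rotation_about_axis,
    unit,
)
from .structure import Atom, Chain, Residue, Structure

# residue spec: (chain_id, res_seq, res_name, {atom_name: (x, y, z)})
FixtureSpec = list[tuple[str, int, str, dict[str, tuple[float, float, float]]]]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _element_of(atom_name: str) -> str:
    if atom_name.upper() == "SE":
        return "SE"
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def generate_fixture(spec: FixtureSpec, entry_id: str = "TOY1") -> Structure:
    """Build a Structure embedding exactly the requested geometry."""
    chains: dict[str, Chain] = {}
    seen: dict[tuple[int, str], str] = {}
    for chain_id, res_seq, res_name, atoms in spec:
        key = (res_seq, res_name)
        if seen.setdefault(key, chain_id) != chain_id:
            raise ValueError(f"atoms of residue {res_seq} {res_name} spread over >1 chain")
        chain = chains.setdefault(chain_id, Chain(chain_id=chain_id))
        residue = None
        for r in chain.residues:
            if r.res_seq == res_seq and r.res_name == res_name:
                residue = r
                break
        if residue is None:
            residue = Residue(chain_id=chain_id, res_seq=res_seq, icode="", res_name=res_name)
            chain.residues.append(residue)
        for name, coord in atoms.items():
            residue.atoms.append(
                Atom(name=name, element=_element_of(name), coord=np.asarray(coord, float))
            )
    return Structure(entry_id=entry_id, models=[list(chains.values())])


# ---------------------------------------------------------------------------
# interaction-type presets


def _cys_residue(chain: str, seq: int, sg: np.ndarray, direction: np.ndarray) -> tuple:
    """A cysteine whose SG sits at ``sg``; remaining atoms trail off along
    ``direction`` (away from the partner chain)."""
    d = unit(np.asarray(direction, float))
    cb = sg + 1.81 * d
    ca = cb + 1.53 * unit(d + np.array([0.0, 0.6, 0.0]))
    n = ca + 1.46 * unit(d + np.array([0.0, -0.8, 0.2]))
    c = ca + 1.53 * unit(d + np.array([0.0, 0.3, -0.9]))
    o = c + 1.23 * d
    coords = {"N": n, "CA": ca, "C": c, "O": o, "CB": cb, "SG": sg}
    return (chain, seq, "CYS", {k: tuple(v) for k, v in coords.items()})


def disulphide(d: float = 2.0) -> Structure:
    """Two cysteines on chains A/B with an SG-SG separation of exactly ``d``."""
    a = _cys_residue("A", 1, np.array([0.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]))
    b = _cys_residue("B", 2, np.array([d, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    return generate_fixture([a, b], entry_id="SS01")


def atom_pair_fixture(res_i: str, atom_i: str, res_j: str, atom_j: str,
                      distance: float) -> Structure:
    """Two single-atom residues on chains A and B at the given separation.

    The minimal fixture for sweeping a distance-criterion interaction type
    across its threshold.
    """
    spec: FixtureSpec = [
        ("A", 1, res_i, {atom_i: (0.0, 0.0, 0.0)}),
        ("B", 2, res_j, {atom_j: (distance, 0.0, 0.0)}),
    ]
    return generate_fixture(spec, entry_id="PAIR")


_RING_RADIUS = 1.39  # benzene C-C ring circumradius, Å


def _hexagon(center: np.ndarray, normal: np.ndarray, phase_deg: float = 0.0) -> np.ndarray:
    nz = unit(np.asarray(normal, float))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, nz)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(nz, ref))
    v = np.cross(nz, u)
    ang = np.radians(phase_deg + 60.0 * np.arange(6))
    return center + _RING_RADIUS * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


_PHE_RING_ORDER = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")  # perimeter order


def _phe_residue(chain: str, seq: int, ring: np.ndarray, away: np.ndarray) -> tuple:
    coords = dict(zip(_PHE_RING_ORDER, ring))
    d = unit(np.asarray(away, float))
    cb = np.asarray(coords["CG"]) + 1.51 * d
    ca = cb + 1.53 * unit(d + np.array([0.0, 0.5, 0.5]))
    n = ca + 1.46 * unit(d + np.array([0.0, -0.9, 0.1]))
    c = ca + 1.53 * unit(d + np.array([0.0, 0.2, -0.9]))
    o = c + 1.23 * d
    coords.update({"CB": cb, "CA": ca, "N": n, "C": c, "O": o})
    return (chain, seq, "PHE", {k: tuple(np.asarray(v)) for k, v in coords.items()})


def ring_pair(dihedral: float, displacement: float,
              centroid_distance: float = 3.8) -> Structure:
    """Two PHE rings: normals subtend ``dihedral`` degrees; the centroid-
    centroid vector makes ``displacement`` degrees with ring A's normal."""
    c1 = np.array([0.0, 0.0, 0.0])
    n1 = np.array([0.0, 0.0, 1.0])
    phi = np.radians(displacement)
    c2 = c1 + centroid_distance * np.array([math.sin(phi), 0.0, math.cos(phi)])
    n2 = rotation_about_axis(np.array([0.0, 1.0, 0.0]), dihedral) @ n1
    ring1 = _hexagon(c1, n1)
    ring2 = _hexagon(c2, n2)
    a = _phe_residue("A", 1, ring1, np.array([-1.0, 0.3, 0.0]))
    b = _phe_residue("B", 2, ring2, np.array([1.0, -0.3, 0.0]))
    s = generate_fixture([a, b], entry_id="RING")
    # self-check the constructed geometry
    na = newell_normal(ring1)
    assert abs(abs(np.dot(na, n1)) - 1.0) < 1e-9
    return s


def _donor_unit(chain: str, n_pos: np.ndarray, h_dir: np.ndarray,
                start_seq: int = 1) -> list[tuple]:
    """Two glycines providing a backbone amide N at ``n_pos`` whose placed
    hydrogen points along ``h_dir`` (antecedents arranged symmetrically)."""
    h = unit(np.asarray(h_dir, float))
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, h)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = unit(np.cross(h, ref))
    alpha = np.radians(60.0)
    u1 = -math.cos(alpha) * h + math.sin(alpha) * perp
    u2 = -math.cos(alpha) * h - math.sin(alpha) * perp
    ca = n_pos + 1.458 * u1
    c_prev = n_pos + 1.329 * u2
    ca_prev = c_prev + 1.525 * unit(u2 + 0.3 * perp)
    n_prev = ca_prev + 1.458 * unit(u2)
    o_prev = c_prev + 1.231 * unit(np.cross(u2, perp))
    c_cur = ca + 1.525 * unit(u1)
    o_cur = c_cur + 1.231 * unit(u1 + 0.5 * perp)
    return [
        (chain, start_seq, "GLY",
         {"N": tuple(n_prev), "CA": tuple(ca_prev), "C": tuple(c_prev), "O": tuple(o_prev)}),
        (chain, start_seq + 1, "GLY",
         {"N": tuple(n_pos), "CA": tuple(ca), "C": tuple(c_cur), "O": tuple(o_cur)}),
    ]


def hbond_fixture(d_DA: float = 2.9, theta_DHA: float = 160.0,
                  theta_DAAA: float | None = None,
                  theta_HAAA: float | None = None) -> tuple[Structure, dict]:
    """Backbone N-H···O=C arrangement with controlled geometry.

    The donor is a backbone amide N (H placed internally along +x by
    construction); the acceptor is a backbone carbonyl O on chain B.  Exactly
    one of ``theta_DAAA`` / ``theta_HAAA`` may be pinned; the antecedent
    carbon is placed in-plane to realize it, and the realized values of all
    five criteria are returned alongside the structure.
    """
    if theta_DAAA is not None and theta_HAAA is not None:
        raise ValueError("pin at most one antecedent angle")
    n_pos = np.array([0.0, 0.0, 0.0])
    h_pos = np.array([1.0, 0.0, 0.0])
    # acceptor position: angle(N, H, A) = theta_DHA, |N-A| = d_DA
    t = np.radians(180.0 - theta_DHA)
    dir_ha = np.array([math.cos(t), math.sin(t), 0.0])
    # solve |h + r*dir| = d_DA
    b = 2.0 * np.dot(h_pos, dir_ha)
    c = np.dot(h_pos, h_pos) - d_DA**2
    disc = b * b - 4 * c
    if disc < 0:
        raise ValueError("requested d_DA/theta_DHA geometry is infeasible")
    r = (-b + math.sqrt(disc)) / 2.0
    a_pos = h_pos + r * dir_ha
    d_HA = float(np.linalg.norm(a_pos - h_pos))

    to_d = unit(n_pos - a_pos)
    to_h = unit(h_pos - a_pos)
    delta = math.degrees(math.acos(np.clip(np.dot(to_d, to_h), -1, 1)))
    if theta_HAAA is not None:
        # antecedent on the far side of A->H
        aa_angle_from_h = theta_HAAA
        base, off = to_h, aa_angle_from_h
    else:
        if theta_DAAA is None:
            theta_DAAA = 120.0
        base, off = to_d, theta_DAAA
    # rotate `base` by `off` degrees in the z=0 plane, away from the partner
    rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), off)
    aa_dir = rot @ base
    aa_pos = a_pos + 1.231 * aa_dir

    spec = _donor_unit("A", n_pos, np.array([1.0, 0.0, 0.0]))
    ca_b = aa_pos + 1.525 * unit(aa_dir + np.array([0.0, 0.0, 0.8]))
    n_b = ca_b + 1.458 * unit(aa_dir)
    spec.append(
        ("B", 3, "GLY",
         {"N": tuple(n_b), "CA": tuple(ca_b), "C": tuple(aa_pos), "O": tuple(a_pos)})
    )
    s = generate_fixture(spec, entry_id="HB01")

    def ang(p, q, w):
        from .geometry import angle_deg
        return angle_deg(p, q, w)

    realized = {
        "d_DA": float(np.linalg.norm(a_pos - n_pos)),
        "d_HA": d_HA,
        "theta_DHA": ang(n_pos, h_pos, a_pos),
        "theta_DAAA": ang(n_pos, a_pos, aa_pos),
        "theta_HAAA": ang(h_pos, a_pos, aa_pos),
    }
    return s, realized


def amino_aromatic_fixture(d_DA: float = 3.2, normal_angle: float = 5.0) -> Structure:
    """Backbone donor above a PHE ring plane.

    The donor N sits at ``normal_angle`` degrees off the ring normal through
    the acceptor carbon, with its placed hydrogen pointing at that carbon.
    """
    ring = _hexagon(np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    acc = ring[0]  # CG
    t = np.radians(normal_angle)
    n_pos = acc + d_DA * np.array([math.sin(t), 0.0, math.cos(t)])
    spec = [_phe_residue("B", 3, ring, np.array([1.0, -0.3, 0.0]))]
    spec += _donor_unit("A", n_pos, acc - n_pos)
    return generate_fixture(spec, entry_id="AMAR")


def water_bridge_fixture(bridging: bool = True) -> Structure:
    """A water bridging a SER OG (chain A) and a backbone O (chain B).

    With ``bridging`` False the chain-B acceptor is moved out of range so the
    water hydrogen-bonds to one chain only.
    """
    w = np.array([0.0, 0.0, 0.0])
    og = np.array([-2.8, 0.0, 0.0])
    ser = ("A", 1, "SER", {
        "N": (-6.5, 0.8, 0.0), "CA": (-5.6, -0.3, 0.0), "C": (-5.9, -1.4, 1.0),
        "O": (-6.9, -1.4, 1.7), "CB": (-4.2, 0.2, 0.2), "OG": tuple(og),
    })
    bx = 2.8 if bridging else 9.0
    gly_o = np.array([bx, 0.0, 0.0])
    gly_c = gly_o + np.array([0.7, 1.0, 0.0])
    gly = ("B", 2, "GLY", {
        "N": tuple(gly_c + (1.4, 1.0, 0.6)), "CA": tuple(gly_c + (0.2, 1.3, 0.2)),
        "C": tuple(gly_c), "O": tuple(gly_o),
    })
    wat = ("W", 101, "HOH", {"O": tuple(w)})
    return generate_fixture([ser, gly, wat], entry_id="WAT1")


# ---------------------------------------------------------------------------
# peptide builder


@lru_cache(maxsize=32)
def _ideal_residue(res_name: str) -> dict[str, np.ndarray]:
    """Heavy-atom ideal coordinates of a canonical residue from the CCD."""
    import biotite.structure.info as info

    arr = info.residue(res_name)
    out: dict[str, np.ndarray] = {}
    for name, elem, xyz in zip(arr.atom_name, arr.element, arr.coord):
        if elem == "H" or name == "OXT":
            continue
        out[str(name)] = np.asarray(xyz, dtype=float)
    return out


_BB = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, n_ca_c=111.2, ca_c_n=116.2, c_n_ca=121.7)


def build_peptide(sequence: str, chain_id: str = "A", phi: float = 180.0,
                  psi: float = 180.0, start_seq: int = 1) -> Chain:
    """Thread ``sequence`` (1-letter codes) onto a regular (phi, psi) backbone.

    Extended conformation by default; (-57, -47) gives an alpha-helix.  Side
    chains keep their CCD ideal internal geometry (rigidly superposed on each
    backbone N/CA/C frame).
    """
    res_names = [_AA3[c] for c in sequence.upper()]
    # backbone trace via NeRF
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["n_ca"], 0.0, 0.0])
    # residue 1 has no preceding C; an arbitrary reference point fixes phi_1
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, _BB["ca_c"], _BB["n_ca_c"], phi)
    frames = [(n, ca, c)]
    for _ in range(1, len(res_names)):
        n_next = place_atom(*frames[-1], _BB["c_n"], _BB["ca_c_n"], psi)
        ca_next = place_atom(frames[-1][1], frames[-1][2], n_next, _BB["n_ca"],
                             _BB["c_n_ca"], 180.0)
        c_next = place_atom(frames[-1][2], n_next, ca_next, _BB["ca_c"],
                            _BB["n_ca_c"], phi)
        frames.append((n_next, ca_next, c_next))

    chain = Chain(chain_id=chain_id)
    for i, (res_name, (bn, bca, bc)) in enumerate(zip(res_names, frames)):
        ideal = _ideal_residue(res_name)
        mob = np.array([ideal["N"], ideal["CA"], ideal["C"]])
        tgt = np.array([bn, bca, bc])
        r, tvec = kabsch(mob, tgt)
        residue = Residue(chain_id=chain_id, res_seq=start_seq + i, icode="",
                          res_name=res_name)
        for name, xyz in ideal.items():
            residue.atoms.append(
                Atom(name=name, element=_element_of(name), coord=xyz @ r.T + tvec)
            )
        chain.residues.append(residue)
    return chain


def tripeptide_reference(res_name: str) -> Structure:
    """Extended Ala-X-Ala used as the relative-accessibility reference."""
    one = {v: k for k, v in _AA3.items()}[res_name.upper()]
    chain = build_peptide("A" + one + "A", chain_id="A")
    return Structure(entry_id="AXA_", models=[[chain]])


# ---------------------------------------------------------------------------
# synthetic helix-dimer complexes (hydrophobic-core interfaces)

_HYDROPHOBIC = "LIVFM"
_POLAR = "KEQNSTDR"


def _heptad_sequence(n: int, rng: np.random.Generator) -> str:
    seq = []
    for i in range(n):
        pos = i % 7
        if pos in (0, 3):  # heptad a/d positions face the partner helix
            seq.append(_HYDROPHOBIC[rng.integers(len(_HYDROPHOBIC))])
        else:
            seq.append(_POLAR[rng.integers(len(_POLAR))])
    return "".join(seq)


def _orient_helix(chain: Chain, face_direction: np.ndarray) -> None:
    """Rotate the helix about its axis so hydrophobic side chains face
    ``face_direction``; recentre the axis on the origin."""
    ca = np.array([r.atom("CA").coord for r in chain.residues])
    centroid = ca.mean(axis=0)
    # helix axis: dominant principal component of the CA trace
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = unit(vt[0])
    cb = [r.atom("CB").coord for r in chain.residues
          if r.res_name in {_AA3[c] for c in _HYDROPHOBIC} and r.atom("CB") is not None]
    face = np.mean(cb, axis=0) - centroid
    face -= np.dot(face, axis) * axis
    target = np.asarray(face_direction, float)
    target = target - np.dot(target, axis) * axis
    ang = math.degrees(math.atan2(np.dot(np.cross(face, target), axis),
                                  np.dot(face, target)))
    rot = rotation_about_axis(axis, ang)
    for res in chain.residues:
        for atom in res.atoms:
            atom.coord = rot @ (atom.coord - centroid)


def synthetic_complex(seed: int, n_res: int = 21, separation: float = 9.3,
                      noise: float = 0.15) -> Structure:
    """A two-helix dimer with hydrophobic heptad faces packed together.

    ``separation`` is the inter-axis distance (9.3 Å, a typical dimeric
    coiled-coil value); ``noise`` adds isotropic Gaussian coordinate jitter
    emulating coordinate error.
    """
    rng = np.random.default_rng(seed)
    seq_a = _heptad_sequence(n_res, rng)
    seq_b = _heptad_sequence(n_res, rng)
    ha = build_peptide(seq_a, chain_id="A", phi=-57.0, psi=-47.0)
    hb = build_peptide(seq_b, chain_id="B", phi=-57.0, psi=-47.0)
    _orient_helix(ha, np.array([1.0, 0.0, 0.0]))
    _orient_helix(hb, np.array([-1.0, 0.0, 0.0]))
    for res in hb.residues:
        for atom in res.atoms:
            atom.coord = atom.coord + np.array([separation, 0.0, 0.0])
    for ch in (ha, hb):
        for res in ch.residues:
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(0.0, noise, 3)
    return Structure(entry_id=f"SYN{seed % 10000:04d}", models=[[ha, hb]])


def synthetic_complex_set(n: int, seed: int) -> list[Structure]:
    """``n`` independent helix-dimer complexes for statistics tests."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [synthetic_complex(int(s)) for s in seeds]


def random_two_chain_fixture(seed: int, n_atoms_per_chain: int = 100,
                             box: float = 12.0) -> Structure:
    """Random ALA CB point clouds on two chains, for brute-force comparisons."""
    rng = np.random.default_rng(seed)
    spec: FixtureSpec = []
    for k, (chain_id, shift) in enumerate((("A", 0.0), ("B", 4.0))):
        for i in range(n_atoms_per_chain):
            xyz = rng.uniform(0, box, 3) + np.array([shift, 0.0, 0.0])
            spec.append((chain_id, k * n_atoms_per_chain + i + 1, "ALA", {"CB": tuple(xyz)}))
    return generate_fixture(spec, entry_id=f"RND{seed % 1000:03d}")
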