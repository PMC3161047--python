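"""Solvent accessible surface area and residue environment classification.

ASA is computed numerically by sphere-point sampling (Shrake-Rupley): each
heavy atom is expanded by the 1.4 Å probe radius and a deterministic
golden-spiral point set on its expanded sphere is tested for burial inside
any neighbouring expanded sphere; the accessible fraction of points times the
expanded-sphere area gives the atom's ASA in Å².

Interface size is the standard buried-surface difference
``ΔASA = ASA(A) + ASA(B) − ASA(AB)``.  Relative side-chain accessibility
expresses a residue's side-chain ASA in the complex as a percentage of the
same residue type's side-chain ASA in an extended Ala-X-Ala tripeptide;
residues are then classed into four structural environments by whether they
engage in inter-chain contacts and whether that relative accessibility is
below 7%: interface core, interface periphery, protein core and exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .contacts import ChainPair
from .structure import Residue, Structure

logger = logging.getLogger(__name__)

PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
REL_ASA_CORE_THRESHOLD = 7.0  # percent; strict "< 7" assigns the core classes

ENVIRONMENTS = ("interface_core", "interface_periphery", "core", "exposed")


@dataclass
class AsaResult:
    per_atom: dict[tuple, float]           # (residue id, atom name) -> Å²
    per_residue: dict[tuple, float]        # residue id -> total Å²
    per_residue_side: dict[tuple, float]   # residue id -> side-chain Å²
    per_residue_main: dict[tuple, float]
    per_chain: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.per_chain.values()))


@dataclass
class InterfaceArea:
    asa_a: float
    asa_b: float
    asa_ab: float

    @property
    def delta_asa(self) -> float:
        return self.asa_a + self.asa_b - self.asa_ab


@dataclass
class ResidueEnvironment:
    res: Residue
    interacting: bool
    rel_sc_asa: float
    environment: str


def _collect_atoms(s: Structure, chain_ids: set[str] | None):
    """Heavy polymer atoms with radii (waters and ligands excluded)."""
    entries = []
    for ch in s.chains:
        if chain_ids is not None and ch.chain_id not in chain_ids:
            continue
        for res in ch.residues:
            if not res.is_polymer:
                continue
            for atom in res.atoms:
                if atom.is_hydrogen:
                    continue
                if res.res_name in chem.STANDARD_AA:
                    r = chem.lookup(res.res_name, atom.name, atom.element).vdw_radius
                else:
                    r = chem.ELEMENT_DEFAULT_RADII.get(
                        atom.element, chem.ELEMENT_DEFAULT_RADII["C"]
                    )[0]
                entries.append((res, atom, r))
    return entries


def compute_asa(s: Structure, chain_ids: set[str] | None = None,
                probe: float = PROBE_RADIUS,
                n_points: int = DEFAULT_N_POINTS) -> AsaResult:
    """Shrake-Rupley ASA of the polymer atoms of ``s`` (optionally a chain
    subset), deterministic for a fixed ``n_points``."""
    from .geometry import sphere_points

    entries = _collect_atoms(s, chain_ids)
    if not entries:
        raise ValueError("no polymer atoms to compute ASA for")
    xyz = np.array([a.coord for _, a, _ in entries])
    radii = np.array([r + probe for _, _, r in entries])
    tree = cKDTree(xyz)
    unit_pts = sphere_points(n_points)
    max_r = radii.max()

    per_atom: dict[tuple, float] = {}
    per_res: dict[tuple, float] = {}
    per_res_side: dict[tuple, float] = {}
    per_res_main: dict[tuple, float] = {}
    per_chain: dict[str, float] = {}
    from .interactions import MAIN_CHAIN_ATOMS

    for idx, (res, atom, _) in enumerate(entries):
        ri = radii[idx]
        pts = xyz[idx] + ri * unit_pts
        neigh = [j for j in tree.query_ball_point(xyz[idx], ri + max_r) if j != idx]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neigh:
            if not accessible.any():
                break
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            accessible &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * ri**2 * accessible.sum() / n_points
        key = res.id
        per_atom[(key, atom.name)] = area
        per_res[key] = per_res.get(key, 0.0) + area
        is_side = atom.name not in MAIN_CHAIN_ATOMS or (
            res.res_name == "GLY" and atom.name == "CA"
        )
        if is_side:
            per_res_side[key] = per_res_side.get(key, 0.0) + area
        else:
            per_res_main[key] = per_res_main.get(key, 0.0) + area
        per_chain[res.chain_id] = per_chain.get(res.chain_id, 0.0) + area

    return AsaResult(per_atom, per_res, per_res_side, per_res_main, per_chain)


def interface_area(s: Structure, pair: ChainPair,
                   n_points: int = DEFAULT_N_POINTS) -> InterfaceArea:
    """Buried surface of a chain pair: three ASA calculations (A, B, AB)."""
    asa_a = compute_asa(s, {pair.chain_i}, n_points=n_points).total
    asa_b = compute_asa(s, {pair.chain_j}, n_points=n_points).total
    asa_ab = compute_asa(s, {pair.chain_i, pair.chain_j}, n_points=n_points).total
    return InterfaceArea(asa_a, asa_b, asa_ab)


@lru_cache(maxsize=32)
def reference_sidechain_asa(res_name: str, n_points: int = DEFAULT_N_POINTS) -> float:
    """Side-chain ASA of X in an extended Ala-X-Ala tripeptide (Å²).

    Computed once per residue type from a generated tripeptide; glycine uses
    the CA-as-side-chain convention.
    """
    from .fixtures import tripeptide_reference

    s = tripeptide_reference(res_name)
    result = compute_asa(s, n_points=n_points)
    mid = s.chains[0].residues[1]
    assert mid.res_name == res_name.upper()
    return result.per_residue_side.get(mid.id, 0.0)


def relative_accessibility(res: Residue, asa: AsaResult,
                           n_points: int = DEFAULT_N_POINTS) -> float:
    """Side-chain ASA as a percent of the Ala-X-Ala reference (may exceed
    100% for unusual conformations; never negative)."""
    ref = reference_sidechain_asa(res.res_name, n_points)
    if ref <= 0:
        logger.warning("zero reference side-chain ASA for %s", res.res_name)
        return 0.0
    return max(0.0, 100.0 * asa.per_residue_side.get(res.id, 0.0) / ref)


def classify_environment(interacting: bool, rel_sc_asa: float) -> str:
    buried = rel_sc_asa < REL_ASA_CORE_THRESHOLD
    if interacting:
        return "interface_core" if buried else "interface_periphery"
    return "core" if buried else "exposed"


def residue_environments(s: Structure, interacting_ids: set[tuple],
                         n_points: int = DEFAULT_N_POINTS) -> list[ResidueEnvironment]:
    """Classify every canonical polymer residue of the complex.

    ``interacting_ids`` holds residue ids with at least one inter-chain atom
    pair whose fingerprint has a flag besides proximal-only; accessibility is
    computed in the complex state.
    """
    asa = compute_asa(s, n_points=n_points)
    out = []
    for ch in s.chains:
        for res in ch.polymer_residues:
            if res.res_name not in chem.STANDARD_AA:
                continue
            rel = relative_accessibility(res, asa, n_points)
            inter = res.id in interacting_ids
            out.append(
                ResidueEnvironment(
                    res=res, interacting=inter, rel_sc_asa=rel,
                    environment=classify_environment(inter, rel),
                )
            )
    return out
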