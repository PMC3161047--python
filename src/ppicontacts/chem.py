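"""Residue-specific atomic radii and interaction-capability flags.

The 20 canonical residues (plus the chain-terminating OXT oxygen) are covered
by a bundled, versioned TSV table giving each heavy atom a van der Waals
radius, a covalent radius and a set of boolean capability flags (hydrophobic,
aromatic, cationic, anionic, hydrogen-bond donor/acceptor, aromatic
hydrogen-bond acceptor).  Radii follow the residue-specific CSD-derived set
used for protein volume calculations; flags encode fixed solution-state
chemistry at pH 7 (carboxylates deprotonated, amino groups protonated,
histidine imidazole optionally charged).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from importlib import resources

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Fallback vdW / covalent radii by element for atoms missing from the table.
ELEMENT_DEFAULT_RADII = {
    "C": (1.88, 0.77),
    "N": (1.64, 0.70),
    "O": (1.42, 0.66),
    "S": (1.77, 1.04),
    "SE": (1.77, 1.17),
}


@dataclass(frozen=True)
class AtomProperties:
    """Radii (Å) and interaction capabilities of one heavy atom."""

    vdw_radius: float
    cov_radius: float
    hydrophobic: bool = False
    aromatic: bool = False
    cationic: bool = False
    anionic: bool = False
    hb_donor: bool = False
    hb_acceptor: bool = False
    aromatic_hb_acceptor: bool = False


@dataclass(frozen=True)
class RingSystem:
    """An ordered planar ring (or fused-ring perimeter) of one residue type."""

    res_name: str
    atom_names: tuple[str, ...]


class UnknownResidueError(KeyError):
    """Raised for residue names outside the canonical 20; sanitize first."""


_RING_SYSTEMS: dict[str, tuple[RingSystem, ...]] = {
    # atom order traces the ring perimeter so Newell's method applies directly
    "PHE": (RingSystem("PHE", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),),
    "TYR": (RingSystem("TYR", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),),
    "HIS": (RingSystem("HIS", ("CG", "ND1", "CE1", "NE2", "CD2")),),
    # TRP: perimeter cycle of the fused indole system
    "TRP": (
        RingSystem(
            "TRP", ("CG", "CD1", "NE1", "CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2")
        ),
    ),
}


def _load_table() -> dict[tuple[str, str], AtomProperties]:
    table: dict[tuple[str, str], AtomProperties] = {}
    text = resources.files("ppicontacts.data").joinpath("atom_properties.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    for row in csv.DictReader(lines, delimiter="\t"):
        key = (row["res_name"], row["atom_name"])
        table[key] = AtomProperties(
            vdw_radius=float(row["vdw_radius"]),
            cov_radius=float(row["cov_radius"]),
            hydrophobic=row["hydrophobic"] == "1",
            aromatic=row["aromatic"] == "1",
            cationic=row["cationic"] == "1",
            anionic=row["anionic"] == "1",
            hb_donor=row["hb_donor"] == "1",
            hb_acceptor=row["hb_acceptor"] == "1",
            aromatic_hb_acceptor=row["aromatic_hb_acceptor"] == "1",
        )
    return table


_TABLE = _load_table()

# HIS imidazole nitrogens; their cationic flag is governed by `his_cationic`
_HIS_RING_N = {("HIS", "ND1"), ("HIS", "NE2"), ("HIS", "CG"), ("HIS", "CD2"), ("HIS", "CE1")}


def lookup(res_name: str, atom_name: str, element: str = "",
           his_cationic: bool = True) -> AtomProperties:
    """Look up the bundled properties of a residue's heavy atom.

    Unknown atoms of known residues fall back to element-level default radii
    with every capability flag off (logged).  Unknown residues raise
    :class:`UnknownResidueError` — run sanitization (modified-residue repair)
    first.

    ``his_cationic`` controls whether the histidine imidazole is treated as
    protonated (solution pKa near 7, on by default).
    """
    res_name = res_name.upper()
    if res_name not in STANDARD_AA:
        raise UnknownResidueError(
            f"residue {res_name!r} is not canonical; sanitize/repair the structure first"
        )
    props = _TABLE.get((res_name, atom_name.upper()))
    if props is None:
        elem = element.upper() or atom_name[:1].upper()
        radii = ELEMENT_DEFAULT_RADII.get(elem)
        if radii is None:
            radii = ELEMENT_DEFAULT_RADII["C"]
        logger.info(
            "unknown atom %s of residue %s: element-default radii, no capabilities",
            atom_name, res_name,
        )
        return AtomProperties(vdw_radius=radii[0], cov_radius=radii[1])
    if not his_cationic and (res_name, atom_name.upper()) in _HIS_RING_N and props.cationic:
        return replace(props, cationic=False)
    return props


def has_entry(res_name: str, atom_name: str) -> bool:
    return (res_name.upper(), atom_name.upper()) in _TABLE


def ring_systems(res_name: str) -> tuple[RingSystem, ...]:
    """Planar ring systems of a canonical residue (empty for non-aromatics)."""
    return _RING_SYSTEMS.get(res_name.upper(), ())


def residue_atom_names(res_name: str) -> tuple[str, ...]:
    """All heavy-atom names of ``res_name`` present in the bundled table."""
    return tuple(a for (r, a) in _TABLE if r == res_name.upper())
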