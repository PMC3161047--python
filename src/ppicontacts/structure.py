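"""Reading, sanitizing and writing PDB-format structures.

The PDB archive is heterogeneous: multi-model NMR ensembles, alternate
locations, hydrogens present or absent, insertion codes, lower-case or numeric
chain identifiers, waters, ligands and several hundred modified amino-acid
types.  This module parses PDB text losslessly into a small hierarchical
domain model (Structure → models → chains → residues → atoms) and provides a
"sanitize" step that normalizes a structure for contact analysis: keep the
first model and the highest-occupancy alternates, strip hydrogens and
(optionally) waters and ligands, and repair the three dominant modified
residues (MSE→MET, MLY→LYS, HYP→PRO) to their parent types.

Parsing and serialization are delegated to gemmi; the domain model keeps the
rest of the package independent of any one PDB toolkit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .chem import STANDARD_AA, residue_atom_names

logger = logging.getLogger(__name__)

WATER_NAMES = frozenset({"HOH", "DOD", "WAT", "H2O"})

#: Modified-residue repair map: parent residue plus atom renames.
#: MSE/MLY/HYP cover >90% of modified residues observed in the archive; the
#: map is extensible through :func:`register_modified_residue`.
MODIFIED_RESIDUES: dict[str, tuple[str, dict[str, str]]] = {
    "MSE": ("MET", {"SE": "SD"}),
    "MLY": ("LYS", {}),
    "HYP": ("PRO", {}),
}


def register_modified_residue(name: str, parent: str, renames: dict[str, str] | None = None) -> None:
    """Extend the repair map with an additional modified-residue type."""
    MODIFIED_RESIDUES[name.upper()] = (parent.upper(), dict(renames or {}))


class StructureParseError(ValueError):
    pass


class StructureWriteError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""
    is_hydrogen: bool = False
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureParseError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            logger.warning("atom %s occupancy %.3f clamped to [0,1]", self.name, self.occupancy)
            self.occupancy = min(max(self.occupancy, 0.0), 1.0)


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    @property
    def id(self) -> tuple[str, int, str]:
        """Author-numbering residue identity (chain, seq, insertion code)."""
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_polymer(self) -> bool:
        """Amino-acid residue judged by name or backbone content (not water)."""
        if self.is_water:
            return False
        if self.res_name in STANDARD_AA or self.res_name in MODIFIED_RESIDUES:
            return True
        names = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= names

    @property
    def is_ca_only(self) -> bool:
        heavy = {a.name for a in self.atoms if not a.is_hydrogen}
        return heavy == {"CA"}

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    @property
    def is_ca_only(self) -> bool:
        poly = self.polymer_residues
        return bool(poly) and all(r.is_ca_only for r in poly)


@dataclass
class Structure:
    entry_id: str = "XXXX"
    models: list[list[Chain]] = field(default_factory=list)
    resolution: float | None = None
    r_factor: float | None = None

    @property
    def chains(self) -> list[Chain]:
        """Chains of the first model."""
        return self.models[0] if self.models else []

    @property
    def has_polymer(self) -> bool:
        return any(ch.polymer_residues for ch in self.chains)

    def chain(self, chain_id: str) -> Chain | None:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        return None

    def iter_residues(self):
        for ch in self.chains:
            yield from ch.residues

    def iter_atoms(self):
        for res in self.iter_residues():
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())


@dataclass
class SanitizeOptions:
    keep_highest_occupancy: bool = True
    strip_hydrogens: bool = True
    first_model_only: bool = True
    strip_waters: bool = True
    strip_ligands: bool = True
    repair_modified: bool = True


_R_FACTOR_RE = re.compile(
    r"REMARK   3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)"
)


def read_structure(pdb_text: str, entry_id: str | None = None) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    The reader is lossless: all models, alternate locations and hydrogens are
    retained.  Resolution (REMARK 2) and R-factor (REMARK 3, working set) are
    captured when present.  A structure without any polymer residue is flagged
    (``has_polymer`` False) but accepted.
    """
    if not pdb_text or not pdb_text.strip():
        raise StructureParseError("empty PDB input (line 1)")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"unparseable PDB input: {exc}") from exc

    models: list[list[Chain]] = []
    for model in st:
        chains: list[Chain] = []
        for ch in model:
            chain = Chain(chain_id=ch.name)
            for res in ch:
                residue = Residue(
                    chain_id=ch.name,
                    res_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    res_name=res.name,
                    het=res.het_flag == "H",
                )
                for at in res:
                    residue.atoms.append(
                        Atom(
                            name=at.name,
                            element=at.element.name.upper(),
                            coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=at.occ,
                            alt_loc=at.altloc if at.altloc != "\x00" else "",
                            is_hydrogen=bool(at.element.is_hydrogen),
                            b_factor=at.b_iso,
                        )
                    )
                chain.residues.append(residue)
            chains.append(chain)
        models.append(chains)

    if sum(len(res.atoms) for chs in models for ch in chs for res in ch.residues) == 0:
        first = pdb_text.strip().splitlines()[0]
        raise StructureParseError(f"no ATOM/HETATM records (first line: {first!r})")

    resolution = st.resolution if st.resolution > 0 else None
    m = _R_FACTOR_RE.search(pdb_text)
    r_factor = float(m.group(1)) if m else None

    out = Structure(
        entry_id=entry_id or (st.name if st.name and st.name != "XXXX" else "XXXX"),
        models=models,
        resolution=resolution,
        r_factor=r_factor,
    )
    if not out.has_polymer:
        logger.warning("structure %s contains no polymer residues", out.entry_id)
    return out


def _select_alternates(res: Residue) -> Residue:
    """Keep one atom per atom name: highest occupancy, ties to the
    alphabetically first alt_loc."""
    best: dict[str, Atom] = {}
    for atom in res.atoms:
        cur = best.get(atom.name)
        if (
            cur is None
            or atom.occupancy > cur.occupancy
            or (atom.occupancy == cur.occupancy and atom.alt_loc < cur.alt_loc)
        ):
            best[atom.name] = atom
    kept = []
    seen = set()
    for atom in res.atoms:  # preserve original atom order
        if atom.name not in seen and best[atom.name] is atom:
            kept.append(replace(atom, alt_loc=""))
            seen.add(atom.name)
        elif atom.name not in seen and best[atom.name] is not atom:
            kept.append(replace(best[atom.name], alt_loc=""))
            seen.add(atom.name)
    return replace(res, atoms=kept)


def _repair_residue(res: Residue) -> Residue:
    entry = MODIFIED_RESIDUES.get(res.res_name)
    if entry is None:
        if res.het and not res.is_water and {"N", "CA", "C"} <= {a.name for a in res.atoms}:
            logger.info("unknown modified residue %s %s kept unchanged", res.res_name, res.id)
        return res
    parent, renames = entry
    allowed = set(residue_atom_names(parent))
    atoms = []
    for atom in res.atoms:
        name = renames.get(atom.name, atom.name)
        if atom.is_hydrogen or name in allowed:
            element = atom.element
            if atom.name in renames:
                element = name[:1]
            atoms.append(replace(atom, name=name, element=element))
        else:
            logger.info(
                "repair %s->%s: dropping atom %s of %s", res.res_name, parent, atom.name, res.id
            )
    logger.info("repaired %s -> %s at %s", res.res_name, parent, res.id)
    return replace(res, res_name=parent, het=False, atoms=atoms)


def sanitize(s: Structure, opts: SanitizeOptions | None = None) -> Structure:
    """Normalize a parsed structure for downstream contact analysis."""
    opts = opts or SanitizeOptions()
    models = s.models[:1] if opts.first_model_only else s.models
    new_models: list[list[Chain]] = []
    for chains in models:
        new_chains: list[Chain] = []
        for ch in chains:
            residues: list[Residue] = []
            for res in ch.residues:
                r = res
                if opts.repair_modified:
                    r = _repair_residue(r)
                if opts.strip_waters and r.is_water:
                    logger.info("removed water %s", r.id)
                    continue
                if opts.strip_ligands and not r.is_polymer and not r.is_water:
                    logger.info("removed ligand %s %s", r.res_name, r.id)
                    continue
                if opts.keep_highest_occupancy:
                    r = _select_alternates(r)
                if opts.strip_hydrogens:
                    r = replace(r, atoms=[a for a in r.atoms if not a.is_hydrogen])
                residues.append(r)
            if residues:
                new_chains.append(Chain(chain_id=ch.chain_id, residues=residues))
        new_models.append(new_chains)
    out = replace(s, models=new_models)
    for ch in out.chains:
        if ch.is_ca_only:
            logger.warning("chain %s is Calpha-only; side-chain contacts unavailable", ch.chain_id)
    return out


def write_structure(s: Structure) -> str:
    """Serialize a sanitized structure to fixed-column PDB text.

    Raises on an empty structure and on chain identifiers wider than the
    single-character PDB chain column (use the assembly chain-map TSV for
    expanded assemblies instead).
    """
    if s.n_atoms == 0:
        raise StructureWriteError("refusing to write a structure with 0 atoms")
    wide = [ch.chain_id for chains in s.models for ch in chains if len(ch.chain_id) > 1]
    if wide:
        raise StructureWriteError(
            f"chain id(s) {sorted(set(wide))} exceed the PDB chain column; "
            "write TSV outputs and the assembly chain map instead"
        )
    st = gemmi.Structure()
    st.name = s.entry_id
    if s.resolution is not None:
        st.resolution = s.resolution
    for i, chains in enumerate(s.models, start=1):
        model = gemmi.Model(i)
        for ch in chains:
            gch = gemmi.Chain(ch.chain_id)
            for res in ch.residues:
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.seqid = gemmi.SeqId(res.res_seq, res.icode or " ")
                gres.het_flag = "H" if res.het or res.is_water else "A"
                for atom in res.atoms:
                    gat = gemmi.Atom()
                    gat.name = atom.name
                    gat.element = gemmi.Element(atom.element)
                    gat.pos = gemmi.Position(*atom.coord)
                    gat.occ = atom.occupancy
                    gat.b_iso = atom.b_factor
                    if atom.alt_loc:
                        gat.altloc = atom.alt_loc
                    gres.add_atom(gat)
                gch.add_residue(gres)
            model.add_chain(gch)
        st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if s.r_factor is not None:
        text = (
            f"REMARK   3   R VALUE            (WORKING SET) : {s.r_factor:.3f}\n" + text
        )
    return text
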