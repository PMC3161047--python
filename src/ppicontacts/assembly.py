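"""Quaternary-structure generation from an ASU plus an assembly specification.

Crystallographic coordinate files contain the asymmetric unit, which often
differs from the biologically functional oligomer.  This module consumes a
PISA-style XML description of predicted assemblies — rotation-translation
operations per source chain, ranked assembly sets and a stability label —
keeps only the top-ranked set's assemblies labelled "stable in solution",
assigns waters to their nearest polymer chain (5 Å rule, before any
transformation) and expands the ASU into assembly coordinates while
maintaining a chain-identifier map.
"""

from __future__ import annotations

import logging
import string
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structure import Chain, Residue, Structure

logger = logging.getLogger(__name__)

STABLE_LABEL = "stable in solution"
WATER_ASSIGN_CUTOFF = 5.0


@dataclass
class AssemblyOperation:
    source_chain: str
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3
    new_chain_id: str


@dataclass
class AssemblySpec:
    entry_id: str
    assembly_id: str
    assembly_set_rank: int
    stability_label: str
    operations: list[AssemblyOperation] = field(default_factory=list)


@dataclass
class ChainMap:
    pairs: list[tuple[str, str]]  # (asu chain id, assembly chain id)


class AssemblySpecError(ValueError):
    pass


_ID_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _next_chain_id(used: set[str]) -> str:
    for c in _ID_ALPHABET:
        if c not in used:
            return c
    i = 0
    while True:  # multi-character internal ids beyond 62 chains
        for c in _ID_ALPHABET:
            cand = f"{c}{i}"
            if cand not in used:
                return cand
        i += 1


def parse_assembly_spec(xml_text: str) -> list[AssemblySpec]:
    """Parse a PISA-dialect assembly XML into :class:`AssemblySpec` records.

    Expected layout: ``<pisa_assemblies><pdb_entry><pdb_code>..</pdb_code>
    <asm_set><ser_no>1</ser_no><assembly><id>..</id><stability>..</stability>
    <molecule><chain_id>A</chain_id><rxx>..</rxx>..<tz>..</tz>
    [<new_chain_id>..</new_chain_id>]</molecule>..</assembly>..</asm_set>
    ..</pdb_entry></pisa_assemblies>``.
    """
    root = ET.fromstring(xml_text)
    specs: list[AssemblySpec] = []
    entries = root.findall(".//pdb_entry") or [root]
    for entry in entries:
        code = entry.findtext("pdb_code", default="XXXX").strip()
        for asm_set in entry.findall("asm_set"):
            rank = int(asm_set.findtext("ser_no", default="1"))
            for asm in asm_set.findall("assembly"):
                asm_id = asm.findtext("id", default="1").strip()
                label = (asm.findtext("stability") or "").strip()
                spec = AssemblySpec(
                    entry_id=code, assembly_id=asm_id,
                    assembly_set_rank=rank, stability_label=label,
                )
                used: set[str] = set()
                for mol in asm.findall("molecule"):
                    chain = (mol.findtext("chain_id") or "").strip()
                    try:
                        r = np.array(
                            [
                                [float(mol.findtext(f"r{a}{b}")) for b in "xyz"]
                                for a in "xyz"
                            ]
                        )
                        t = np.array([float(mol.findtext(f"t{a}")) for a in "xyz"])
                    except (TypeError, ValueError) as exc:
                        raise AssemblySpecError(
                            f"malformed matrix for assembly {code}/{asm_id}, chain {chain}"
                        ) from exc
                    if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
                        raise AssemblySpecError(
                            f"non-orthonormal rotation for assembly {code}/{asm_id}, chain {chain}"
                        )
                    new_id = (mol.findtext("new_chain_id") or "").strip()
                    if not new_id:
                        new_id = chain if chain not in used else _next_chain_id(used)
                    if new_id in used:
                        raise AssemblySpecError(
                            f"duplicate assembly chain id {new_id!r} in {code}/{asm_id}"
                        )
                    used.add(new_id)
                    spec.operations.append(AssemblyOperation(chain, r, t, new_id))
                specs.append(spec)
    if not specs or all(not sp.operations for sp in specs):
        logger.warning("assembly specification contains no operations")
    return specs


def select_stable(specs: list[AssemblySpec]) -> list[AssemblySpec]:
    """Keep only rank-1 assembly-set members labelled stable in solution.

    A rank-1 set may legitimately contain several assemblies (distinct
    biological units in one ASU); all of its stable members are retained.
    """
    return [
        sp
        for sp in specs
        if sp.assembly_set_rank == 1 and sp.stability_label.lower() == STABLE_LABEL
    ]


def assign_waters(s: Structure, cutoff: float = WATER_ASSIGN_CUTOFF) -> Structure:
    """Re-chain each water to the nearest polymer chain within ``cutoff`` Å.

    Applied before any assembly transformation so waters ride along with
    their host chain.  Exact distance ties break alphanumerically; waters
    beyond the cutoff from every chain stay on their original chain.
    """
    polymer_chains = [ch for ch in s.chains if ch.polymer_residues]
    trees = []
    for ch in sorted(polymer_chains, key=lambda c: c.chain_id):
        xyz = np.array(
            [a.coord for r in ch.polymer_residues for a in r.atoms if not a.is_hydrogen]
        )
        if len(xyz):
            trees.append((ch.chain_id, cKDTree(xyz)))

    new_chains: dict[str, Chain] = {}
    order: list[str] = []

    def _chain(cid: str) -> Chain:
        if cid not in new_chains:
            new_chains[cid] = Chain(chain_id=cid)
            order.append(cid)
        return new_chains[cid]

    for ch in s.chains:
        for res in ch.residues:
            target = ch.chain_id
            if res.is_water and trees:
                coords = np.array([a.coord for a in res.atoms])
                best = None
                for cid, tree in trees:
                    d = float(np.min(tree.query(coords)[0]))
                    if d < cutoff and (best is None or d < best[0] - 1e-12):
                        best = (d, cid)
                if best is not None:
                    target = best[1]
            moved = replace(res, chain_id=target) if target != res.chain_id else res
            _chain(target).residues.append(moved)

    return replace(s, models=[[new_chains[cid] for cid in order]])


def apply_assembly(s: Structure, spec: AssemblySpec) -> tuple[Structure, ChainMap]:
    """Expand the ASU with the spec's rigid-body operations.

    Each operation produces a transformed copy of its source chain under the
    operation's new chain id; intra-chain geometry is preserved exactly.
    """
    chains: list[Chain] = []
    mapping: list[tuple[str, str]] = []
    for op in spec.operations:
        src = s.chain(op.source_chain)
        if src is None:
            raise ValueError(
                f"assembly {spec.entry_id}/{spec.assembly_id}: missing source chain "
                f"{op.source_chain!r}"
            )
        residues = []
        for res in src.residues:
            atoms = [
                replace(a, coord=op.rotation @ a.coord + op.translation)
                for a in res.atoms
            ]
            residues.append(replace(res, chain_id=op.new_chain_id, atoms=atoms))
        chains.append(Chain(chain_id=op.new_chain_id, residues=residues))
        mapping.append((op.source_chain, op.new_chain_id))
    out = replace(s, models=[chains])
    return out, ChainMap(pairs=mapping)
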