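"""Chain-pair enumeration and radial proximal-pair search.

For n polymer chains, all n(n-1)/2 alphanumerically ordered chain pairs are
examined.  Within a pair, every inter-chain atom pair closer than the search
radius (default 6.05 Å, the maximum length of a water-mediated hydrogen bond)
is flagged proximal.  The search uses a kd-tree; results are identical to a
brute-force double loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Residue, Structure

DEFAULT_RADIUS = 6.05


@dataclass(frozen=True)
class ChainPair:
    chain_i: str
    chain_j: str

    def __post_init__(self):
        if self.chain_i == self.chain_j:
            raise ValueError("chain pair requires two distinct chains")
        if self.chain_i > self.chain_j:
            raise ValueError("chain pair must be ordered alphanumerically")


@dataclass
class ProximalPair:
    """An ordered inter-chain atom pair within the search radius."""

    res_i: Residue
    atom_i: Atom
    res_j: Residue
    atom_j: Atom
    distance: float


def enumerate_chain_pairs(s: Structure) -> list[ChainPair]:
    """All unique alphanumerically ordered pairs of polymer chains."""
    ids = sorted(ch.chain_id for ch in s.chains if ch.polymer_residues)
    return [
        ChainPair(ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]


def _chain_atoms(s: Structure, chain_id: str) -> list[tuple[Residue, Atom]]:
    chain = s.chain(chain_id)
    if chain is None:
        return []
    out = []
    for res in chain.residues:
        if not res.is_polymer:
            continue  # waters and ligands are handled by dedicated passes
        for atom in res.atoms:
            if not atom.is_hydrogen:
                out.append((res, atom))
    return out


def find_proximal_pairs(
    s: Structure, pair: ChainPair, radius: float = DEFAULT_RADIUS
) -> list[ProximalPair]:
    """All inter-chain atom pairs with d < ``radius`` (strict boundary)."""
    atoms_i = _chain_atoms(s, pair.chain_i)
    atoms_j = _chain_atoms(s, pair.chain_j)
    if not atoms_i or not atoms_j:
        return []
    xyz_i = np.array([a.coord for _, a in atoms_i])
    xyz_j = np.array([a.coord for _, a in atoms_j])
    tree_j = cKDTree(xyz_j)
    out: list[ProximalPair] = []
    for ii, neighbours in enumerate(cKDTree(xyz_i).query_ball_tree(tree_j, r=radius)):
        for jj in neighbours:
            d = float(np.linalg.norm(xyz_i[ii] - xyz_j[jj]))
            if d < radius:  # query_ball_tree includes the boundary; we exclude it
                res_i, atom_i = atoms_i[ii]
                res_j, atom_j = atoms_j[jj]
                out.append(ProximalPair(res_i, atom_i, res_j, atom_j, d))
    out.sort(key=lambda p: (p.res_i.id, p.atom_i.name, p.res_j.id, p.atom_j.name))
    return out
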