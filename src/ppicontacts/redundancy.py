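"""Interface filtering, redundancy clustering and representative selection.

The structure archive is highly redundant: the same complex is solved many
times.  Interfaces are first filtered — trivial peripheral contacts
(R_i x R_j <= 25 interface residues) and short peptide chains (< 15 valid
residues) are removed — then grouped by the ordered pair of UniProt
accessions of the two sides and co-clustered whenever BOTH sides share
strictly more than 75% of their unique UniProt residue positions with
another interface (single-linkage closure).  One representative per cluster
is kept: the interface from the highest-quality structure, ranked by an
empirical score in which resolution dominates R-factor and the proportion of
missing internal residues.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .structure import Structure

logger = logging.getLogger(__name__)

MIN_CHAIN_LENGTH = 15
PRODUCT_THRESHOLD = 25
OVERLAP_THRESHOLD = 0.75

#: penalties standing in for header values absent from NMR entries
MISSING_RESOLUTION_PENALTY = 100.0
MISSING_R_FACTOR = 0.4
R_FACTOR_WEIGHT = 10.0


@dataclass
class InterfaceRecord:
    entry_id: str
    chain_pair: tuple[str, str]
    residues_i: frozenset
    residues_j: frozenset
    chain_len_i: int
    chain_len_j: int
    uniprot_i: str | None = None
    uniprot_j: str | None = None
    uniprot_positions_i: frozenset = field(default_factory=frozenset)
    uniprot_positions_j: frozenset = field(default_factory=frozenset)
    quality: float = 0.0

    @property
    def r_i(self) -> int:
        return len(self.residues_i)

    @property
    def r_j(self) -> int:
        return len(self.residues_j)

    @property
    def key(self) -> tuple:
        return (self.entry_id, self.chain_pair)

    @property
    def uniprot_pair(self) -> tuple[str, str] | None:
        """Ordered UniProt pair; for homotypic interfaces the side order is
        fixed by chain id so the "ordered combination" is stable."""
        if self.uniprot_i is None or self.uniprot_j is None:
            return None
        return tuple(sorted((self.uniprot_i, self.uniprot_j)))

    def sides_by_uniprot(self) -> tuple[frozenset, frozenset]:
        """Position sets ordered consistently with :attr:`uniprot_pair`."""
        if self.uniprot_pair is None:
            return self.uniprot_positions_i, self.uniprot_positions_j
        if (self.uniprot_i, self.uniprot_j) == self.uniprot_pair:
            return self.uniprot_positions_i, self.uniprot_positions_j
        return self.uniprot_positions_j, self.uniprot_positions_i


@dataclass
class QualityScore:
    resolution: float | None
    r_factor: float | None
    missing_fraction: float
    score: float


def filter_interfaces(records: list[InterfaceRecord],
                      min_chain_len: int = MIN_CHAIN_LENGTH,
                      product_threshold: int = PRODUCT_THRESHOLD) -> list[InterfaceRecord]:
    """Drop trivial interfaces (R_i x R_j <= threshold) and short peptides."""
    out = []
    for rec in records:
        if rec.r_i * rec.r_j <= product_threshold:
            logger.info("filtered %s: Ri*Rj = %d", rec.key, rec.r_i * rec.r_j)
            continue
        if rec.chain_len_i < min_chain_len or rec.chain_len_j < min_chain_len:
            logger.info("filtered %s: peptide chain", rec.key)
            continue
        out.append(rec)
    return out


def _overlap(a: frozenset, b: frozenset, mode: str) -> float:
    if not a and not b:
        return 1.0
    inter = len(a & b)
    if mode == "jaccard":
        denom = len(a | b)
    elif mode == "min":
        denom = min(len(a), len(b)) or 1
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return inter / denom if denom else 0.0


def reciprocal_overlap(a: InterfaceRecord, b: InterfaceRecord,
                       mode: str = "jaccard") -> tuple[float, float]:
    """Per-side fraction of shared unique UniProt residue positions.

    Symmetric by construction; ``mode`` selects the denominator (Jaccard
    |A∩B|/|A∪B| by default, or the smaller set's size with ``"min"``).
    """
    ai, aj = a.sides_by_uniprot()
    bi, bj = b.sides_by_uniprot()
    return _overlap(ai, bi, mode), _overlap(aj, bj, mode)


def cluster_interfaces(records: list[InterfaceRecord],
                       threshold: float = OVERLAP_THRESHOLD,
                       mode: str = "jaccard") -> list[list[InterfaceRecord]]:
    """Partition interfaces into redundancy clusters.

    Within each UniProt-pair group, two interfaces are co-clustered when both
    reciprocal overlaps exceed ``threshold`` strictly; clusters are the
    connected components of that relation.  Records without a UniProt mapping
    cannot be compared and each forms its own cluster.
    """
    graph = nx.Graph()
    groups: dict[tuple, list[InterfaceRecord]] = {}
    for rec in records:
        graph.add_node(rec.key)
        up = rec.uniprot_pair
        if up is None:
            logger.info("no UniProt mapping for %s: kept as its own cluster", rec.key)
            continue
        groups.setdefault(up, []).append(rec)
    for members in groups.values():
        for a, b in itertools.combinations(members, 2):
            fi, fj = reciprocal_overlap(a, b, mode)
            if fi > threshold and fj > threshold:
                graph.add_edge(a.key, b.key)
    by_key = {rec.key: rec for rec in records}
    clusters = [
        sorted((by_key[k] for k in comp), key=lambda r: r.key)
        for comp in nx.connected_components(graph)
    ]
    clusters.sort(key=lambda c: c[0].key)
    return clusters


def missing_internal_fraction(s: Structure) -> float:
    """Proportion of internal residues absent from the coordinates, judged
    from author-numbering gaps (terminal disorder is invisible and excluded)."""
    missing = 0
    expected = 0
    for ch in s.chains:
        poly = [r for r in ch.polymer_residues if not r.icode]
        if len(poly) < 2:
            expected += len(poly)
            continue
        nums = sorted({r.res_seq for r in poly})
        span = nums[-1] - nums[0] + 1
        expected += span
        missing += span - len(nums)
    return missing / expected if expected else 0.0


def quality_score(s: Structure) -> QualityScore:
    """Empirical structure-quality score; higher is better.

    ``score = -(resolution + 10*r_factor + M)`` with absent resolution
    heavily penalized (NMR entries rank below any X-ray structure) and
    absent R-factor imputed pessimistically.
    """
    m = missing_internal_fraction(s)
    res = s.resolution if s.resolution is not None else MISSING_RESOLUTION_PENALTY
    rf = s.r_factor if s.r_factor is not None else MISSING_R_FACTOR
    return QualityScore(
        resolution=s.resolution, r_factor=s.r_factor, missing_fraction=m,
        score=-(res + R_FACTOR_WEIGHT * rf + m),
    )


def select_representatives(clusters: list[list[InterfaceRecord]]) -> list[InterfaceRecord]:
    """Highest-quality member of each cluster; ties break to the
    lexicographically smallest (entry, chain pair)."""
    out = []
    for cluster in clusters:
        best = min(cluster, key=lambda r: (-r.quality, r.key))
        out.append(best)
    out.sort(key=lambda r: r.key)
    return out
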