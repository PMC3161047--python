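"""Interface filtering, overlap clustering and representative selection."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ppicontacts.redundancy import (
    InterfaceRecord,
    cluster_interfaces,
    filter_interfaces,
    missing_internal_fraction,
    quality_score,
    reciprocal_overlap,
    select_representatives,
)
from ppicontacts.structure import read_structure


def _record(entry="1abc", chains=("A", "B"), n_i=8, n_j=8, len_i=100, len_j=100,
            up=("P11111", "P22222"), pos_i=None, pos_j=None, quality=0.0):
    pos_i = frozenset(pos_i if pos_i is not None else range(1, n_i + 1))
    pos_j = frozenset(pos_j if pos_j is not None else range(1, n_j + 1))
    return InterfaceRecord(
        entry_id=entry, chain_pair=chains,
        residues_i=frozenset(range(n_i)), residues_j=frozenset(range(n_j)),
        chain_len_i=len_i, chain_len_j=len_j,
        uniprot_i=up[0], uniprot_j=up[1],
        uniprot_positions_i=pos_i, uniprot_positions_j=pos_j,
        quality=quality,
    )


class TestFiltering:
    def test_product_of_25_removed_30_kept(self):
        removed = _record(n_i=5, n_j=5)
        kept = _record(entry="2abc", n_i=5, n_j=6)
        out = filter_interfaces([removed, kept])
        assert [r.entry_id for r in out] == ["2abc"]

    def test_short_peptide_removed_regardless_of_product(self):
        rec = _record(n_i=10, n_j=10, len_i=14)
        assert filter_interfaces([rec]) == []

    def test_filter_order_independence(self):
        records = [
            _record(entry=f"{i}xyz", n_i=i, n_j=8, len_i=10 + i, len_j=100)
            for i in range(2, 12)
        ]
        by_product_first = filter_interfaces(
            filter_interfaces(records, min_chain_len=0), product_threshold=-1
        )
        by_length_first = filter_interfaces(
            filter_interfaces(records, product_threshold=-1), min_chain_len=0
        )
        assert [r.key for r in by_product_first] == [r.key for r in by_length_first]


class TestOverlap:
    def test_identical_sets_full_overlap(self):
        a, b = _record(), _record(entry="2abc")
        assert reciprocal_overlap(a, b) == (1.0, 1.0)

    def test_disjoint_side_scores_zero(self):
        a = _record(pos_i=range(10))
        b = _record(entry="2abc", pos_i=range(100, 110))
        fi, fj = reciprocal_overlap(a, b)
        assert fi == 0.0 and fj == 1.0

    def test_symmetric(self):
        a = _record(pos_i=range(10), pos_j=range(5))
        b = _record(entry="2abc", pos_i=range(5, 15), pos_j=range(3, 8))
        assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)

    @settings(derandomize=True, max_examples=50)
    @given(
        pos=st.tuples(
            st.frozensets(st.integers(1, 40), min_size=1),
            st.frozensets(st.integers(1, 40), min_size=1),
            st.frozensets(st.integers(1, 40), min_size=1),
            st.frozensets(st.integers(1, 40), min_size=1),
        )
    )
    def test_overlap_bounds_symmetry_and_mode_ordering(self, pos):
        a = _record(pos_i=pos[0], pos_j=pos[1])
        b = _record(entry="2abc", pos_i=pos[2], pos_j=pos[3])
        for mode in ("jaccard", "min"):
            fi, fj = reciprocal_overlap(a, b, mode)
            assert 0.0 <= fi <= 1.0 and 0.0 <= fj <= 1.0
            assert (fi, fj) == reciprocal_overlap(b, a, mode)
        # the min-set denominator can only raise the fraction
        ja = reciprocal_overlap(a, b, "jaccard")
        mi = reciprocal_overlap(a, b, "min")
        assert mi[0] >= ja[0] and mi[1] >= ja[1]

    def test_min_denominator_mode(self):
        a = _record(pos_i=range(10))
        b = _record(entry="2abc", pos_i=range(5))
        fi_j, _ = reciprocal_overlap(a, b, mode="jaccard")
        fi_m, _ = reciprocal_overlap(a, b, mode="min")
        assert fi_j == 0.5 and fi_m == 1.0


class TestClustering:
    def test_exact_75_percent_not_co_clustered(self):
        # |A∩B| / |A∪B| = 18/24 = 0.75 exactly on both sides: strict boundary
        a = _record(pos_i=range(21), pos_j=range(21))
        b = _record(entry="2abc", pos_i=range(3, 24), pos_j=range(3, 24))
        fi, fj = reciprocal_overlap(a, b)
        assert fi == pytest.approx(0.75) and fj == pytest.approx(0.75)
        clusters = cluster_interfaces([a, b])
        assert len(clusters) == 2

    def test_above_threshold_co_clustered(self):
        a = _record(pos_i=range(20), pos_j=range(20))
        b = _record(entry="2abc", pos_i=range(1, 21), pos_j=range(1, 21))
        assert len(cluster_interfaces([a, b])) == 1

    def test_single_linkage_closure_matches_component_search(self):
        # A~B and B~C overlap; A~C do not: one cluster {A,B,C} by closure
        a = _record(entry="1aaa", pos_i=range(0, 20), pos_j=range(20))
        b = _record(entry="2bbb", pos_i=range(2, 22), pos_j=range(20))
        c = _record(entry="3ccc", pos_i=range(4, 24), pos_j=range(20))
        records = [a, b, c]
        fi_ac, _ = reciprocal_overlap(a, c)
        assert fi_ac < 0.75  # A and C alone would not merge

        # explicit component search oracle
        adj = {r.key: set() for r in records}
        for x, y in itertools.combinations(records, 2):
            fi, fj = reciprocal_overlap(x, y)
            if fi > 0.75 and fj > 0.75:
                adj[x.key].add(y.key)
                adj[y.key].add(x.key)
        seen, components = set(), []
        for r in records:
            if r.key in seen:
                continue
            stack, comp = [r.key], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            components.append(comp)

        clusters = cluster_interfaces(records)
        got = sorted(frozenset(r.key for r in cl) for cl in clusters)
        assert got == sorted(frozenset(c) for c in components)
        assert len(clusters) == 1  # transitive closure merges all three

    def test_different_uniprot_pairs_never_co_clustered(self):
        a = _record()
        b = _record(entry="2abc", up=("P33333", "P44444"))
        assert len(cluster_interfaces([a, b])) == 2

    def test_missing_uniprot_forms_own_cluster(self):
        a = _record(up=(None, None))
        b = _record(entry="2abc", up=(None, None))
        assert len(cluster_interfaces([a, b])) == 2

    def test_clustering_partitions_records(self):
        records = [
            _record(entry=f"{i}abc", pos_i=range(i, i + 20), pos_j=range(20))
            for i in range(8)
        ]
        clusters = cluster_interfaces(records)
        flat = [r.key for cl in clusters for r in cl]
        assert sorted(flat) == sorted(r.key for r in records)


def _structure_with(resolution=None, r_factor=None, gap=False):
    seqs = [1, 2, 3, 6, 7] if gap else [1, 2, 3, 4, 5]
    lines = []
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.")
    if r_factor is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : {r_factor:.3f}")
    serial = 1
    for seq in seqs:
        for name, dx in (("N", 0.0), ("CA", 1.4), ("C", 2.0), ("O", 3.0)):
            x = seq * 5.0 + dx
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} GLY A{seq:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           {name[0]}"
            )
            serial += 1
    lines.append("END")
    return read_structure("\n".join(lines))


class TestQuality:
    def test_resolution_dominates(self):
        # over the realistic R-factor range (~0.15-0.25) a large resolution
        # gap always outweighs an opposing R-factor gap
        good = quality_score(_structure_with(resolution=1.5, r_factor=0.25))
        bad = quality_score(_structure_with(resolution=3.0, r_factor=0.16))
        assert good.score > bad.score

    def test_fewer_missing_residues_score_higher(self):
        full = quality_score(_structure_with(resolution=2.0, r_factor=0.2))
        gappy = quality_score(_structure_with(resolution=2.0, r_factor=0.2, gap=True))
        assert full.missing_fraction == 0.0
        assert gappy.missing_fraction > 0.0
        assert full.score > gappy.score

    def test_xray_outranks_nmr(self):
        nmr = quality_score(_structure_with())  # no resolution, no R-factor
        xray = quality_score(_structure_with(resolution=2.0, r_factor=0.2))
        assert xray.score > nmr.score

    def test_internal_gap_counting_excludes_termini(self):
        s = _structure_with(gap=True)  # residues 1,2,3,6,7 -> 2 missing of 7
        assert missing_internal_fraction(s) == pytest.approx(2 / 7)


class TestRepresentatives:
    def test_singleton_cluster_returns_itself(self):
        rec = _record()
        assert select_representatives([[rec]]) == [rec]

    def test_best_quality_wins(self):
        lo = _record(entry="1lo", quality=-3.0)
        hi = _record(entry="1hi", quality=-1.5)
        assert select_representatives([[lo, hi]]) == [hi]

    def test_exact_tie_breaks_lexicographically(self):
        a = _record(entry="1aaa", quality=-2.0)
        b = _record(entry="1bbb", quality=-2.0)
        assert select_representatives([[b, a]]) == [a]

    def test_representatives_are_interfaces_not_assemblies(self):
        # two interfaces of one entry may both be representatives of their
        # own clusters (non-redundant set of interfaces, not assemblies)
        ab = _record(entry="1abc", chains=("A", "B"))
        cd = _record(entry="1abc", chains=("C", "D"), up=("P55555", "P66666"))
        reps = select_representatives(cluster_interfaces([ab, cd]))
        assert {r.chain_pair for r in reps} == {("A", "B"), ("C", "D")}
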