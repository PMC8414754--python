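"""Alignment DP, coordinate maps, and neighbor joining."""
import functools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sixscan.io_core import SixscanError
from sixscan.msa import (AlignScheme, MultipleAlignment, map_column,
                         map_position, neighbor_joining,
                         pairwise_global_align, progressive_align)

from conftest import random_dna

SCHEME = AlignScheme(match=1, mismatch=-1, gap=-1)


def brute_force_global_score(a: str, b: str, scheme: AlignScheme) -> float:
    """Exponential recursive oracle for the optimal global alignment score."""
    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -1e18
        if i < len(a) and j < len(b):
            s = scheme.match if a[i] == b[j] else scheme.mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, scheme.gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, scheme.gap + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestPairwise:
    def test_identical_no_gaps(self):
        ga, gb, score = pairwise_global_align("ACGT", "ACGT", SCHEME)
        assert (ga, gb) == ("ACGT", "ACGT") and score == 4

    def test_single_deletion(self):
        ga, gb, score = pairwise_global_align("ACGT", "AGT", SCHEME)
        assert score == 2
        assert ga.replace("-", "") == "ACGT" and gb.replace("-", "") == "AGT"
        assert gb.count("-") - ga.count("-") == 1

    def test_empty_vs_sequence(self):
        ga, gb, score = pairwise_global_align("", "ACG", SCHEME)
        assert ga == "---" and gb == "ACG" and score == -3

    @given(st.text(alphabet="ACGT", max_size=9),
           st.text(alphabet="ACGT", max_size=9))
    def test_score_matches_recursive_oracle(self, a, b):
        _, _, score = pairwise_global_align(a, b, SCHEME)
        assert score == brute_force_global_score(a, b, SCHEME)


class TestProgressive:
    def test_identical_sequences_gap_free(self):
        aln = progressive_align([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")])
        assert aln.rows == ["ACGT"] * 3

    def test_degap_invariant(self, rng):
        seqs = [(f"s{i}", random_dna(rng, int(rng.integers(20, 40))))
                for i in range(6)]
        aln = progressive_align(seqs)
        for sid, s in seqs:
            assert aln.degapped(sid) == s

    def test_two_sequences_reduce_to_pairwise(self):
        a, b = "ACGTACGT", "ACGACGT"
        scheme = AlignScheme()
        aln = progressive_align([("a", a), ("b", b)], scheme=scheme)
        ga, gb, _ = pairwise_global_align(a, b, scheme)
        assert aln.rows == [ga, gb]

    def test_single_sequence_trivial(self):
        aln = progressive_align([("a", "ACGT")])
        assert aln.rows == ["ACGT"]


class TestColumnMaps:
    def test_forward_map_counts_through_gaps(self):
        aln = MultipleAlignment(["r"], ["AC-GT"])
        assert map_position(aln, "r", 2) == 3  # the G

    def test_inverse_of_residue_column(self):
        aln = MultipleAlignment(["r"], ["AC-GT"])
        assert map_column(aln, "r", 3) == (2, True)

    def test_inverse_of_gap_column_nearest_left_inexact(self):
        aln = MultipleAlignment(["r"], ["AC-GT"])
        assert map_column(aln, "r", 2) == (1, False)

    def test_round_trip_on_non_gap_columns(self, rng):
        seqs = [(f"s{i}", random_dna(rng, 25)) for i in range(4)]
        aln = progressive_align(seqs)
        for sid, s in seqs:
            for pos in range(len(s)):
                col = map_position(aln, sid, pos)
                assert map_column(aln, sid, col) == (pos, True)

    def test_out_of_range_rejected(self):
        aln = MultipleAlignment(["r"], ["ACGT"])
        with pytest.raises(SixscanError):
            map_position(aln, "r", 4)


def random_additive_tree(rng, n):
    """A random binary tree with positive branch lengths and its leaf
    distance matrix (additive by construction)."""
    nodes = list(range(n))
    dist = {(i, i): 0.0 for i in range(n)}
    paths = {i: {i: 0.0} for i in range(n)}  # node -> leaf -> distance
    leaves = {i: [i] for i in range(n)}
    next_id = n
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la = round(float(rng.uniform(0.1, 2.0)), 3)
        lb = round(float(rng.uniform(0.1, 2.0)), 3)
        for leaf_a, da in paths[a].items():
            for leaf_b, db in paths[b].items():
                dist[tuple(sorted((leaf_a, leaf_b)))] = da + la + db + lb
        merged = {}
        merged.update({l: d + la for l, d in paths[a].items()})
        merged.update({l: d + lb for l, d in paths[b].items()})
        paths[next_id] = merged
        leaves[next_id] = leaves[a] + leaves[b]
        nodes = [x for x in nodes if x not in (a, b)] + [next_id]
        next_id += 1
    D = np.zeros((n, n))
    for (i, j), d in dist.items():
        D[i, j] = D[j, i] = d
    return D


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree, _ = neighbor_joining(["A", "B", "C"], D)
        lengths = {c.label: l for c, l in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("n", [4, 5, 6, 8])
    def test_additive_matrix_recovered_exactly(self, n):
        rng = np.random.default_rng(40 + n)
        D = random_additive_tree(rng, n)
        labels = [f"t{i}" for i in range(n)]
        tree, _ = neighbor_joining(labels, D)
        paths = tree.leaf_distances()
        for i in range(n):
            for j in range(i + 1, n):
                assert paths[(f"t{i}", f"t{j}")] == pytest.approx(
                    D[i, j], abs=1e-9)

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(7)
        n = 6
        D = random_additive_tree(rng, n)
        labels = [f"t{i}" for i in range(n)]
        ours, _ = neighbor_joining(labels, D)
        theirs = skbio_nj(DistanceMatrix(D, labels))
        ours_d = ours.leaf_distances()
        for i in range(n):
            for j in range(i + 1, n):
                a, b = f"t{i}", f"t{j}"
                assert ours_d[(a, b)] == pytest.approx(
                    theirs.find(a).distance(theirs.find(b)), abs=1e-6)

    def test_identical_points_zero_star(self):
        D = np.zeros((4, 4))
        tree, _ = neighbor_joining(list("ABCD"), D)
        assert all(d == pytest.approx(0.0, abs=1e-12)
                   for d in tree.leaf_distances().values())
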