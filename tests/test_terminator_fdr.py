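"""Dinucleotide shuffle, hairpin scoring, and the adaptive threshold rule."""
import math
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from sixscan.io_core import Genome, SixscanError, revcomp
from sixscan.terminator_fdr import (TerminatorParams, adaptive_threshold,
                                    call_terminators, dinucleotide_shuffle,
                                    merge_overlapping_terminators,
                                    score_terminators)

from conftest import random_dna


class TestDinucleotideShuffle:
    def test_homopolymer_unchanged(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    def test_unique_eulerian_arrangement(self):
        # edges {AC, CG, GT} starting at A admit exactly one walk
        assert dinucleotide_shuffle("ACGT", seed=123) == "ACGT"

    def test_too_short_rejected(self):
        with pytest.raises(SixscanError):
            dinucleotide_shuffle("A", seed=0)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=200),
           st.integers(0, 1000))
    def test_preserves_dinucleotides_and_ends(self, seq, seed):
        out = dinucleotide_shuffle(seq, seed)
        assert len(out) == len(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]
        assert Counter(zip(out, out[1:])) == Counter(zip(seq, seq[1:]))

    def test_actually_shuffles(self, rng):
        seq = random_dna(rng, 500)
        outs = {dinucleotide_shuffle(seq, s) for s in range(5)}
        assert len(outs) > 1


def brute_force_hairpins(seq: str, params: TerminatorParams):
    """Independent cubic enumeration of maximal-stem hairpins, one strand."""
    found = set()
    n = len(seq)
    for loop_start in range(n):
        for loop_len in range(params.loop_min, params.loop_max + 1):
            # extend outward checking maximality explicitly
            pairs = []
            k = 0
            while True:
                i, j = loop_start - 1 - k, loop_start + loop_len + k
                if i < 0 or j >= n:
                    break
                p = params.pair_score(seq[i], seq[j])
                if p is None:
                    break
                pairs.append(p)
                k += 1
            if len(pairs) >= params.min_stem:
                i = loop_start - len(pairs)
                j = loop_start + loop_len + len(pairs)
                u = seq[j:j + params.utract_len].count("T")
                score = (sum(pairs)
                         - params.loop_penalty * (loop_len - params.loop_min)
                         + u)
                found.add((i, j, len(pairs), loop_len, score))
    return found


class TestScoreTerminators:
    def test_worked_example(self):
        cands = score_terminators(Genome("g", "GGGGGAAAACCCCCTTTTTTTT"))
        best = max((c for c in cands if c.strand == "+"),
                   key=lambda c: c.score)
        assert (best.stem_len, best.loop_len) == (5, 4)
        assert best.score == pytest.approx(15 - 0.5 + 8)

    def test_homopolymer_has_no_candidates(self):
        assert score_terminators(Genome("g", "A" * 60)) == []

    def test_matches_brute_force_enumeration(self, rng):
        params = TerminatorParams()
        seq = random_dna(rng, 500)
        cands = score_terminators(Genome("g", seq), params)
        got_plus = {(c.hairpin_start, c.hairpin_end, c.stem_len, c.loop_len,
                     c.score) for c in cands if c.strand == "+"}
        assert got_plus == brute_force_hairpins(seq, params)
        rc = revcomp(seq)
        n = len(seq)
        got_minus = {(n - j, n - i, st_, ll, sc)
                     for i, j, st_, ll, sc in brute_force_hairpins(rc, params)}
        assert got_minus == {(c.hairpin_start, c.hairpin_end, c.stem_len,
                              c.loop_len, c.score)
                             for c in cands if c.strand == "-"}


class TestAdaptiveThreshold:
    def test_worked_example_boundary(self):
        # 100 original hits at score >= 90: the mean shuffled count at >= 90
        # may not exceed 5
        ok = adaptive_threshold([90.0] * 100, [[90.0] * 5] * 10)
        assert ok.threshold == 90.0
        assert ok.n_original_above == 100
        assert ok.mean_shuffled_above == 5.0
        too_many = adaptive_threshold([90.0] * 100, [[90.0] * 6] * 10)
        assert math.isinf(too_many.threshold)

    def test_empty_shuffles_accept_everything(self):
        res = adaptive_threshold([5.0, 9.0, 2.0], [[], [], []])
        assert res.threshold == 2.0 and res.n_original_above == 3

    def test_two_level_example(self):
        original = [10.0] * 20 + [5.0] * 80
        shuffled = [[10.0] * 1 + [5.0] * 39, [5.0] * 1]  # means: 0.5 @>=10, 20 @>=5
        res = adaptive_threshold(original, shuffled, fraction=0.05)
        assert res.threshold == 10.0
        assert res.n_original_above == 20
        assert res.mean_shuffled_above == 0.5

    def test_invalid_fraction_rejected(self):
        with pytest.raises(SixscanError):
            adaptive_threshold([1.0], [[1.0]], fraction=0.0)

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=30),
           st.lists(st.lists(st.integers(0, 20), max_size=30),
                    min_size=1, max_size=5))
    def test_threshold_monotone_in_fraction(self, orig, shuf):
        orig = [float(x) for x in orig]
        shuf = [[float(x) for x in lst] for lst in shuf]
        t_small = adaptive_threshold(orig, shuf, fraction=0.05).threshold
        t_large = adaptive_threshold(orig, shuf, fraction=0.5).threshold
        assert t_large <= t_small

    def test_invariant_when_finite(self):
        res = adaptive_threshold([3.0, 7.0, 9.0], [[3.0, 8.0], [2.0]],
                                 fraction=0.5)
        if math.isfinite(res.threshold):
            assert res.mean_shuffled_above <= 0.5 * res.n_original_above


class TestMergeOverlapping:
    def _cand(self, s, e, score, strand="+"):
        from sixscan.terminator_fdr import TerminatorCandidate
        return TerminatorCandidate("g", s, e, strand, 5, 4, score)

    def test_nested_keeps_higher_score(self):
        out = merge_overlapping_terminators(
            [self._cand(10, 40, 12.0), self._cand(15, 30, 20.0)])
        assert [(c.hairpin_start, c.hairpin_end, c.score) for c in out] \
            == [(15, 30, 20.0)]

    def test_disjoint_unchanged(self):
        out = merge_overlapping_terminators(
            [self._cand(0, 10, 5.0), self._cand(20, 30, 6.0)])
        assert len(out) == 2

    def test_chain_collapses_to_one(self):
        out = merge_overlapping_terminators(
            [self._cand(0, 12, 5.0), self._cand(10, 22, 9.0),
             self._cand(20, 32, 7.0)])
        assert len(out) == 1 and out[0].score == 9.0

    def test_strands_independent(self):
        out = merge_overlapping_terminators(
            [self._cand(0, 12, 5.0), self._cand(5, 15, 6.0, strand="-")])
        assert len(out) == 2


def test_planted_terminator_accepted(rng):
    from sixscan.synthetic_data import TERMINATOR_SEQ
    seq = random_dna(rng, 1500) + TERMINATOR_SEQ + random_dna(rng, 1500)
    res = call_terminators(Genome("g", seq), seed=5)
    start = 1500
    assert math.isfinite(res.threshold)
    assert any(c.hairpin_start >= start - 2
               and c.hairpin_end <= start + len(TERMINATOR_SEQ) + 2
               for c in res.accepted)
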