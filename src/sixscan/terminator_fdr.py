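"""Rho-independent terminator calls with a shuffled-genome adaptive threshold.

A deliberately simple, fully specified hairpin scorer proposes candidate
terminators (inverted repeat with a 3-10 nt loop, G-U wobble allowed,
scored as stem pairing + U-tract bonus - loop penalty).  Significance is
the study's own contribution and is reproduced exactly: each genome is
shuffled ten times preserving its mono- and dinucleotide composition, all
shuffles are re-scored, and the acceptance threshold is the smallest
candidate score t such that the mean number of shuffled-genome candidates
scoring >= t is at most 5% of the number of original candidates scoring
>= t.  If we find 100 hits at or above score 90 in the genome, the
average count at or above 90 in the shuffles may not exceed 5, otherwise
a higher threshold is chosen; in the absence of tool-provided p-values
this roughly emulates a 0.05 significance level.

The shuffle is the Altschul-Erikson Eulerian-walk construction, which
samples uniformly among sequences with exactly the same 16 dinucleotide
counts (hence also mononucleotide counts) and the same first and last
character.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import Genome, SixscanError, revcomp

__all__ = [
    "TerminatorParams",
    "TerminatorCandidate",
    "AdaptiveThresholdResult",
    "dinucleotide_shuffle",
    "score_terminators",
    "adaptive_threshold",
    "merge_overlapping_terminators",
    "call_terminators",
]


@dataclass(frozen=True)
class TerminatorParams:
    """Hairpin scorer weights; only the thresholding rule is study-specific,
    so these are plain configuration."""

    min_stem: int = 4
    loop_min: int = 3
    loop_max: int = 10
    pair_gc: float = 3.0
    pair_at: float = 2.0
    pair_gt: float = 1.0
    loop_penalty: float = 0.5
    utract_len: int = 8

    def pair_score(self, a: str, b: str) -> float | None:
        pair = a + b
        if pair in ("GC", "CG"):
            return self.pair_gc
        if pair in ("AT", "TA"):
            return self.pair_at
        if pair in ("GT", "TG"):
            return self.pair_gt
        return None


@dataclass
class TerminatorCandidate:
    """A scored hairpin candidate (coordinates on the forward strand)."""

    genome_id: str
    hairpin_start: int
    hairpin_end: int
    strand: str
    stem_len: int
    loop_len: int
    score: float


@dataclass
class AdaptiveThresholdResult:
    threshold: float                 # +inf when no threshold qualifies
    n_original_above: int
    mean_shuffled_above: float
    accepted: list[TerminatorCandidate] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Uniform dinucleotide-preserving shuffle (Altschul-Erikson).

    The output has exactly the input's mono- and dinucleotide multisets and
    preserves the first and last characters.  Edge multisets per source
    character are shuffled, a random last-edge choice is retried until the
    chosen last edges form a tree into the final character (the condition
    for every edge ordering to admit an Eulerian walk), and the walk is
    read off.  Deterministic given the seed.
    """
    if len(seq) < 2:
        raise SixscanError("cannot shuffle a sequence shorter than 2")
    rng = np.random.default_rng(seed)
    chars = sorted(set(seq))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    sources = [c for c in chars if c != last and edges[c]]

    if any(edges[c] for c in chars):
        while True:
            # pick a candidate final edge per non-terminal source vertex
            final_edge = {c: edges[c][rng.integers(len(edges[c]))]
                          for c in sources}
            # the final edges must lead every source into `last`
            ok = True
            for c in sources:
                seen = {c}
                cur = c
                while cur != last:
                    cur = final_edge.get(cur)
                    if cur is None or cur in seen:
                        ok = False
                        break
                    seen.add(cur)
                if not ok:
                    break
            if ok:
                break
    else:
        final_edge = {}

    shuffled: dict[str, list[str]] = {}
    for c in chars:
        pool = list(edges[c])
        if c in final_edge:
            pool.remove(final_edge[c])
        order = rng.permutation(len(pool))
        pool = [pool[i] for i in order]
        if c in final_edge:
            pool.append(final_edge[c])
        shuffled[c] = pool

    out = [seq[0]]
    counters = {c: 0 for c in chars}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# Hairpin candidates
# ---------------------------------------------------------------------------

def _scan_forward(seq: str, gid: str, strand: str, n_total: int,
                  params: TerminatorParams) -> list[TerminatorCandidate]:
    n = len(seq)
    out = []
    for loop_start in range(1, n):
        for loop_len in range(params.loop_min, params.loop_max + 1):
            i = loop_start - 1
            j = loop_start + loop_len
            score = 0.0
            stem = 0
            while i >= 0 and j < n:
                p = params.pair_score(seq[i], seq[j])
                if p is None:
                    break
                score += p
                stem += 1
                i -= 1
                j += 1
            if stem < params.min_stem:
                continue
            hp_start, hp_end = i + 1, j
            utract = seq[hp_end:hp_end + params.utract_len].count("T")
            total = score - params.loop_penalty * (loop_len - params.loop_min) \
                + utract
            if strand == "+":
                s, e = hp_start, hp_end
            else:  # map back to forward coordinates
                s, e = n_total - hp_end, n_total - hp_start
            out.append(TerminatorCandidate(gid, s, e, strand, stem,
                                           loop_len, total))
    return out


def score_terminators(genome: Genome,
                      params: TerminatorParams = TerminatorParams()
                      ) -> list[TerminatorCandidate]:
    """All maximal-stem hairpin candidates on both strands.

    For every (loop position, loop length) pair the stem is extended
    outward as far as it pairs (Watson-Crick plus G-U wobble) and reported
    once at its maximal length when that reaches ``min_stem``.  The score
    is stem pairing (G-C 3, A-T 2, G-T 1) minus 0.5 per loop nucleotide
    beyond 3, plus the count of T in the 8 nt 3' of the hairpin.
    Deterministic; candidates are sorted by coordinates.
    """
    n = len(genome.seq)
    cands = _scan_forward(genome.seq, genome.id, "+", n, params)
    cands += _scan_forward(revcomp(genome.seq), genome.id, "-", n, params)
    cands.sort(key=lambda c: (c.hairpin_start, c.hairpin_end, c.strand,
                              c.loop_len))
    return cands


# ---------------------------------------------------------------------------
# Adaptive threshold
# ---------------------------------------------------------------------------

def adaptive_threshold(original_scores: Sequence[float],
                       shuffled_score_lists: Sequence[Sequence[float]],
                       fraction: float = 0.05) -> AdaptiveThresholdResult:
    """Smallest observed score t with mean shuffled count(>=t) <=
    fraction * original count(>=t).

    Candidate thresholds are the distinct original scores in ascending
    order ("at or above" includes ties); any threshold between two observed
    values selects the same hit sets, so nothing else needs testing.  When
    no candidate qualifies the threshold is +inf and nothing is accepted.
    """
    if not (0 < fraction <= 1):
        raise SixscanError("fraction must lie in (0, 1]")
    if len(shuffled_score_lists) < 1:
        raise SixscanError("need at least one shuffled score list")
    orig = np.asarray(sorted(original_scores), dtype=float)
    shuffled = [np.asarray(sorted(lst), dtype=float)
                for lst in shuffled_score_lists]
    n_shuf = len(shuffled)
    for t in sorted(set(original_scores)):
        n_orig = int(orig.size - np.searchsorted(orig, t, side="left"))
        mean_shuf = sum(
            s.size - np.searchsorted(s, t, side="left") for s in shuffled
        ) / n_shuf
        if mean_shuf <= fraction * n_orig:
            return AdaptiveThresholdResult(
                threshold=float(t), n_original_above=n_orig,
                mean_shuffled_above=float(mean_shuf))
    return AdaptiveThresholdResult(threshold=math.inf, n_original_above=0,
                                   mean_shuffled_above=0.0)


def merge_overlapping_terminators(cands: Sequence[TerminatorCandidate]
                                  ) -> list[TerminatorCandidate]:
    """Merge same-strand overlapping candidates, keeping the coordinates and
    score of the highest-scoring member of each overlap chain."""
    by_strand: dict[tuple[str, str], list[TerminatorCandidate]] = {}
    for c in cands:
        by_strand.setdefault((c.genome_id, c.strand), []).append(c)
    out: list[TerminatorCandidate] = []
    for group in by_strand.values():
        group.sort(key=lambda c: (c.hairpin_start, c.hairpin_end))
        chain: list[TerminatorCandidate] = []
        chain_end = -1
        for c in group:
            if chain and c.hairpin_start >= chain_end:
                out.append(max(chain, key=lambda x: (x.score, -x.hairpin_start)))
                chain = []
                chain_end = -1
            chain.append(c)
            chain_end = max(chain_end, c.hairpin_end)
        if chain:
            out.append(max(chain, key=lambda x: (x.score, -x.hairpin_start)))
    out.sort(key=lambda c: (c.hairpin_start, c.hairpin_end, c.strand))
    return out


def call_terminators(genome: Genome, n_shuffles: int = 10,
                     fraction: float = 0.05, seed: int = 0,
                     params: TerminatorParams = TerminatorParams()
                     ) -> AdaptiveThresholdResult:
    """Full per-genome procedure: score, shuffle n times, re-score, threshold.

    The accepted candidates (score >= threshold) are merged by overlap.
    """
    cands = score_terminators(genome, params)
    if not cands:
        return AdaptiveThresholdResult(math.inf, 0, 0.0, [])
    rng = np.random.default_rng(seed)
    shuffled_lists = []
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(genome.seq, int(rng.integers(0, 2**31 - 1)))
        shuffled_lists.append(
            [c.score for c in score_terminators(
                Genome(id=genome.id, seq=shuf), params)])
    result = adaptive_threshold([c.score for c in cands], shuffled_lists,
                                fraction)
    if math.isfinite(result.threshold):
        result.accepted = merge_overlapping_terminators(
            [c for c in cands if c.score >= result.threshold])
    return result
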