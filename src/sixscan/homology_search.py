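"""Seeded ungapped local similarity search with analytic significance.

This is the pipeline's search engine: exact k-mer seeds are extended
ungapped in both directions with an x-drop rule, and each hit gets an
e-value from ungapped Karlin–Altschul statistics,

    E = K * m * n * exp(-lambda * S),

where ``lambda`` is the unique positive root of
``sum_ij p_i p_j exp(lambda * s_ij) = 1`` for the match/mismatch scheme
under the background base composition.  Keeping the alignment ungapped
makes this significance exact rather than an empirical fit; sensitivity to
co-linear gapped homology is recovered downstream by joining overlapping
segments.

Post-processing implements the study's hit rules: overlapping same-strand
hits are joined transitively, at most one best hit is accepted per genome,
and tiered e-value thresholds gate each pipeline stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .io_core import Genome, SixscanError, revcomp

__all__ = [
    "ScoringScheme",
    "Hit",
    "solve_lambda",
    "search",
    "join_overlapping",
    "best_hit_per_genome",
    "filter_by_evalue",
]

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def solve_lambda(match: int, mismatch: int,
                 background: Sequence[float]) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda*s_ij) = 1, to 1e-10 rel. tol.

    Requires a negative expected per-position score under the background
    (otherwise no positive root exists and local-alignment statistics do
    not apply).
    """
    p = np.asarray(background, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
        raise SixscanError("background must be 4 nonnegative reals summing to 1")
    p_match = float((p * p).sum())
    p_mismatch = 1.0 - p_match
    expected = p_match * match + p_mismatch * mismatch
    if expected >= 0:
        raise SixscanError(
            f"expected per-position score {expected:.4g} is non-negative; "
            "choose a scheme with negative drift")
    if match <= 0:
        raise SixscanError("match score must be positive")

    def f(lam: float) -> float:
        return (p_match * math.exp(lam * match)
                + p_mismatch * math.exp(lam * mismatch) - 1.0)

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, rtol=1e-12, maxiter=200))


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores plus the derived Karlin–Altschul parameters.

    ``K`` scales all e-values by a constant and is a configuration
    constant (default 0.1) rather than being computed by series expansion;
    thresholds are calibrated with it in mind.
    """

    match: int = 1
    mismatch: int = -1
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    K: float = 0.1
    lam: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lam", solve_lambda(self.match, self.mismatch, self.background))

    def evalue(self, score: int, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


@dataclass
class Hit:
    """A scored, stranded interval on a target genome."""

    genome_id: str
    query_id: str
    start: int
    end: int
    strand: str
    raw_score: int
    evalue: float

    def length(self) -> int:
        return self.end - self.start


def _sort_key(h: Hit):
    return (h.evalue, -h.raw_score, h.start, 0 if h.strand == "+" else 1)


def _extend_runs(q: np.ndarray, t: np.ndarray, diag: int, seed_len: int,
                 match: int, mismatch: int, x_drop: float):
    """Maximal-scoring ungapped extensions of every exact-match run >= seed_len
    on one diagonal.  Yields (q_start, q_end, score) in overlap coordinates.

    The extension on each side walks until the running score drops ``x_drop``
    below its maximum, then the hit boundary is the maximal prefix/suffix
    (smallest right endpoint / largest left endpoint on ties, i.e. the
    shortest interval attaining the maximum).
    """
    i0 = max(0, -diag)
    i1 = min(len(q), len(t) - diag)
    if i1 - i0 < seed_len:
        return
    qa = q[i0:i1]
    ta = t[i0 + diag:i1 + diag]
    matches = qa == ta
    score = np.where(matches, match, mismatch).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(score)])  # segment [a,b) = P[b]-P[a]

    # maximal runs of consecutive matches
    padded = np.concatenate([[False], matches, [False]]).astype(np.int8)
    delta = np.diff(padded)
    starts = np.flatnonzero(delta == 1)
    ends = np.flatnonzero(delta == -1)
    for rs, re_ in zip(starts, ends):
        if re_ - rs < seed_len:
            continue
        # rightwards: choose b >= re_ maximizing P[b], x-drop limited
        sub = prefix[re_:]
        cummax = np.maximum.accumulate(sub)
        dropped = np.flatnonzero(sub < cummax - x_drop)
        stop = dropped[0] if dropped.size else sub.size
        b = re_ + int(np.argmax(sub[:stop]))
        # leftwards: choose a <= rs minimizing P[a]; ties -> largest a
        sub2 = prefix[rs::-1]
        cummin = np.minimum.accumulate(sub2)
        dropped2 = np.flatnonzero(sub2 > cummin + x_drop)
        stop2 = dropped2[0] if dropped2.size else sub2.size
        a = rs - int(np.argmin(sub2[:stop2]))
        yield i0 + a, i0 + b, int(prefix[b] - prefix[a])


def _search_one_strand(qseq: str, t: np.ndarray, seed_len: int):
    """Candidate (diag set) discovery via an exact k-mer index of the query."""
    index: dict[str, list[int]] = {}
    for i in range(len(qseq) - seed_len + 1):
        index.setdefault(qseq[i:i + seed_len], []).append(i)
    return index


def search(query: Genome, target: Genome, scheme: ScoringScheme,
           seed_len: int = 11, x_drop: float = 20.0) -> list[Hit]:
    """Search both strands of ``target`` for local ungapped matches to ``query``.

    Exact ``seed_len``-mer matches are extended ungapped in both directions;
    the hit is the maximal-scoring extension, and its e-value is
    ``K*m*n*exp(-lambda*S)`` with m, n the query and target lengths.  The
    reverse strand is searched with the reverse complement of the query and
    reported with strand '-'.  Hits are sorted by e-value (deterministic
    tie-breaking by score, position, strand).
    """
    if seed_len < 4:
        raise SixscanError("seed_len must be >= 4")
    t = _encode(target.seq)
    tseq = target.seq
    m, n = len(query.seq), len(target.seq)
    hits: dict[tuple[int, int, str], Hit] = {}
    for strand, qseq in (("+", query.seq), ("-", revcomp(query.seq))):
        if len(qseq) < seed_len:
            continue
        q = _encode(qseq)
        index = _search_one_strand(qseq, t, seed_len)
        diagonals: set[int] = set()
        for j in range(n - seed_len + 1):
            kmer = tseq[j:j + seed_len]
            for i in index.get(kmer, ()):
                diagonals.add(j - i)
        for diag in diagonals:
            for qa, qb, score in _extend_runs(
                    q, t, diag, seed_len, scheme.match, scheme.mismatch, x_drop):
                ts, te = qa + diag, qb + diag
                key = (ts, te, strand)
                if key not in hits or hits[key].raw_score < score:
                    hits[key] = Hit(
                        genome_id=target.id, query_id=query.id,
                        start=ts, end=te, strand=strand,
                        raw_score=score, evalue=scheme.evalue(score, m, n))
    return sorted(hits.values(), key=_sort_key)


def join_overlapping(hits: Iterable[Hit]) -> list[Hit]:
    """Transitively merge same-strand hits whose intervals overlap by >= 1 nt.

    The merged hit spans the union; it keeps the maximal member score and
    the minimal member e-value.
    """
    by_group: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        by_group.setdefault((h.genome_id, h.strand), []).append(h)
    merged: list[Hit] = []
    for (_gid, _strand), group in by_group.items():
        group.sort(key=lambda h: (h.start, h.end))
        current = None
        for h in group:
            if current is None or h.start >= current.end:
                if current is not None:
                    merged.append(current)
                current = Hit(**vars(h))
            else:
                current.end = max(current.end, h.end)
                current.raw_score = max(current.raw_score, h.raw_score)
                if h.evalue < current.evalue:
                    current.evalue = h.evalue
                    current.query_id = h.query_id
        if current is not None:
            merged.append(current)
    return sorted(merged, key=_sort_key)


def best_hit_per_genome(hits: Sequence[Hit]) -> Hit | None:
    """The single most significant hit, or None when the list is empty.

    Ties on e-value are broken by higher raw score, then leftmost start,
    then + strand, so the choice is deterministic.
    """
    if not hits:
        return None
    gids = {h.genome_id for h in hits}
    if len(gids) > 1:
        raise SixscanError(f"hits span multiple genomes: {sorted(gids)}")
    return min(hits, key=_sort_key)


def filter_by_evalue(hits: Iterable[Hit], threshold: float) -> list[Hit]:
    """Keep hits with evalue <= threshold, preserving order."""
    if threshold <= 0:
        raise SixscanError("e-value threshold must be > 0")
    return [h for h in hits if h.evalue <= threshold]
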