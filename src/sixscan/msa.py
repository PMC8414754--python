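"""Progressive multiple alignment and alignment-column coordinate maps.

Sequence-only progressive alignment: a neighbor-joining guide tree is built
on pairwise distances (1 - identity of optimal pairwise alignments), and
profiles are merged leaf-to-root by profile-profile dynamic programming
with average-of-pairs column scoring under a linear gap penalty.  Once a
gap has been introduced into a profile it is never removed ("once a gap,
always a gap").

This replaces a structure-aware RNA aligner: for the >=70%-identity 6S
sequence sets the pipeline handles, sequence alignment is sufficient for
coordinate projection, and that simplification is the single largest one
in the package (see docs/methods.md).

The module also houses the neighbor-joining implementation (Saitou-Nei,
deterministic tie-breaking by taxon order) because the aligner needs it
for its guide tree; the pRNA module reuses it for its tree of pRNA
sequences.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import edlib
import numpy as np

from .io_core import GAP, SixscanError

__all__ = [
    "AlignScheme",
    "MultipleAlignment",
    "ColumnMap",
    "pairwise_global_align",
    "progressive_align",
    "map_position",
    "map_column",
    "PhyloNode",
    "neighbor_joining",
    "write_aligned_fasta",
    "write_stockholm",
]


@dataclass(frozen=True)
class AlignScheme:
    """Linear gap-penalty global alignment parameters."""

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0


_BASES = "ACGT" + GAP
_BASE_INDEX = {c: i for i, c in enumerate(_BASES)}


def _pair_score_matrix(scheme: AlignScheme) -> np.ndarray:
    """5x5 residue/gap scoring used for average-of-pairs profile columns."""
    M = np.full((5, 5), scheme.mismatch)
    for i in range(4):
        M[i, i] = scheme.match
    M[4, :] = scheme.gap
    M[:, 4] = scheme.gap
    M[4, 4] = 0.0
    return M


@dataclass
class MultipleAlignment:
    """Gapped rows of equal length; degapping row i recovers input i exactly."""

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise SixscanError("alignment rows differ in length")
        if len(self.row_ids) != len(self.rows):
            raise SixscanError("row_ids and rows differ in count")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.row_ids.index(row_id)]
        except ValueError:
            raise SixscanError(f"no alignment row {row_id!r}") from None

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")


@dataclass
class ColumnMap:
    """Bidirectional ungapped-position <-> alignment-column maps for one row."""

    to_column: np.ndarray    # ungapped index -> column
    to_ungapped: np.ndarray  # column -> ungapped index of residue, or nearest left
    exact: np.ndarray        # column -> True when the column holds a residue

    @classmethod
    def from_row(cls, row: str) -> "ColumnMap":
        to_column = []
        to_ungapped = np.empty(len(row), dtype=np.int64)
        exact = np.zeros(len(row), dtype=bool)
        u = -1
        for c, ch in enumerate(row):
            if ch != GAP:
                u += 1
                to_column.append(c)
                exact[c] = True
            to_ungapped[c] = u
        return cls(np.asarray(to_column, dtype=np.int64), to_ungapped, exact)


def map_position(aln: MultipleAlignment, row_id: str, ungapped_pos: int) -> int:
    """Alignment column holding residue ``ungapped_pos`` (0-based) of a row."""
    cmap = ColumnMap.from_row(aln.row(row_id))
    if not (0 <= ungapped_pos < len(cmap.to_column)):
        raise SixscanError(
            f"position {ungapped_pos} out of range for row {row_id!r}")
    return int(cmap.to_column[ungapped_pos])


def map_column(aln: MultipleAlignment, row_id: str, column: int) -> tuple[int, bool]:
    """Inverse of :func:`map_position`: ``(ungapped_index, exact)``.

    For a gap column the nearest residue to the left is returned and the
    flag is False (inexact).  A gap column before the first residue maps to
    ungapped index 0, also inexact.
    """
    cmap = ColumnMap.from_row(aln.row(row_id))
    if not (0 <= column < len(cmap.to_ungapped)):
        raise SixscanError(f"column {column} out of range for row {row_id!r}")
    u = int(cmap.to_ungapped[column])
    exact = bool(cmap.exact[column])
    return (max(u, 0), exact)


# ---------------------------------------------------------------------------
# Pairwise and profile dynamic programming
# ---------------------------------------------------------------------------

def _needleman_wunsch(S: np.ndarray, gap_a: np.ndarray, gap_b: np.ndarray):
    """Global DP over a precomputed column-score matrix.

    ``S[i, j]`` scores pairing item i of A with item j of B; ``gap_a[i]``
    is the cost of aligning A's item i against a gap (and symmetrically for
    ``gap_b``).  Traceback tie-breaking prefers diagonal, then up
    (consume A), then left (consume B), so the alignment is deterministic.
    Returns (path, score) where path is a list of (i|None, j|None).
    """
    la, lb = S.shape
    D = np.empty((la + 1, lb + 1))
    D[0, 0] = 0.0
    D[1:, 0] = np.cumsum(gap_a)
    D[0, 1:] = np.cumsum(gap_b)
    for i in range(1, la + 1):
        row = D[i]
        prev = D[i - 1]
        srow = S[i - 1]
        ga = gap_a[i - 1]
        for j in range(1, lb + 1):
            row[j] = max(prev[j - 1] + srow[j - 1],
                         prev[j] + ga,
                         row[j - 1] + gap_b[j - 1])
    path: list[tuple[int | None, int | None]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + S[i - 1, j - 1]:
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + gap_a[i - 1]:
            path.append((i - 1, None))
            i -= 1
        else:
            path.append((None, j - 1))
            j -= 1
    path.reverse()
    return path, float(D[la, lb])


def pairwise_global_align(a: str, b: str,
                          scheme: AlignScheme = AlignScheme()
                          ) -> tuple[str, str, float]:
    """Optimal global alignment under a linear gap penalty.

    Deterministic tie-breaking: diagonal, then a gap in ``b``, then a gap
    in ``a``.
    """
    S = np.where(
        (np.frombuffer(a.encode(), np.uint8)[:, None]
         == np.frombuffer(b.encode(), np.uint8)[None, :]),
        scheme.match, scheme.mismatch) if a and b else np.zeros((len(a), len(b)))
    gap_a = np.full(len(a), scheme.gap)
    gap_b = np.full(len(b), scheme.gap)
    path, score = _needleman_wunsch(S, gap_a, gap_b)
    ga = "".join(a[i] if i is not None else GAP for i, _ in path)
    gb = "".join(b[j] if j is not None else GAP for _, j in path)
    return ga, gb, score


class _Profile:
    """Rows plus per-column base/gap counts for average-of-pairs scoring."""

    def __init__(self, row_ids: list[str], rows: list[str]):
        self.row_ids = row_ids
        self.rows = rows
        L = len(rows[0])
        counts = np.zeros((L, 5))
        for r in rows:
            idx = np.fromiter((_BASE_INDEX[c] for c in r), dtype=np.int64,
                              count=L)
            np.add.at(counts, (np.arange(L), idx), 1.0)
        self.counts = counts

    def __len__(self) -> int:
        return self.counts.shape[0]


def _merge_profiles(pa: _Profile, pb: _Profile, scheme: AlignScheme) -> _Profile:
    M = _pair_score_matrix(scheme)
    na, nb = len(pa.rows), len(pb.rows)
    S = (pa.counts @ M @ pb.counts.T) / (na * nb)
    # aligning a column against an all-gap column costs `gap` per residue
    gap_a = (pa.counts[:, :4].sum(axis=1) * scheme.gap) / na
    gap_b = (pb.counts[:, :4].sum(axis=1) * scheme.gap) / nb
    path, _ = _needleman_wunsch(S, gap_a, gap_b)
    rows_a = ["".join(r[i] if i is not None else GAP for i, _ in path)
              for r in pa.rows]
    rows_b = ["".join(r[j] if j is not None else GAP for _, j in path)
              for r in pb.rows]
    return _Profile(pa.row_ids + pb.row_ids, rows_a + rows_b)


def _guide_distance(a: str, b: str) -> float:
    """1 - identity of an optimal unit-cost pairwise alignment (via edlib)."""
    res = edlib.align(a, b, task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    matched = nice["matched_aligned"]
    ident = matched.count("|") / max(len(matched), 1)
    return 1.0 - ident


def progressive_align(seqs: Sequence[tuple[str, str]],
                      scheme: AlignScheme = AlignScheme(),
                      distance: Callable[[str, str], float] | None = None
                      ) -> MultipleAlignment:
    """Progressive alignment of ``(id, sequence)`` pairs.

    The guide tree is neighbor-joining on pairwise distances (by default
    1 - identity of unit-cost pairwise alignments); profiles are merged in
    the NJ agglomeration order.  A single sequence yields a trivial
    one-row alignment; two sequences reduce to
    :func:`pairwise_global_align`.
    """
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise SixscanError("duplicate sequence ids in alignment input")
    if not seqs:
        raise SixscanError("nothing to align")
    if len(seqs) == 1:
        return MultipleAlignment([ids[0]], [seqs[0][1]])
    dist = distance or _guide_distance
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(seqs[i][1], seqs[j][1])
    _, join_order = neighbor_joining(ids, D)
    profiles: dict[int, _Profile] = {
        i: _Profile([ids[i]], [seqs[i][1]]) for i in range(n)}
    next_node = n
    for i, j in join_order:
        profiles[next_node] = _merge_profiles(profiles.pop(i), profiles.pop(j),
                                              scheme)
        next_node += 1
    (final,) = profiles.values()
    # restore input row order
    order = sorted(range(len(final.row_ids)),
                   key=lambda k: ids.index(final.row_ids[k]))
    aln = MultipleAlignment([final.row_ids[k] for k in order],
                            [final.rows[k] for k in order])
    for rid, (sid, s) in zip(aln.row_ids, sorted(seqs, key=lambda x: ids.index(x[0]))):
        assert aln.degapped(rid) == s, "degapping invariant violated"
    return aln


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou-Nei)
# ---------------------------------------------------------------------------

@dataclass
class PhyloNode:
    """A node of an unrooted tree; leaves carry labels, edges carry lengths."""

    label: str | None = None
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.label or ""
        inner = ",".join(f"{c._newick()}:{l:.10g}" for c, l in self.children)
        return f"({inner})" + (self.label or "")

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every pair of leaf labels."""
        acc: dict[tuple[str, str], float] = {}

        def collect(node: PhyloNode) -> list[tuple[str, float]]:
            if node.is_leaf():
                return [(node.label or "", 0.0)]
            below: list[list[tuple[str, float]]] = []
            for child, length in node.children:
                below.append([(lab, d + length) for lab, d in collect(child)])
            for gi in range(len(below)):
                for gj in range(gi + 1, len(below)):
                    for la, da in below[gi]:
                        for lb, db in below[gj]:
                            acc[tuple(sorted((la, lb)))] = da + db
            return [pair for grp in below for pair in grp]

        collect(self)
        return acc


def neighbor_joining(labels: Sequence[str], D: np.ndarray
                     ) -> tuple[PhyloNode, list[tuple[int, int]]]:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by current node order (row-major,
    i < j), with newly created internal nodes appended after existing ones.
    Returns the unrooted tree (a final node of degree 3, or 2 for two taxa)
    and the binary join order as pairs of node indices; indices >= len(labels)
    refer to internal nodes in creation order.  The join order is what the
    progressive aligner consumes as its guide.
    """
    n = len(labels)
    if n < 2:
        raise SixscanError("neighbor joining needs at least 2 taxa")
    D = np.asarray(D, dtype=float)
    if D.shape != (n, n):
        raise SixscanError("distance matrix shape does not match labels")
    nodes: list[PhyloNode | None] = [PhyloNode(label=l) for l in labels]
    active = list(range(n))
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(n) if i < j}

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    join_order: list[tuple[int, int]] = []
    next_idx = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best, best_q = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best  # type: ignore[misc]
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        new = PhyloNode(children=[(nodes[i], li), (nodes[j], lj)])  # type: ignore[arg-type]
        nodes.append(new)
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_idx), max(k, next_idx))] = \
                0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [next_idx]
        join_order.append((i, j))
        next_idx += 1

    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
        lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
        lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        root = PhyloNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])  # type: ignore[list-item]
        join_order.extend([(i, j), (next_idx, k)])
    else:
        i, j = active
        root = PhyloNode(children=[(nodes[i], 0.5 * d(i, j)), (nodes[j], 0.5 * d(i, j))])  # type: ignore[list-item]
        join_order.append((i, j))
    return root, join_order


# ---------------------------------------------------------------------------
# Alignment output
# ---------------------------------------------------------------------------

def write_aligned_fasta(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.row_ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def write_stockholm(aln: MultipleAlignment, path) -> None:
    """Minimal Stockholm writer (sequence lines only)."""
    width = max((len(r) for r in aln.row_ids), default=0) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for rid, row in zip(aln.row_ids, aln.rows):
            fh.write(f"{rid:<{width}}{row.replace(GAP, '.')}\n")
        fh.write("//\n")
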