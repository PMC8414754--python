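"""pRNA start projection, motif-guided shift correction, and the pRNA tree.

6S RNA serves as a template for RNA polymerase, which synthesizes short
product RNAs (pRNAs) starting at a conserved template position.  The
experimentally known start sites of reference 6S RNAs (e.g. E. coli K12,
B. subtilis 168 6S-1/6S-2) are projected through a multiple alignment
onto target 6S sequences: each reference start maps to its alignment
column, the modal column is chosen, and that column maps back to each
target's ungapped coordinate.  Sixteen-nt pRNA sequences are extracted in
antisense orientation, a consensus motif (per-column frequencies and
information content) is built, and each start may be shifted by up to
three nucleotides toward a better motif match.  Finally a neighbor-joining
tree of the pRNA sequences (positions 1-15) plus their consensus is
computed from normalized Hamming distances.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .io_core import SixscanError, revcomp
from .msa import MultipleAlignment, map_column, map_position, neighbor_joining

__all__ = [
    "PRNACall",
    "MotifProfile",
    "project_starts",
    "extract_prna",
    "build_motif",
    "adjust_starts",
    "nj_tree",
]

_BASE = {c: i for i, c in enumerate("ACGT")}


@dataclass
class PRNACall:
    """A pRNA call on one target 6S sequence.

    ``start`` is the 0-based template position paired with the pRNA's 5'
    nucleotide; ``seq`` is the extracted pRNA (antisense of the template
    window); ``exact`` is False when the projection went through a gap
    column.
    """

    target_id: str
    start: int
    seq: str
    shift_applied: int = 0
    motif_score: float = 0.0
    exact: bool = True


@dataclass
class MotifProfile:
    """Per-column base frequencies and information content of a motif."""

    width: int
    freqs: np.ndarray          # (4, width), columns sum to 1
    information: np.ndarray    # (width,), bits in [0, 2]
    n_seqs: int

    def loglik(self, window: str, pseudocount: float = 0.5) -> float:
        """Log2 likelihood of a window under pseudocounted frequencies."""
        if len(window) != self.width:
            raise SixscanError("window width mismatch")
        probs = (self.freqs * self.n_seqs + pseudocount) \
            / (self.n_seqs + 4 * pseudocount)
        return float(sum(math.log2(probs[_BASE[c], i])
                         for i, c in enumerate(window)))


def project_starts(aln: MultipleAlignment,
                   references: Sequence[tuple[str, int]]
                   ) -> dict[str, tuple[int, bool]]:
    """Project reference start sites through the alignment to every row.

    Each reference ``(row_id, ref_start)`` votes for its alignment column;
    the modal column wins (ties: smallest column).  The winning column is
    mapped back to each row's ungapped coordinates; rows where it falls on
    a gap get the nearest residue to the left, flagged inexact (False).
    Returns ``{row_id: (position, exact)}`` for all non-reference rows.
    """
    if not references:
        raise SixscanError("at least one reference start is required")
    columns = [map_position(aln, rid, pos) for rid, pos in references]
    counts = Counter(columns)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    ref_ids = {rid for rid, _ in references}
    out: dict[str, tuple[int, bool]] = {}
    for rid in aln.row_ids:
        if rid in ref_ids:
            continue
        out[rid] = map_column(aln, rid, best)
    return out


def extract_prna(seq6s: str, start: int, length: int = 16,
                 direction: str = "toward_5prime") -> str:
    """Extract the pRNA as the reverse complement of the template window.

    ``toward_5prime`` (default): the window is
    ``seq6s[start - length + 1 .. start]`` — the product grows as the
    template is read 3'->5'.  ``toward_3prime``: the window is
    ``seq6s[start .. start + length - 1]``.  In both conventions the base
    at ``start`` pairs with the pRNA's 5' nucleotide.
    """
    if direction == "toward_5prime":
        lo, hi = start - length + 1, start + 1
    elif direction == "toward_3prime":
        lo, hi = start, start + length
    else:
        raise SixscanError(f"unknown direction {direction!r}")
    if lo < 0 or hi > len(seq6s):
        raise SixscanError(
            f"pRNA window [{lo}, {hi}) outside sequence of length {len(seq6s)}")
    return revcomp(seq6s[lo:hi])


def build_motif(prna_seqs: Sequence[str]) -> MotifProfile:
    """Column frequencies and information content (2 - Shannon entropy in
    bits, no small-sample correction) of equal-length pRNA sequences."""
    if len(prna_seqs) < 2:
        raise SixscanError("need at least 2 sequences for a motif")
    width = len(prna_seqs[0])
    if any(len(s) != width for s in prna_seqs):
        raise SixscanError("pRNA sequences must have equal length")
    counts = np.zeros((4, width))
    for s in prna_seqs:
        for i, c in enumerate(s):
            counts[_BASE[c], i] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    return MotifProfile(width=width, freqs=freqs,
                        information=np.clip(info, 0.0, 2.0),
                        n_seqs=len(prna_seqs))


def adjust_starts(calls: Sequence[PRNACall], seqs: Mapping[str, str],
                  motif: MotifProfile, max_shift: int = 3,
                  length: int | None = None,
                  direction: str = "toward_5prime") -> list[PRNACall]:
    """Shift each start by up to ``max_shift`` nt toward a better motif match.

    Candidate shifts are scored by the motif log-likelihood of the
    re-extracted window; the best strictly-better shift is adopted, with
    ties resolved toward smaller absolute shift and then the negative
    direction.  A single pass, no iteration to a fixed point.
    """
    if max_shift < 0:
        raise SixscanError("max_shift must be >= 0")
    order = [0]
    for k in range(1, max_shift + 1):
        order.extend([-k, k])
    out: list[PRNACall] = []
    for call in calls:
        seq = seqs[call.target_id]
        L = length or len(call.seq) or motif.width
        best_shift, best_score, best_seq = 0, -math.inf, call.seq
        for shift in order:
            try:
                window = extract_prna(seq, call.start + shift, L, direction)
            except SixscanError:
                continue
            score = motif.loglik(window)
            if score > best_score:
                best_shift, best_score, best_seq = shift, score, window
        out.append(replace(call, start=call.start + best_shift,
                           seq=best_seq, shift_applied=best_shift,
                           motif_score=best_score))
    return out


def nj_tree(seqs: Sequence[tuple[str, str]],
            consensus: tuple[str, str]) -> str:
    """Neighbor-joining newick tree of pRNA sequences plus their consensus.

    Sequences are trimmed to positions 1-15 (the first 15 nt); the
    distance is Hamming distance / 15.  Requires at least 3 taxa after
    adding the consensus; ties in the join criterion are broken by taxon
    order.
    """
    taxa = list(seqs) + [consensus]
    if len(taxa) < 3:
        raise SixscanError("need at least 3 taxa for a tree")
    trimmed = [(tid, s[:15]) for tid, s in taxa]
    if any(len(s) < 15 for _, s in trimmed):
        raise SixscanError("all sequences must be at least 15 nt")
    ids = [tid for tid, _ in trimmed]
    if len(set(ids)) != len(ids):
        raise SixscanError("duplicate taxon ids")
    n = len(trimmed)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h = sum(a != b for a, b in zip(trimmed[i][1], trimmed[j][1]))
            D[i, j] = D[j, i] = h / 15.0
    tree, _ = neighbor_joining(ids, D)
    return tree.to_newick()
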