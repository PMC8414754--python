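"""Synteny-constrained second-pass 6S RNA search.

Genomes where the first search pass found nothing are re-searched with
relaxed significance (e-value 0.1) and exhaustive settings (minimal seed
length, unbounded x-drop), but only inside windows of +-anchor_window_nt
(default 2000 nt) around rarA/uspA anchor homologs.  A window from either
anchor suffices ("and/or"); both contribute when present.  Distances are
measured from the anchor boundary.  Hits outside every window are
impossible by construction, which is what makes the permissive threshold
safe.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .homology_search import (Hit, ScoringScheme, filter_by_evalue,
                              join_overlapping, search)
from .io_core import Feature, Genome, SixscanError

__all__ = ["AnchorSet", "RescueWindow", "locate_anchors", "build_windows",
           "rescue_search"]


@dataclass
class AnchorSet:
    """Anchor-gene homolog locations on one genome."""

    genome_id: str
    anchors: list[Feature] = field(default_factory=list)


@dataclass
class RescueWindow:
    """A merged +-W neighborhood of one or more anchors (0-based half-open)."""

    genome_id: str
    start: int
    end: int
    source_kinds: list[str] = field(default_factory=list)


def locate_anchors(genome: Genome, anchor_refs: Sequence[Genome],
                   scheme: ScoringScheme, evalue_anchor: float = 1e-40,
                   seed_len: int = 11, x_drop: float = 20.0) -> AnchorSet:
    """Annotate rarA/uspA homologs by similarity search at a strict e-value.

    Each reference's ``id`` names its anchor kind (e.g. ``rarA``);
    overlapping hits per kind are joined.  An empty set is a valid result.
    """
    anchors: list[Feature] = []
    for ref in anchor_refs:
        hits = search(ref, genome, scheme, seed_len=seed_len, x_drop=x_drop)
        hits = filter_by_evalue(hits, evalue_anchor)
        for h in join_overlapping(hits):
            anchors.append(Feature(
                genome_id=genome.id, start=h.start, end=h.end,
                strand=h.strand, kind=ref.id, score=float(h.raw_score),
                attributes={"evalue": f"{h.evalue:.3g}"}))
    anchors.sort(key=lambda f: (f.start, f.end))
    return AnchorSet(genome_id=genome.id, anchors=anchors)


def build_windows(anchor_set: AnchorSet, genome_length: int,
                  W: int = 2000) -> list[RescueWindow]:
    """Per-anchor intervals extended by W on both sides, clipped to the
    genome, and merged when they overlap or touch."""
    if W < 0:
        raise SixscanError("anchor window W must be >= 0")
    intervals = sorted(
        (max(0, a.start - W), min(genome_length, a.end + W), a.kind)
        for a in anchor_set.anchors)
    windows: list[RescueWindow] = []
    for s, e, kind in intervals:
        if windows and s <= windows[-1].end:
            windows[-1].end = max(windows[-1].end, e)
            if kind not in windows[-1].source_kinds:
                windows[-1].source_kinds.append(kind)
        else:
            windows.append(RescueWindow(anchor_set.genome_id, s, e, [kind]))
    return windows


def rescue_search(genome: Genome, windows: Sequence[RescueWindow],
                  queries: Sequence[Genome], scheme: ScoringScheme,
                  evalue_rescue: float = 0.1, seed_len: int = 4,
                  exclude: Sequence[Hit] = ()) -> list[Hit]:
    """Exhaustive relaxed search restricted to rescue windows.

    Each window subsequence is searched with the minimal seed length and an
    unbounded x-drop; hit coordinates are lifted back to the genome frame.
    Hits overlapping any ``exclude`` interval (e.g. first-pass accepted
    hits) are dropped to avoid double reporting.
    """
    out: list[Hit] = []
    for w in windows:
        if w.genome_id != genome.id:
            raise SixscanError("window/genome mismatch")
        sub = Genome(id=genome.id, seq=genome.seq[w.start:w.end])
        for q in queries:
            hits = search(q, sub, scheme, seed_len=seed_len,
                          x_drop=float("inf"))
            for h in filter_by_evalue(hits, evalue_rescue):
                h.start += w.start
                h.end += w.start
                out.append(h)
    out = join_overlapping(out)
    kept = []
    for h in out:
        if any(h.genome_id == x.genome_id and h.start < x.end and x.start < h.end
               for x in exclude):
            continue
        kept.append(h)
    return kept
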