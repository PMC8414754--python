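"""Redundancy reduction: collapse near-identical 6S sequences to consensi.

Identical sequences are first merged to a single representative; the
survivors are then single-linkage clustered with an edit-distance cutoff
(default 10) and each cluster is replaced by its majority-vote consensus.
Single linkage (connected components of the <=cutoff graph) is the only
parameter-free reading of "merge everything within edit distance ten";
cluster diameters are logged so chaining is visible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import edlib

from .io_core import GAP, SixscanError
from .msa import AlignScheme, progressive_align

__all__ = [
    "SequenceCluster",
    "edit_distance",
    "dedupe_exact",
    "cluster_by_distance",
    "consensus_of_cluster",
    "reduce_to_representatives",
]

logger = logging.getLogger("sixscan")


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit costs (substitution, insertion, deletion)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class SequenceCluster:
    """A group of sequences pairwise connected at <= cutoff edit distance."""

    member_ids: list[str]
    members: list[str]
    representative: str = ""

    def diameter(self) -> int:
        return max(
            (edit_distance(a, b) for i, a in enumerate(self.members)
             for b in self.members[i + 1:]), default=0)


def dedupe_exact(seqs: Sequence[tuple[str, str]]
                 ) -> list[tuple[str, str, list[str]]]:
    """Collapse identical strings to ``(representative_id, seq, member_ids)``.

    The representative id is the lexicographically smallest member id;
    output is ordered by representative id.
    """
    groups: dict[str, list[str]] = {}
    for sid, s in seqs:
        groups.setdefault(s, []).append(sid)
    out = []
    for s, ids in groups.items():
        ids = sorted(ids)
        out.append((ids[0], s, ids))
    out.sort(key=lambda t: t[0])
    return out


def cluster_by_distance(seqs: Sequence[tuple[str, str]],
                        cutoff: int = 10) -> list[SequenceCluster]:
    """Single-linkage clusters: connected components of the <=cutoff graph.

    With cutoff 0 this degenerates to exact deduplication.  Clusters are
    ordered by (and members ordered within) their smallest member id.
    """
    if cutoff < 0:
        raise SixscanError("cutoff must be >= 0")
    n = len(seqs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if edit_distance(seqs[i][1], seqs[j][1]) <= cutoff:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    clusters = []
    for members in comps.values():
        members.sort(key=lambda i: seqs[i][0])
        clusters.append(SequenceCluster(
            member_ids=[seqs[i][0] for i in members],
            members=[seqs[i][1] for i in members]))
    clusters.sort(key=lambda c: c.member_ids[0])
    return clusters


def consensus_of_cluster(cluster: SequenceCluster,
                         scheme: AlignScheme = AlignScheme()) -> str:
    """Majority-vote consensus over a multiple alignment of the members.

    Per column the most frequent character wins; columns whose majority
    character is the gap are dropped.  Ties are broken by the fixed base
    order A < C < G < T, with a base preferred over the gap on a base/gap
    tie, so the consensus is deterministic.  A singleton cluster is its
    own consensus.
    """
    if not cluster.members:
        raise SixscanError("empty cluster has no consensus")
    if len(cluster.members) == 1:
        return cluster.members[0]
    aln = progressive_align(list(zip(cluster.member_ids, cluster.members)),
                            scheme=scheme)
    out = []
    for col in zip(*aln.rows):
        counts = {c: 0 for c in "ACGT" + GAP}
        for ch in col:
            counts[ch] += 1
        best = max("ACGT" + GAP, key=lambda c: (counts[c], c != GAP, -ord(c)))
        if best != GAP:
            out.append(best)
    return "".join(out)


def reduce_to_representatives(seqs: Sequence[tuple[str, str]],
                              cutoff: int = 10,
                              scheme: AlignScheme = AlignScheme()
                              ) -> list[tuple[str, str, list[str]]]:
    """Full reduction: exact dedupe, distance clustering, per-cluster consensus.

    Returns ``(representative_id, consensus_seq, member_ids)`` per cluster,
    where member_ids covers every original input id.
    """
    deduped = dedupe_exact(seqs)
    clusters = cluster_by_distance([(rid, s) for rid, s, _ in deduped], cutoff)
    members_of = {rid: ids for rid, _s, ids in deduped}
    out = []
    for cl in clusters:
        cl.representative = consensus_of_cluster(cl, scheme)
        all_ids = sorted(
            mid for rid in cl.member_ids for mid in members_of[rid])
        logger.info("cluster %s: %d members, diameter %d",
                    cl.member_ids[0], len(all_ids), cl.diameter())
        out.append((cl.member_ids[0], cl.representative, all_ids))
    return out
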