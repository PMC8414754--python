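"""End-to-end orchestration of the 6S RNA annotation pipeline.

Stage order: first-pass homology search -> redundancy reduction of the
accepted 6S sequences -> synteny-constrained rescue for genomes the first
pass missed -> shuffled-genome terminator calls -> cre motif scanning at
each accepted locus -> pRNA start projection, motif, shift correction and
tree.  Intermediate artifacts are written as plain FASTA/GFF3/TSV files so
any stage can be rerun and audited on the orchestrator's own outputs, and
the whole run is deterministic given the config seed.

A genome's 6S status is ``primary`` when the first pass accepted a hit,
``rescued`` when only the second, synteny-restricted iteration did, and
``not_located`` otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cre_motif, prna, redundancy, synteny_rescue, terminator_fdr
from .homology_search import (Hit, ScoringScheme, best_hit_per_genome,
                              filter_by_evalue, join_overlapping, search)
from .io_core import (Feature, Genome, PipelineConfig, SixscanError,
                      write_fasta, write_gff3)
from .msa import progressive_align, write_aligned_fasta

__all__ = ["RunReport", "GenomeResult", "run_all"]

logger = logging.getLogger("sixscan")


@dataclass
class GenomeResult:
    genome_id: str
    status: str                      # primary | rescued | not_located
    six_hit: Hit | None = None
    six_seq: str = ""
    terminator_threshold: float = float("inf")
    features: list[Feature] = field(default_factory=list)


@dataclass
class RunReport:
    """Per-genome bookkeeping of the whole run."""

    results: list[GenomeResult]
    config: PipelineConfig
    newick: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            counts = {}
            for f in r.features:
                counts[f.kind] = counts.get(f.kind, 0) + 1
            rows.append({
                "genome_id": r.genome_id,
                "status": r.status,
                "ssrS": counts.get("ssrS", 0),
                "terminator": counts.get("terminator", 0),
                "cre_site": counts.get("cre_site", 0),
                "prna": counts.get("prna", 0),
                "terminator_threshold": r.terminator_threshold,
                "seed": self.config.seed,
            })
        return pd.DataFrame(rows)


def _hit_to_feature(h: Hit, kind: str, iteration: int) -> Feature:
    return Feature(
        genome_id=h.genome_id, start=h.start, end=h.end, strand=h.strand,
        kind=kind, score=float(h.raw_score),
        attributes={"evalue": f"{h.evalue:.6g}", "iteration": str(iteration)})


def _extract(genome: Genome, h: Hit) -> str:
    seq = genome.seq[h.start:h.end]
    from .io_core import revcomp
    return seq if h.strand == "+" else revcomp(seq)


def run_all(config: PipelineConfig,
            genomes: Sequence[Genome],
            six_refs: Sequence[Genome],
            anchor_refs: Sequence[Genome],
            cre_sites: Sequence[str] | None = None,
            prna_refs: Sequence[tuple[str, int]] | None = None,
            outdir: str | Path | None = None) -> RunReport:
    """Run every stage on a genome cohort.

    ``six_refs`` are reference 6S sequences (first-pass queries),
    ``anchor_refs`` anchor-gene references whose ids name their kind,
    ``cre_sites`` cre training sites (defaults to the packaged synthetic
    list) and ``prna_refs`` ``(reference_id, start)`` pairs naming rows of
    ``six_refs``.  When ``outdir`` is given, every intermediate artifact is
    written beneath it.
    """
    config.validate()
    config.log_resolved(logger)
    scheme = ScoringScheme(match=config.match, mismatch=config.mismatch,
                           K=config.k_const)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ---- stage 1: first-pass search -------------------------------------
    results: list[GenomeResult] = []
    for genome in genomes:
        hits: list[Hit] = []
        for ref in six_refs:
            hits.extend(search(ref, genome, scheme,
                               seed_len=config.seed_len,
                               x_drop=config.x_drop))
        hits = join_overlapping(hits)
        hits = filter_by_evalue(hits, config.evalue_primary)
        best = best_hit_per_genome(hits)
        if best is not None:
            r = GenomeResult(genome.id, "primary", best,
                             six_seq=_extract(genome, best))
            r.features.append(_hit_to_feature(best, "ssrS", 1))
            logger.info("%s: primary 6S hit at [%d, %d) e=%.3g",
                        genome.id, best.start, best.end, best.evalue)
        else:
            r = GenomeResult(genome.id, "not_located")
            logger.info("%s: 6S not located in first pass", genome.id)
        results.append(r)

    # ---- stage 2: redundancy reduction ----------------------------------
    found = [(r.genome_id, r.six_seq) for r in results if r.six_seq]
    if found:
        representatives = redundancy.reduce_to_representatives(
            found, cutoff=config.merge_edit_distance)
    else:
        representatives = []
    consensus_queries = [Genome(id=f"consensus_{rid}", seq=seq)
                         for rid, seq, _ in representatives] or list(six_refs)
    if out is not None:
        write_fasta([Genome(id=rid, seq=seq,
                            description=f"{rid} members={','.join(ids)}")
                     for rid, seq, ids in representatives]
                    or list(six_refs), out / "representatives.fasta")

    # ---- stage 3: synteny rescue ----------------------------------------
    by_id = {g.id: g for g in genomes}
    for r in results:
        if r.status != "not_located":
            continue
        genome = by_id[r.genome_id]
        anchor_set = synteny_rescue.locate_anchors(
            genome, anchor_refs, scheme,
            evalue_anchor=config.evalue_anchor,
            seed_len=config.seed_len, x_drop=config.x_drop)
        windows = synteny_rescue.build_windows(
            anchor_set, len(genome.seq), W=config.anchor_window_nt)
        rescued = synteny_rescue.rescue_search(
            genome, windows, consensus_queries, scheme,
            evalue_rescue=config.evalue_rescue,
            seed_len=config.rescue_seed_len)
        best = best_hit_per_genome(rescued) if rescued else None
        r.features.extend(
            Feature(genome.id, a.start, a.end, a.strand, a.kind,
                    score=a.score) for a in anchor_set.anchors)
        if best is not None:
            r.status = "rescued"
            r.six_hit = best
            r.six_seq = _extract(genome, best)
            r.features.append(_hit_to_feature(best, "ssrS", 2))
            logger.info("%s: rescued 6S hit at [%d, %d) e=%.3g",
                        genome.id, best.start, best.end, best.evalue)

    # ---- stage 4: terminators -------------------------------------------
    for r in results:
        genome = by_id[r.genome_id]
        term = terminator_fdr.call_terminators(
            genome, n_shuffles=config.n_shuffles,
            fraction=config.fdr_fraction,
            seed=int(rng.integers(0, 2**31 - 1)))
        r.terminator_threshold = term.threshold
        logger.info("%s: terminator threshold %s (%d original, %.2f shuffled)",
                    genome.id, term.threshold, term.n_original_above,
                    term.mean_shuffled_above)
        for c in term.accepted:
            r.features.append(Feature(
                genome.id, c.hairpin_start, c.hairpin_end, c.strand,
                "terminator", score=c.score,
                attributes={"threshold": f"{term.threshold:g}"}))

    # ---- stage 5: cre sites ----------------------------------------------
    sites = list(cre_sites) if cre_sites else list(cre_motif.SYNTHETIC_CRE_SITES)
    pwm = cre_motif.build_pwm(sites)
    for r in results:
        if r.six_hit is None:
            continue
        genome = by_id[r.genome_id]
        bg = cre_motif.fit_background(genome)
        ssrS = Feature(genome.id, r.six_hit.start, r.six_hit.end,
                       r.six_hit.strand, "ssrS")
        for hit in cre_motif.scan_locus(
                pwm, bg, genome, ssrS,
                upstream_nt=config.cre_upstream_nt,
                p_threshold=config.cre_pvalue):
            gstart = ssrS.start + hit.position
            r.features.append(Feature(
                genome.id, gstart, gstart + pwm.width, hit.strand,
                "cre_site", score=hit.score,
                attributes={"pvalue": f"{hit.pvalue:.3g}",
                            "region_class": hit.region_class}))

    # ---- stage 6: pRNAs ---------------------------------------------------
    newick = ""
    with_six = [r for r in results if r.six_seq]
    prna_refs = list(prna_refs or [])
    ref_ids = {rid for rid, _ in prna_refs}
    if with_six and prna_refs:
        rows = [(f"ref_{g.id}" if g.id in ref_ids else g.id, g.seq)
                for g in six_refs if g.id in ref_ids]
        rows += [(r.genome_id, r.six_seq) for r in with_six]
        aln = progressive_align(rows)
        if out is not None:
            write_aligned_fasta(aln, out / "sixs_alignment.fasta")
        projected = prna.project_starts(
            aln, [(f"ref_{rid}", pos) for rid, pos in prna_refs])
        seqs = {r.genome_id: r.six_seq for r in with_six}
        calls = []
        for r in with_six:
            pos, exact = projected[r.genome_id]
            try:
                window = prna.extract_prna(seqs[r.genome_id], pos,
                                           config.prna_length)
            except SixscanError:
                continue
            calls.append(prna.PRNACall(r.genome_id, pos, window, exact=exact))
        if len(calls) >= 2:
            motif = prna.build_motif([c.seq for c in calls])
            calls = prna.adjust_starts(calls, seqs, motif,
                                       max_shift=config.prna_max_shift,
                                       length=config.prna_length)
            for c in calls:
                r = next(x for x in results if x.genome_id == c.target_id)
                six = r.six_hit
                assert six is not None
                # genome coordinates of the template window (forward gene)
                if six.strand == "+":
                    gpos = six.start + c.start
                else:
                    gpos = six.end - 1 - c.start
                r.features.append(Feature(
                    r.genome_id, max(gpos - config.prna_length + 1, 0),
                    gpos + 1, six.strand, "prna",
                    score=c.motif_score,
                    attributes={"shift": str(c.shift_applied),
                                "prna_seq": c.seq}))
            if len(calls) >= 2 and config.prna_length >= 15:
                consensus_seq = "".join(
                    "ACGT"[int(i)] for i in np.argmax(
                        prna.build_motif([c.seq for c in calls]).freqs, axis=0))
                newick = prna.nj_tree(
                    [(c.target_id, c.seq) for c in calls],
                    ("consensus", consensus_seq))

    # ---- outputs ----------------------------------------------------------
    report = RunReport(results=results, config=config, newick=newick)
    if out is not None:
        genome_lengths = {g.id: len(g.seq) for g in genomes}
        all_feats = [f for r in results for f in r.features]
        write_gff3(all_feats, out / "annotations.gff3", genome_lengths)
        report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
        if newick:
            (out / "prna_tree.nwk").write_text(newick + "\n")
    return report
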