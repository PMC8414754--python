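# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, what the synthetic cohorts do and do not
emulate, and the known limitations.

## Search engine and significance

The pipeline's search engine is seed-and-extend, ungapped: exact k-mer
matches between query and target (both strands; the reverse strand via the
reverse-complemented query) are extended in both directions until the
running score drops `x_drop` below its maximum, and the reported interval
is the maximal-scoring extension (shortest such interval on ties, so
results are deterministic). Significance is ungapped Karlin–Altschul
theory: *E* = *K·m·n·*exp(−λ*S*) with λ the unique positive root of
Σᵢⱼ *p*ᵢ*p*ⱼ e^(λ·sᵢⱼ) = 1, solved by bracketed Brent root-finding to
~1e-12 relative tolerance. The scheme must have negative expected
per-position score, or no positive root exists and the construction is
rejected. *K* only rescales e-values by a constant, so it is a
configuration constant (default 0.1) rather than being computed by series
expansion; the default thresholds are calibrated with that in mind.

Keeping extension ungapped is a deliberate trade: the significance theory
is then exact instead of an empirical fit, and sensitivity to co-linear
gapped homology is recovered by transitively joining overlapping
same-strand hits (union of intervals, max member score, min member
e-value). Original production pipelines of this kind use BLAST plus a
covariance-model search; those engines are black boxes with incompatible
e-value scales, so mapping their threshold tiers onto one engine is
necessarily a re-calibration, not an equivalence. Defaults: first pass
1e-30, relaxed profile-like tier 1e-8, synteny rescue 0.1, anchor
annotation 1e-40, seed length 11 (4 in rescue, which also sets x_drop
infinite — exhaustive extension).

The orchestrator filters its first pass at the strict 1e-30 tier, because
with a single engine that is the tier that plays the first-pass role; the
1e-8 value remains configurable for users who want the relaxed regime.

Per-genome acceptance follows a best-hit rule: the minimum-e-value hit is
the genome's 6S candidate, with deterministic tie-breaking (higher raw
score, then leftmost start, then + strand). Note that an equally strong
off-locus copy can legitimately win under this rule; the synteny windows
exist precisely to discipline weak candidates.

## Redundancy reduction

Identical sequences collapse to one representative (lexicographically
smallest id). Survivors are clustered by Levenshtein distance with
single linkage: connected components of the graph with an edge wherever
the distance is ≤ 10. Single linkage is the only parameter-free reading
of "merge everything within distance ten"; because chaining can produce
clusters whose diameter exceeds the cutoff, cluster diameters are logged.
The consensus is per-column majority over a progressive multiple alignment
of the cluster, dropping columns whose majority character is the gap, with
ties broken A<C<G<T (base preferred over gap). Consensus is computed per
cluster, not from one global alignment of all sequences.

## Multiple alignment and coordinate maps

Progressive alignment, sequence-only: guide tree by neighbor joining on
1 − identity of optimal unit-cost pairwise alignments (computed via edlib
for speed), profiles merged leaf-to-root with average-of-pairs column
scoring under a linear gap penalty (defaults match 2 / mismatch −1 /
gap −2), "once a gap, always a gap". Traceback tie-breaking is fixed
(diagonal, then gap in the second profile, then the first), so alignments
are deterministic. Coordinate maps between ungapped positions and
alignment columns are exact on residue columns; a gap column maps back to
the nearest residue on the left and is flagged inexact.

Replacing the structure-aware RNA aligner of a production pipeline with
sequence-only alignment is the single largest simplification in this
package. For 6S sequence sets at roughly ≥70% identity — the regime the
redundancy reduction produces — sequence alignment suffices for
coordinate projection; where a structural and a sequence alignment would
disagree, projected pRNA starts may differ, and the package does not
attempt to detect that.

## Synteny rescue

Anchor references (ids naming their kind, rarA/uspA) are located at
e ≤ 1e-40; each anchor interval is extended ±2000 nt (measured from the
anchor boundary, not its midpoint), clipped, and overlapping windows
merged. Either anchor suffices; both contribute when present. The rescue
search runs only on window subsequences, so out-of-window hits are
impossible by construction; hits are lifted back to genome coordinates and
those overlapping first-pass accepted hits are dropped to avoid double
reporting. The rescue query set is the consensus representatives from the
redundancy stage (falling back to the input references when the first
pass found nothing anywhere), standing in for a cohort-specialized profile
model.

## Terminator calls and the adaptive threshold

The hairpin scorer is deliberately simple and fully specified, because
only the thresholding rule is the scientific contribution here: for every
loop position and loop length 3–10, the stem is extended outward as far as
it pairs (G·C = 3, A·T = 2, G·U wobble = 1) and kept if the maximal stem
reaches 4 bp. Score = stem pairing − 0.5·(loop − 3) + (count of T in the
8 nt 3′ of the hairpin), both strands. All weights are configurable.

Significance: the genome is shuffled ten times preserving its exact mono-
and dinucleotide multisets (Altschul–Erikson Eulerian-walk sampling, which
also fixes the first and last character), each shuffle is re-scored, and
the threshold is the smallest observed candidate score *t* such that the
mean shuffled count of candidates ≥ *t* is at most 5% of the original
count ≥ *t*. "At or above" includes ties, and only observed scores need
testing since any threshold between two observed values selects identical
hit sets. When no threshold qualifies, the result is +∞ and nothing is
accepted. Accepted candidates are merged by overlap, keeping the
highest-scoring representative. Counting is per genome sequence. The rule
emulates roughly a 0.05 empirical significance level; on terminator-free
backgrounds the fraction of genomes with any accepted call is checked
empirically (one-sided binomial test over 50 replicates) rather than
asserted exactly, because tie structure among discrete scores makes the
realized rate only approximately the nominal fraction.

## cre motif scanning

A PWM is built from training sites with pseudocount 0.5. The background is
the scanned genome's own dinucleotide distribution, as a smoothed
first-order Markov chain; window scores are log-odds in bits, with the
first position conditioned on the actual preceding genomic base when one
exists (this matches a dinucleotide background more faithfully than
stationary initialization). Exact p-values come from a dynamic program
over (position, previous base, discretized score); per-position
contributions are rounded *up* to the resolution grid (default 1e-3
bits), which makes every reported p-value provably ≥ the exact tail
probability and within `width × resolution` of it in score. One table is
built per conditioning state (none + four preceding bases). Windows with
zero PWM probability score −∞ and are excluded from the finite
distribution; p(−∞) = 1 by definition.

Scanning covers the 6S gene plus 100 nt upstream on both strands (cre
sites are pseudo-palindromic, so both strands are scanned; a site found on
both typically appears twice, once per strand). Hits at p ≤ 1e-5 are
classified upstream/internal by the sign of their offset from the gene
start; overlapping same-strand hits collapse to the best p-value, and at
most the 5 best hits are reported per locus — a per-window p-value regime
replaces sequence-level e-values, which degenerate on single-locus scans.
The original training matrix for cre sites is not published; the package
ships a synthetic stand-in site list (`SYNTHETIC_CRE_SITES`, constructed
fixture data) and accepts user site lists.

## pRNA projection

Reference start coordinates are inputs, not constants. Each reference
start maps to its alignment column; the modal column across references
wins (smallest column on ties) and maps back to every target row. pRNAs
are extracted as the reverse complement of the 16-nt template window; the
default orientation is `toward_5prime` (the product grows as the template
is read 3′→5′), with the base at the start position pairing the pRNA's 5′
nucleotide in either orientation — the opposite convention is a switch.
The consensus motif is per-column frequencies with information content
2 − H bits (no small-sample correction). Start correction evaluates
shifts −3…+3 by motif log-likelihood (frequencies pseudocounted by 0.5 to
avoid −∞), adopting the best strictly better shift, ties toward smaller
absolute shift and then negative; one pass only, no fixed-point
iteration. Shifts are signed: "up to three nucleotides" is read as either
direction. The pRNA tree is Saitou–Nei neighbor joining on Hamming
distance/15 over positions 1–15 plus the consensus sequence, with
deterministic tie-breaking by taxon order; on additive matrices the
implementation recovers path lengths exactly (tested), and it is
cross-checked against an independent implementation.

## Synthetic cohorts

Backgrounds are sampled from the stationary first-order chain of a
16-entry dinucleotide frequency table (uniform by default). Each genome
carries one planted 6S copy derived from a packaged ~190-nt seed sequence
with the canonical architecture (complementary 40-nt hairpin arms around a
weakly paired 110-nt center; a constructed fixture, not a biological
sequence), mutated at per-position substitution rate 0.05 by default
(substitutions always change the base; indels, default off, are
length-uniform on {1,2,3}). Anchors are fixed pseudo-random ≥300-nt
marker sequences rather than real protein genes — the rescue stage only
needs locatable anchors, and markers keep the fixture self-contained. The
planted locus is rarA · 120 nt · 6S · terminator · 120 nt · uspA on the
forward strand; the terminator is a perfect 10-bp GC stem, 4-nt loop and
8-nt U-tract; cre sites are sampled column-wise from the PWM and written
at offset −60 (upstream) and/or +40 (internal); decoy 6S copies are
placed farther than the anchor window from every anchor. The truth set
records exact coordinates and planted sequences.

What the cohorts do **not** emulate: real gene models and codon
structure, phylogenetically correlated divergence, strand variation of
the planted locus (always forward), GC skew, repeats, or multi-replicon
genomes. Passing tests therefore demonstrate correctness of the
algorithms under controlled conditions, not field performance on real
genomes.

## Problem sizes and determinism

The test suite runs the statistical checks at desk scale, as the
package's own choice of problem size: 1000 shuffles (lengths 2–2000), 100
random search instances against the quadratic oracle, exhaustive 4^w PWM
enumeration for widths 4–8, 200 clustering instances, a 50-genome rescue
cohort at 15% divergence, a 40-target pRNA cohort at 10% divergence, 30
random additive trees (n ≤ 8), and 50 terminator-free replicates of 3 kb.
Every random draw is seeded; cohort generation, the pipeline, and all
outputs are bit-reproducible given the configuration seed. All internal
coordinates are 0-based half-open; emitted GFF3 is 1-based inclusive, and
the round trip is the identity.

## Known limitations

* Ungapped extension under-scores planted copies containing indels; the
  join-overlaps step only partially compensates. Rescue sensitivity
  guarantees are stated for substitution-only divergence.
* The adaptive terminator rule's realized false-call rate is only
  approximately its nominal fraction (tie effects); it is validated
  statistically, not exactly.
* Sequence-only alignment may project pRNA starts differently from a
  structural alignment on low-identity sets.
* The e-value scale of this engine is not comparable to BLAST or
  covariance-model e-values; thresholds are calibrations, not
  equivalences.
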