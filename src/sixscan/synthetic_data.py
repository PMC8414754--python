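"""Synthetic genome cohorts with planted ground truth.

Every downstream stage is exercised on cohorts built here: a background
genome sampled from a stationary first-order (dinucleotide) chain, a
mutated copy of a seed 6S RNA gene flanked by anchor-gene markers (rarA
upstream, uspA downstream — the conserved syntenic neighborhood of the 6S
gene in lactic acid bacteria), an intrinsic terminator (GC-rich hairpin
plus U-tract) appended downstream, cre sites written into the 100-nt
promoter region and/or the gene body, and decoy 6S copies planted farther
than the anchor window from any anchor.  The returned truth set records
exact coordinates, so extracting any recorded interval from the genome
reproduces the planted sequence.

The anchor markers are fixed pseudo-random nucleotide sequences (>=300 nt)
rather than real protein genes: the rescue stage only needs locatable
anchors, and markers keep the fixture self-contained.  The default seed
6S sequence is likewise a constructed ~190-nt fixture with the canonical
architecture (paired hairpin arms flanking a weakly paired central
region); its exact identity is not a biological claim.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cre_motif import PWM, SYNTHETIC_CRE_SITES, build_pwm, sample_site
from .io_core import Feature, Genome, SixscanError, revcomp

__all__ = [
    "PlantSpec",
    "TruthSet",
    "DEFAULT_6S",
    "DEFAULT_PRNA_START",
    "RARA_MARKER",
    "USPA_MARKER",
    "TERMINATOR_SEQ",
    "generate_background",
    "mutate_sequence",
    "plant_cohort",
]

_BASES = "ACGT"

# --- fixture sequences -----------------------------------------------------

_ARM5 = "GTTCGGTCAATCTGACGGATTCCCTGCGTAACGCGGATCT"  # 40 nt
# central region, 110 nt, weakly structured
_CENTER = (
    "AACTGGTCAGAATTTCACGATACAGGTTCCAGAAGTATTC"  # 40
    "CTAAGCCGAACTTCAGGATACGAAGGCATTCAACATGAGT"  # 40
    "TCGACGATAGTTCTGGACCAGTTAGGCAGT"             # 30
)

#: Packaged ~190-nt seed 6S sequence: two complementary 40-nt hairpin arms
#: flanking a 110-nt weakly paired central region (a constructed fixture).
DEFAULT_6S = _ARM5 + _CENTER + revcomp(_ARM5)

#: Template position (0-based, on the 6S sequence) paired with the 5' end of
#: the product RNA in the default fixture; lies in the central bubble.
DEFAULT_PRNA_START = 100

#: Intrinsic terminator planted downstream of the 6S gene: a perfect
#: GC-rich 10-bp stem, 4-nt loop, and an 8-nt U(T)-tract.
_TERM_STEM = "GCCGCCAGGC"
TERMINATOR_SEQ = _TERM_STEM + "TTCG" + revcomp(_TERM_STEM) + "TTTTTTTT"


def _fixed_marker(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))

#: Anchor-gene marker sequences (constructed fixtures, not real genes).
RARA_MARKER = _fixed_marker(20260901, 350)
USPA_MARKER = _fixed_marker(20260902, 350)


# --- spec / truth containers ----------------------------------------------

def _uniform_freqs() -> np.ndarray:
    return np.full((4, 4), 1.0 / 16.0)


@dataclass
class PlantSpec:
    """What to plant in each synthetic genome, and at what rates."""

    seed_6s_sequence: str = DEFAULT_6S
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    n_decoys_outside_window: int = 1
    terminator_present: bool = True
    cre_upstream_present: bool = True
    cre_internal_present: bool = False
    anchor_layout: str = "both"  # rarA_upstream | uspA_downstream | both | none
    genome_length: int = 10000
    dinucleotide_freqs: np.ndarray = field(default_factory=_uniform_freqs)
    anchor_window_nt: int = 2000
    cre_pwm: PWM | None = None
    cre_upstream_offset: int = -60   # relative to 6S start
    cre_internal_offset: int = 40

    def validate(self) -> "PlantSpec":
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise SixscanError("mutation rates must lie in [0, 1]")
        if self.anchor_layout not in (
                "rarA_upstream", "uspA_downstream", "both", "none"):
            raise SixscanError(f"unknown anchor_layout {self.anchor_layout!r}")
        if self.n_decoys_outside_window < 0:
            raise SixscanError("n_decoys_outside_window must be >= 0")
        freqs = np.asarray(self.dinucleotide_freqs, dtype=float).reshape(4, 4)
        if abs(freqs.sum() - 1) > 1e-9 or (freqs < 0).any():
            raise SixscanError("dinucleotide_freqs must be 16 nonnegative "
                               "reals summing to 1")
        return self


@dataclass
class TruthSet:
    """Planted features of one synthetic genome (kinds: ssrS, rarA, uspA,
    terminator, cre_site, decoy)."""

    genome_id: str
    features: list[Feature]

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


# --- generators ------------------------------------------------------------

def generate_background(length: int, dinucleotide_freqs, seed: int,
                        allow_degenerate: bool = False) -> Genome:
    """Sample a genome from the stationary first-order chain of the given
    dinucleotide frequencies.  Deterministic given the seed.

    A base with zero marginal frequency makes the chain degenerate; this is
    an error unless ``allow_degenerate`` is set (useful for e.g. an all-A
    test chain).
    """
    if length < 1:
        raise SixscanError("length must be >= 1")
    freqs = np.asarray(dinucleotide_freqs, dtype=float).reshape(4, 4)
    if abs(freqs.sum() - 1) > 1e-9 or (freqs < 0).any():
        raise SixscanError("dinucleotide_freqs must sum to 1 and be >= 0")
    marginal = freqs.sum(axis=1)
    if (marginal <= 0).any() and not allow_degenerate:
        raise SixscanError("a base is unreachable under these frequencies; "
                           "pass allow_degenerate=True if intended")
    rng = np.random.default_rng(seed)
    initial = marginal / marginal.sum()
    rows = np.where(marginal[:, None] > 0,
                    freqs / np.maximum(marginal[:, None], 1e-300), 0.25)
    cum_init = np.cumsum(initial)
    cum_rows = np.cumsum(rows, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    out[0] = np.searchsorted(cum_init, u[0])
    for i in range(1, length):
        out[i] = np.searchsorted(cum_rows[out[i - 1]], u[i])
    return Genome(id=f"bg_{seed}",
                  seq="".join(_BASES[i] for i in np.minimum(out, 3)))


def mutate_sequence(seq: str, substitution_rate: float, indel_rate: float,
                    seed: int) -> str:
    """Point-mutate a sequence: per-position substitutions to a different
    uniformly chosen base, plus insertions/deletions of length 1-3 at a
    per-position rate.  Deterministic given the seed.
    """
    if not (0 <= substitution_rate <= 1 and 0 <= indel_rate <= 1):
        raise SixscanError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion before current position
                out.extend(_BASES[k] for k in rng.integers(0, 4, size=length))
            else:                   # deletion of up to `length` bases
                i += length
                continue
        c = seq[i]
        if substitution_rate > 0 and rng.random() < substitution_rate:
            alternatives = [b for b in _BASES if b != c]
            c = alternatives[rng.integers(3)]
        out.append(c)
        i += 1
    return "".join(out)


def _place_decoys(rng: np.random.Generator, n_decoys: int, decoy_len: int,
                  genome_len: int, anchors: list[tuple[int, int]],
                  occupied: list[tuple[int, int]], window: int) -> list[int]:
    """Start positions for decoys farther than ``window`` from every anchor
    and not overlapping anything already planted."""
    def far_enough(s: int) -> bool:
        e = s + decoy_len
        for a0, a1 in anchors:
            if s < a1 + window and a0 - window < e:
                return False
        for o0, o1 in occupied:
            if s < o1 and o0 < e:
                return False
        return True

    starts: list[int] = []
    for _ in range(n_decoys):
        placed = False
        for _attempt in range(2000):
            s = int(rng.integers(0, genome_len - decoy_len))
            if far_enough(s):
                starts.append(s)
                occupied.append((s, s + decoy_len))
                placed = True
                break
        if not placed:
            raise SixscanError(
                "cannot place decoys outside the anchor window; "
                "increase genome_length or reduce n_decoys_outside_window")
    return starts


def plant_cohort(n_genomes: int, spec: PlantSpec, seed: int
                 ) -> list[tuple[Genome, TruthSet]]:
    """Generate ``n_genomes`` synthetic genomes with planted 6S loci.

    Per genome: background from the spec's dinucleotide chain; one mutated
    6S copy with anchors per the layout (within the anchor window);
    optional terminator immediately downstream and cre sites in the
    promoter region / gene body; decoy copies planted farther than the
    anchor window from any anchor.  Bit-reproducible given (spec, seed).
    """
    spec.validate()
    if n_genomes < 0:
        raise SixscanError("n_genomes must be >= 0")
    pwm = spec.cre_pwm or build_pwm(SYNTHETIC_CRE_SITES)
    master = np.random.default_rng(seed)
    cohort: list[tuple[Genome, TruthSet]] = []
    for g in range(n_genomes):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        gid = f"synth_{g:03d}"
        genome = list(generate_background(
            spec.genome_length, spec.dinucleotide_freqs,
            int(rng.integers(0, 2**31 - 1))).seq)

        six = mutate_sequence(spec.seed_6s_sequence, spec.substitution_rate,
                              spec.indel_rate, int(rng.integers(0, 2**31 - 1)))
        upstream_gap, downstream_gap = 120, 120
        has_rarA = spec.anchor_layout in ("rarA_upstream", "both")
        has_uspA = spec.anchor_layout in ("uspA_downstream", "both")
        term = TERMINATOR_SEQ if spec.terminator_present else ""
        block_len = ((len(RARA_MARKER) if has_rarA else 0) + upstream_gap
                     + len(six) + len(term) + downstream_gap
                     + (len(USPA_MARKER) if has_uspA else 0))
        margin = 200
        lo = margin
        hi = spec.genome_length - block_len - margin
        if hi <= lo:
            raise SixscanError("genome_length too small to host the locus")
        block_start = int(rng.integers(lo, hi))

        feats: list[Feature] = []
        pos = block_start
        anchors: list[tuple[int, int]] = []

        def write(seq_piece: str, at: int) -> None:
            genome[at:at + len(seq_piece)] = list(seq_piece)

        if has_rarA:
            write(RARA_MARKER, pos)
            feats.append(Feature(gid, pos, pos + len(RARA_MARKER), "+", "rarA"))
            anchors.append((pos, pos + len(RARA_MARKER)))
            pos += len(RARA_MARKER)
        pos += upstream_gap
        six_start = pos
        write(six, six_start)
        ssrS_feat = Feature(gid, six_start, six_start + len(six), "+", "ssrS",
                            attributes={"ID": f"{gid}_ssrS",
                                        "planted_seq": six})
        feats.append(ssrS_feat)
        pos += len(six)
        if spec.terminator_present:
            write(term, pos)
            feats.append(Feature(gid, pos, pos + len(term), "+", "terminator"))
            pos += len(term)
        pos += downstream_gap
        if has_uspA:
            write(USPA_MARKER, pos)
            feats.append(Feature(gid, pos, pos + len(USPA_MARKER), "+", "uspA"))
            anchors.append((pos, pos + len(USPA_MARKER)))
            pos += len(USPA_MARKER)

        for flag, offset, cls in (
                (spec.cre_upstream_present, spec.cre_upstream_offset, "upstream"),
                (spec.cre_internal_present, spec.cre_internal_offset, "internal")):
            if not flag:
                continue
            site = sample_site(pwm, rng)
            at = six_start + offset
            if at < 0 or at + len(site) > spec.genome_length:
                raise SixscanError("cre site falls outside the genome")
            write(site, at)
            feats.append(Feature(gid, at, at + len(site), "+", "cre_site",
                                 attributes={"region_class": cls,
                                             "offset": str(offset),
                                             "planted_seq": site}))
            if cls == "internal":
                # the gene body was overwritten; refresh its recorded sequence
                ssrS_feat.attributes["planted_seq"] = "".join(
                    genome[ssrS_feat.start:ssrS_feat.end])

        occupied = [(block_start, pos)]
        if spec.n_decoys_outside_window:
            decoys = [mutate_sequence(
                spec.seed_6s_sequence, spec.substitution_rate,
                spec.indel_rate, int(rng.integers(0, 2**31 - 1)))
                for _ in range(spec.n_decoys_outside_window)]
            decoy_len = max(len(d) for d in decoys)
            starts = _place_decoys(rng, len(decoys), decoy_len,
                                   spec.genome_length, anchors, occupied,
                                   spec.anchor_window_nt)
            for d, s in zip(decoys, starts):
                write(d, s)
                feats.append(Feature(gid, s, s + len(d), "+", "decoy",
                                     attributes={"planted_seq": d}))

        seq = "".join(genome)
        truth = TruthSet(gid, feats)
        # planted-coordinate invariant: the recorded interval is the sequence
        for f in feats:
            assert 0 <= f.start < f.end <= len(seq)
        cohort.append((Genome(id=gid, seq=seq), truth))
    return cohort
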