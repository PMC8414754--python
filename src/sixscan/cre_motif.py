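"""Catabolite-responsive-element (cre) motif scanning at 6S RNA loci.

A position weight matrix trained on known cre sites is scanned over the
6S gene and its 100-nt upstream region on both strands.  Scores are
log-odds in bits against a first-order Markov background fitted to the
dinucleotide composition of the scanned genome, and each score gets an
exact p-value from a dynamic program over the full score distribution of
width-length windows under that background chain.  Sites are classified
as promoter-upstream (negative offset relative to the gene start) or
gene-internal.

The p-value DP discretizes per-position score contributions upward (ceil
to the resolution grid), which makes every reported p-value provably
conservative: never smaller than the exact tail probability, and within
``width * resolution`` of it in score.

cre sites are pseudo-palindromic; both strands are scanned.  The training
matrix used in the original study is not published, so the module ships a
small synthetic stand-in site list (:data:`SYNTHETIC_CRE_SITES`) and
accepts user-provided site lists in plain text (one site per line).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_core import Feature, Genome, SixscanError, revcomp

__all__ = [
    "PWM",
    "MarkovBackground",
    "MotifHit",
    "SYNTHETIC_CRE_SITES",
    "build_pwm",
    "read_sites",
    "fit_background",
    "logodds_score",
    "score_pvalue_table",
    "PValueTable",
    "scan_locus",
    "sample_site",
]

_BASE = {c: i for i, c in enumerate("ACGT")}

#: Synthetic stand-in training sites for the cre motif (14 nt, degenerate
#: pseudo-palindrome around the WTGNAARCGNWWWCAW-family consensus).  These
#: are constructed fixture data, not experimentally determined sites.
SYNTHETIC_CRE_SITES = [
    "ATGAAAGCGCTTTCAT",
    "TTGAAAGCGCTTTCAA",
    "ATGTAAGCGCTTACAT",
    "ATGAAAACGTTTTCAT",
    "TTGAAAACGTTTTCAA",
    "ATGACAGCGCTGTCAT",
    "AAGAAAGCGCTTTCTT",
    "ATGAAAGCGTTTTCAT",
    "ATGAAAGCGCTTTCAT",
    "TTGTAAGCGCTTACAA",
    "ATGAAATCGATTTCAT",
    "ATGAAAGCGCTTGCAT",
    "CTGAAAGCGCTTTCAG",
    "ATGAAAGGGCCTTCAT",
    "ATGAAAGCGCTTTAAT",
    "ATTAAAGCGCTTTAAT",
    "ATGAAAGCCCTTTCAT",
    "ATGCAAGCGCTTGCAT",
    "GTGAAAGCGCTTTCAC",
    "ATGAAAGTGCTTTCAT",
]


@dataclass
class PWM:
    """Column-stochastic base probabilities for a fixed-width motif."""

    width: int
    probs: np.ndarray  # shape (4, width), columns sum to 1
    pseudocount: float

    def __post_init__(self) -> None:
        if self.width < 1:
            raise SixscanError("PWM width must be >= 1")
        if self.probs.shape != (4, self.width):
            raise SixscanError("PWM probs must have shape (4, width)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-12):
            raise SixscanError("PWM columns must sum to 1")

    def revcomp(self) -> "PWM":
        return PWM(self.width, self.probs[::-1, ::-1].copy(), self.pseudocount)


@dataclass
class MarkovBackground:
    """First-order background: initial base frequencies plus transitions."""

    initial: np.ndarray     # shape (4,)
    transition: np.ndarray  # shape (4, 4), rows sum to 1

    def __post_init__(self) -> None:
        if not np.allclose(self.initial.sum(), 1.0, atol=1e-9):
            raise SixscanError("initial distribution must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise SixscanError("transition rows must sum to 1")
        if (self.initial <= 0).any() or (self.transition <= 0).any():
            raise SixscanError("background must be strictly positive; "
                               "use a positive smoothing constant")


@dataclass
class MotifHit:
    """A motif match positioned relative to the 6S gene start.

    ``position`` is the 0-based offset of the site's leftmost genomic base
    from the gene start (negative = upstream); ``region_class`` is
    'upstream' exactly when the offset is negative.
    """

    position: int
    strand: str
    score: float
    pvalue: float
    region_class: str
    seq: str = ""


def build_pwm(sites: Sequence[str], pseudocount: float = 0.5) -> PWM:
    """Per-column base counts plus pseudocount, normalized column-wise."""
    if len(sites) < 2:
        raise SixscanError("need at least 2 training sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise SixscanError("training sites must all have equal length")
    if pseudocount < 0:
        raise SixscanError("pseudocount must be >= 0")
    counts = np.zeros((4, width))
    for s in sites:
        for i, c in enumerate(s.upper()):
            if c not in _BASE:
                raise SixscanError(f"non-ACGT character {c!r} in site {s!r}")
            counts[_BASE[c], i] += 1
    counts += pseudocount
    return PWM(width, counts / counts.sum(axis=0, keepdims=True), pseudocount)


def read_sites(path) -> list[str]:
    """Plain-text site list: one site per line, '#' comments allowed."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                sites.append(line.upper().replace("U", "T"))
    return sites


def fit_background(genome: Genome, smoothing: float = 0.5) -> MarkovBackground:
    """Dinucleotide-derived first-order background of one genome.

    Transitions are smoothed conditional dinucleotide frequencies; the
    initial distribution is the (smoothed) mononucleotide composition.
    """
    if len(genome.seq) < 2:
        raise SixscanError("genome too short to fit a dinucleotide background")
    if smoothing <= 0:
        raise SixscanError("smoothing must be > 0 to keep the chain positive")
    enc = np.fromiter((_BASE[c] for c in genome.seq), dtype=np.int64)
    mono = np.bincount(enc, minlength=4).astype(float) + smoothing
    di = np.zeros((4, 4))
    np.add.at(di, (enc[:-1], enc[1:]), 1.0)
    di += smoothing
    return MarkovBackground(initial=mono / mono.sum(),
                            transition=di / di.sum(axis=1, keepdims=True))


def _window_contribs(pwm: PWM, bg: MarkovBackground,
                     preceding: int | None) -> list[np.ndarray]:
    """Per-position log2 odds: contribs[i][prev, cur] (position 0: [cur])."""
    first_probs = (bg.initial if preceding is None
                   else bg.transition[preceding])
    with np.errstate(divide="ignore"):  # zero PWM prob -> -inf, handled later
        out = [np.log2(pwm.probs[:, 0] / first_probs)]
        for i in range(1, pwm.width):
            out.append(np.log2(pwm.probs[np.newaxis, :, i] / bg.transition))
    return out


def logodds_score(pwm: PWM, window: str, bg: MarkovBackground,
                  preceding_base: str | None = None) -> float:
    """Log2 odds (bits) of ``window`` under the PWM vs the background chain.

    Position 0 is conditioned on ``preceding_base`` when given, otherwise
    on the background's initial distribution.
    """
    if len(window) != pwm.width:
        raise SixscanError(
            f"window length {len(window)} != PWM width {pwm.width}")
    enc = [_BASE[c] for c in window]
    prev = None if preceding_base is None else _BASE[preceding_base]
    first = (bg.initial[enc[0]] if prev is None
             else bg.transition[prev, enc[0]])
    total = math.log2(pwm.probs[enc[0], 0] / first)
    for i in range(1, pwm.width):
        total += math.log2(pwm.probs[enc[i], i]
                           / bg.transition[enc[i - 1], enc[i]])
    return total


class PValueTable:
    """Exact (conservatively discretized) score -> p-value map.

    One survival function is tabulated per conditioning state of the first
    window position: no preceding base (initial distribution) and each of
    the four possible preceding bases.
    """

    def __init__(self, pwm: PWM, bg: MarkovBackground, resolution: float):
        self.resolution = resolution
        self.pwm = pwm
        self._tables: dict[int | None, tuple[np.ndarray, int]] = {}
        for state in (None, 0, 1, 2, 3):
            self._tables[state] = self._build(pwm, bg, state)

    def _build(self, pwm: PWM, bg: MarkovBackground, preceding: int | None):
        res = self.resolution
        contribs = _window_contribs(pwm, bg, preceding)
        # ceil-discretized integer contributions: binned sum >= true sum.
        # A -inf contribution (zero PWM probability) makes the whole window
        # score -inf; such windows never count toward P(score >= s) for
        # finite s, so their mass is simply dropped from the distribution.
        ok0 = np.isfinite(contribs[0])
        oks = [np.isfinite(c) for c in contribs[1:]]
        if not ok0.any() or any(not ok.any() for ok in oks):
            return np.zeros(1), 0
        with np.errstate(invalid="ignore"):
            k0 = np.where(ok0, np.ceil(np.where(ok0, contribs[0], 0) / res),
                          0).astype(np.int64)
            ks = [np.where(ok, np.ceil(np.where(ok, c, 0) / res),
                           0).astype(np.int64)
                  for c, ok in zip(contribs[1:], oks)]
        lo = int(k0[ok0].min()) + sum(int(k[ok].min())
                                      for k, ok in zip(ks, oks))
        hi = int(k0[ok0].max()) + sum(int(k[ok].max())
                                      for k, ok in zip(ks, oks))
        nbins = hi - lo + 1
        # dist[cur_base, bin]
        dist = np.zeros((4, nbins))
        first_probs = (bg.initial if preceding is None
                       else bg.transition[preceding])
        # run_lo tracks the minimum achievable binned sum so far, so array
        # index 0 always corresponds to it and indices stay in range
        run_lo = int(k0[ok0].min())
        for c in range(4):
            if ok0[c]:
                dist[c, k0[c] - run_lo] += first_probs[c]
        for k, ok in zip(ks, oks):
            new_lo = run_lo + int(k[ok].min())
            new = np.zeros((4, nbins))
            for pbase in range(4):
                col = dist[pbase]
                nz = col.nonzero()[0]
                if nz.size == 0:
                    continue
                hi_nz = nz[-1] + 1
                for cbase in range(4):
                    if not ok[pbase, cbase]:
                        continue
                    shift = run_lo + int(k[pbase, cbase]) - new_lo
                    new[cbase, shift:shift + hi_nz] += (
                        col[:hi_nz] * bg.transition[pbase, cbase])
            dist = new
            run_lo = new_lo
        total = dist.sum(axis=0)
        # survival[i] = P(binned score >= (run_lo + i) * res)
        survival = np.cumsum(total[::-1])[::-1]
        return survival, run_lo

    def pvalue(self, score: float, preceding_base: str | None = None) -> float:
        """P(window score >= ``score``) under the background, conservatively.

        ``pvalue(-inf)`` is 1 by construction (total probability mass).
        """
        if math.isinf(score) and score < 0:
            return 1.0
        state = None if preceding_base is None else _BASE[preceding_base]
        survival, lo = self._tables[state]
        # smallest grid point >= score (tolerate float fuzz)
        k = math.ceil(score / self.resolution - 1e-9)
        idx = max(k - lo, 0)
        if idx >= survival.size:
            return 0.0
        return float(min(survival[idx], 1.0))

    def __call__(self, score: float, preceding_base: str | None = None) -> float:
        return self.pvalue(score, preceding_base)


def score_pvalue_table(pwm: PWM, bg: MarkovBackground,
                       resolution: float = 1e-3) -> PValueTable:
    """Tabulate the exact score distribution by dynamic programming.

    States are (position, last base, discretized score); contributions are
    rounded up to the resolution grid, so reported p-values are never
    smaller than the exact tail probability.
    """
    if resolution <= 0:
        raise SixscanError("resolution must be > 0")
    return PValueTable(pwm, bg, resolution)


def _scan_strand(region: str, preceding: str | None, pwm: PWM,
                 bg: MarkovBackground, table: PValueTable):
    """Yield (offset_in_region, score, pvalue) for every window, one strand."""
    w = pwm.width
    for j in range(len(region) - w + 1):
        prev = region[j - 1] if j > 0 else preceding
        s = logodds_score(pwm, region[j:j + w], bg, prev)
        yield j, s, table.pvalue(s, prev)


def scan_locus(pwm: PWM, bg: MarkovBackground, genome: Genome,
               ssrS: Feature, upstream_nt: int = 100,
               p_threshold: float = 1e-5, resolution: float = 1e-3,
               max_hits: int = 5,
               table: PValueTable | None = None) -> list[MotifHit]:
    """Scan the 6S gene plus its upstream region for cre sites.

    Both strands of ``[ssrS.start - upstream_nt, ssrS.end)`` (clipped to the
    genome) are scanned; hits at p-value <= ``p_threshold`` are reported in
    the gene's frame, overlapping same-strand hits reduced to the best
    p-value, and at most ``max_hits`` best hits kept per locus.
    """
    if not (0 <= ssrS.start < ssrS.end <= len(genome.seq)):
        raise SixscanError("ssrS feature outside genome bounds")
    if table is None:
        table = score_pvalue_table(pwm, bg, resolution)
    s0 = max(0, ssrS.start - upstream_nt)
    region = genome.seq[s0:ssrS.end]
    L = len(region)
    w = pwm.width
    if L < w:
        return []
    raw: list[MotifHit] = []
    preceding_fwd = genome.seq[s0 - 1] if s0 > 0 else None
    for j, score, pv in _scan_strand(region, preceding_fwd, pwm, bg, table):
        if pv <= p_threshold:
            pos = s0 + j - ssrS.start
            raw.append(MotifHit(pos, "+", score, pv,
                                "upstream" if pos < 0 else "internal",
                                region[j:j + w]))
    rc_region = revcomp(region)
    preceding_rev = (revcomp(genome.seq[ssrS.end])
                     if ssrS.end < len(genome.seq) else None)
    for j, score, pv in _scan_strand(rc_region, preceding_rev, pwm, bg, table):
        if pv <= p_threshold:
            fwd_start = s0 + (L - j - w)
            pos = fwd_start - ssrS.start
            raw.append(MotifHit(pos, "-", score, pv,
                                "upstream" if pos < 0 else "internal",
                                rc_region[j:j + w]))
    # overlap reduction: greedily keep the best p-value per same-strand pile
    raw.sort(key=lambda h: (h.pvalue, -h.score, h.position, h.strand))
    kept: list[MotifHit] = []
    for h in raw:
        clash = any(k.strand == h.strand
                    and h.position < k.position + w
                    and k.position < h.position + w
                    for k in kept)
        if not clash:
            kept.append(h)
    return kept[:max_hits]


def sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one site column-independently from the PWM."""
    return "".join(
        "ACGT"[rng.choice(4, p=pwm.probs[:, i])] for i in range(pwm.width))
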