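"""PWM building, dinucleotide background, exact p-values, locus scanning."""
import itertools
import math

import numpy as np
import pytest

from sixscan.cre_motif import (SYNTHETIC_CRE_SITES, MarkovBackground,
                               build_pwm, fit_background, logodds_score,
                               sample_site, scan_locus, score_pvalue_table)
from sixscan.io_core import Feature, Genome, SixscanError, revcomp

from conftest import random_dna

B = {c: i for i, c in enumerate("ACGT")}


def uniform_bg():
    return MarkovBackground(initial=np.full(4, 0.25),
                            transition=np.full((4, 4), 0.25))


def chain_probability(window, bg, preceding=None):
    p = (bg.initial[B[window[0]]] if preceding is None
         else bg.transition[B[preceding], B[window[0]]])
    for a, b in zip(window, window[1:]):
        p *= bg.transition[B[a], B[b]]
    return p


class TestBuildPwm:
    def test_pure_column_without_pseudocount(self):
        pwm = build_pwm(["AA", "AA"], pseudocount=0)
        assert pwm.probs[B["A"], 0] == 1.0

    def test_even_split(self):
        pwm = build_pwm(["A", "C"], pseudocount=0)
        assert pwm.probs[B["A"], 0] == pwm.probs[B["C"], 0] == 0.5

    def test_pseudocount_arithmetic(self):
        pwm = build_pwm(["A", "A"], pseudocount=0.5)
        assert pwm.probs[B["A"], 0] == pytest.approx(2.5 / 4)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(SixscanError):
            build_pwm(["AA", "AAA"])


class TestFitBackground:
    def test_homopolymer_transition_approaches_one(self):
        bg = fit_background(Genome("g", "A" * 1000), smoothing=1e-6)
        assert bg.transition[B["A"], B["A"]] == pytest.approx(1.0, abs=1e-6)

    def test_uniform_genome_near_quarter(self, rng):
        bg = fit_background(Genome("g", random_dna(rng, 100_000)))
        assert np.abs(bg.transition - 0.25).max() < 0.02

    def test_rows_always_stochastic(self, rng):
        bg = fit_background(Genome("g", random_dna(rng, 57)))
        assert np.allclose(bg.transition.sum(axis=1), 1.0)
        assert np.allclose(bg.initial.sum(), 1.0)


class TestLogOdds:
    def test_certain_column_uniform_background_two_bits(self):
        pwm = build_pwm(["A", "A"], pseudocount=0)
        assert logodds_score(pwm, "A", uniform_bg()) == pytest.approx(2.0)

    def test_pwm_equal_to_background_zero_bits(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0)
        assert logodds_score(pwm, "G", uniform_bg()) == pytest.approx(0.0)

    def test_width_two_hand_expansion(self):
        pwm = build_pwm(["AC", "AG"], pseudocount=0)
        bg = uniform_bg()
        expected = math.log2(1.0 / 0.25) + math.log2(0.5 / 0.25)
        assert logodds_score(pwm, "AC", bg) == pytest.approx(expected)

    def test_preceding_base_conditioning(self, rng):
        bg = fit_background(Genome("g", random_dna(rng, 5000)))
        pwm = build_pwm(["ACGT", "ACGA"])
        s_init = logodds_score(pwm, "ACGT", bg, None)
        s_cond = logodds_score(pwm, "ACGT", bg, "G")
        assert s_init != pytest.approx(s_cond)

    def test_width_mismatch_rejected(self):
        with pytest.raises(SixscanError):
            logodds_score(build_pwm(["AA", "AA"]), "A", uniform_bg())


class TestPvalueTable:
    def test_width_one_concentrated_pwm(self):
        pwm = build_pwm(["A", "A"], pseudocount=0)
        table = score_pvalue_table(pwm, uniform_bg())
        top = logodds_score(pwm, "A", uniform_bg())
        assert table.pvalue(top) == pytest.approx(0.25)

    def test_minus_infinity_is_one(self):
        pwm = build_pwm(["AC", "AG"])
        table = score_pvalue_table(pwm, uniform_bg())
        assert table.pvalue(float("-inf")) == 1.0

    def test_monotone_non_increasing(self, rng):
        sites = [random_dna(rng, 5) for _ in range(6)]
        bg = fit_background(Genome("g", random_dna(rng, 3000)))
        table = score_pvalue_table(build_pwm(sites), bg)
        grid = np.linspace(-15, 15, 61)
        pvals = [table.pvalue(s) for s in grid]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_conservative_and_tight_vs_enumeration(self, width):
        rng = np.random.default_rng(300 + width)
        sites = [random_dna(rng, width) for _ in range(8)]
        pwm = build_pwm(sites)
        bg = fit_background(Genome("g", random_dna(rng, 4000)))
        res = 1e-3
        table = score_pvalue_table(pwm, bg, resolution=res)
        for prev in (None, "C"):
            pairs = []
            for w in itertools.product("ACGT", repeat=width):
                w = "".join(w)
                pairs.append((logodds_score(pwm, w, bg, prev),
                              chain_probability(w, bg, prev)))
            for q in np.quantile([s for s, _ in pairs],
                                 [0.05, 0.3, 0.6, 0.9, 0.99]):
                exact = sum(p for s, p in pairs if s >= q)
                shifted = sum(p for s, p in pairs if s >= q - width * res)
                reported = table.pvalue(float(q), prev)
                assert reported >= exact - 1e-12          # conservative
                assert reported <= shifted + 1e-12        # discretization bound


class TestScanLocus:
    def _locus(self, rng, site, offset, gene_len=190, upstream=100):
        bg_seq = random_dna(rng, 2000)
        gene_start = 800
        seq = list(bg_seq)
        at = gene_start + offset
        seq[at:at + len(site)] = list(site)
        genome = Genome("g", "".join(seq))
        ssrS = Feature("g", gene_start, gene_start + gene_len, "+", "ssrS")
        return genome, ssrS

    def consensus(self):
        pwm = build_pwm(SYNTHETIC_CRE_SITES, pseudocount=0)
        return pwm, "".join("ACGT"[i] for i in np.argmax(pwm.probs, axis=0))

    def test_planted_consensus_upstream(self, rng):
        pwm, consensus = self.consensus()
        genome, ssrS = self._locus(rng, consensus, -60)
        bg = fit_background(genome)
        hits = scan_locus(build_pwm(SYNTHETIC_CRE_SITES), bg, genome, ssrS)
        plus = [h for h in hits if h.strand == "+"]
        assert plus and plus[0].position == -60
        assert plus[0].region_class == "upstream"

    def test_planted_consensus_internal(self, rng):
        pwm, consensus = self.consensus()
        genome, ssrS = self._locus(rng, consensus, +40)
        bg = fit_background(genome)
        hits = scan_locus(build_pwm(SYNTHETIC_CRE_SITES), bg, genome, ssrS)
        assert any(h.position == 40 and h.region_class == "internal"
                   for h in hits)

    def test_background_false_positive_rate_bounded(self, rng):
        # conservative p-values: observed hit counts must not exceed the
        # nominal threshold x window count allowance (one-sided, 3 SE)
        pwm = build_pwm([random_dna(rng, 10) for _ in range(6)])
        genome = Genome("g", random_dna(rng, 60_000))
        bg = fit_background(genome)
        table = score_pvalue_table(pwm, bg)
        thr = 1e-3
        n_loci, gene_len, upstream = 200, 100, 100
        total = 0
        for k in range(n_loci):
            start = 100 + k * 250
            ssrS = Feature("g", start, start + gene_len, "+", "ssrS")
            total += len(scan_locus(pwm, bg, genome, ssrS,
                                    upstream_nt=upstream, p_threshold=thr,
                                    table=table, max_hits=10**6))
        windows_per_locus = 2 * (gene_len + upstream - pwm.width + 1)
        bound = thr * windows_per_locus * n_loci
        assert total <= bound + 3 * math.sqrt(bound)

    def test_strand_symmetry_of_scores(self, rng):
        # under an iid complement-symmetric background, a window scores the
        # same as its reverse complement under the reverse-complemented PWM
        pwm = build_pwm([random_dna(rng, 8) for _ in range(5)])
        bg = uniform_bg()
        for _ in range(20):
            w = random_dna(rng, 8)
            assert logodds_score(pwm, w, bg) == pytest.approx(
                logodds_score(pwm.revcomp(), revcomp(w), bg))

    def test_minus_strand_site_detected(self, rng):
        pwm0, consensus = self.consensus()
        genome, ssrS = self._locus(rng, revcomp(consensus), -60)
        bg = fit_background(genome)
        hits = scan_locus(build_pwm(SYNTHETIC_CRE_SITES), bg, genome, ssrS)
        assert any(h.strand == "-" and h.position == -60 for h in hits)


def test_sample_site_deterministic(rng):
    pwm = build_pwm(SYNTHETIC_CRE_SITES)
    a = sample_site(pwm, np.random.default_rng(5))
    b = sample_site(pwm, np.random.default_rng(5))
    assert a == b and len(a) == pwm.width
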