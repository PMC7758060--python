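"""Cross-lineage pair statistics: segmentation, re-alignment, EVD p-values."""

import numpy as np
import pytest
from scipy import stats

from themebridge import (AlignConfig, BridgeCandidate, DomainRecord,
                         align_match_segments, empirical_pvalue,
                         flank_similarity, sample_random_segments,
                         segment_domain, select_representatives,
                         smith_waterman)
from themebridge.alignment import AlignmentResult
from themebridge.bridge import pvalue_from_fit
from themebridge.gumbel import GumbelFit
from themebridge.theme_search import ThemeHit
from themebridge._alphabet import AMINO_ACIDS


def _hit(dom, interval, length=None):
    return ThemeHit("t", dom, "2004", "f", interval, 50.0, 1e-5, 1.0,
                    length or (interval[1] - interval[0]))


class TestSegmentation:
    def test_internal_interval(self):
        d = DomainRecord("d", "2004", "f", "AAAGGGKKK")
        sd = segment_domain(d, _hit("d", (3, 6)))
        assert (sd.left_flank, sd.match_segment, sd.right_flank) == \
               ("AAA", "GGG", "KKK")
        assert sd.sequence == d.sequence

    def test_full_span_gives_empty_flanks(self):
        d = DomainRecord("d", "2004", "f", "AAAGGGKKK")
        sd = segment_domain(d, _hit("d", (0, 9)))
        assert sd.left_flank == "" and sd.right_flank == ""

    def test_prefix_interval(self):
        d = DomainRecord("d", "2004", "f", "AAAGGGKKK")
        sd = segment_domain(d, _hit("d", (0, 3)))
        assert sd.left_flank == "" and sd.match_segment == "AAA"

    def test_out_of_bounds_rejected(self):
        d = DomainRecord("d", "2004", "f", "AAA")
        with pytest.raises(ValueError, match="interval"):
            segment_domain(d, _hit("d", (1, 9)))

    def test_wrong_domain_rejected(self):
        d = DomainRecord("d", "2004", "f", "AAA")
        with pytest.raises(ValueError, match="hit is for"):
            segment_domain(d, _hit("other", (0, 3)))


class TestMatchRealignment:
    def test_identical_segments_stay_local(self):
        seg = "VLIVGPSGSGKSTLLRAIAGNELDA"
        res, mode = align_match_segments(seg, seg)
        assert mode == "SW"
        assert res.identity == 1.0
        assert res.a_length == len(seg)

    def test_short_shared_motif_falls_back_to_global(self):
        # only a high-scoring 5-mer in common; local covers 5/25 < 50%
        a = "P" * 10 + "WCWCW" + "P" * 10
        b = "G" * 10 + "WCWCW" + "G" * 10
        sw = smith_waterman(a, b)
        assert sw.a_length / len(a) < 0.5
        res, mode = align_match_segments(a, b)
        assert mode == "NW" and res.mode == "global"

    def test_printed_loop_self_alignment(self):
        res, mode = align_match_segments("VGPNGSGKSTV", "VGPNGSGKSTV")
        assert mode == "SW" and res.identity == 1.0

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            align_match_segments("", "GKT")


class TestRandomSegments:
    def test_degenerate_composition(self):
        assert sample_random_segments("AAAA", 5, seed=0) == ["AAAA"] * 5

    def test_lengths_match_template(self):
        segs = sample_random_segments("A" * 30, 50, seed=1)
        assert all(len(s) == 30 for s in segs)

    def test_frequency_concentration(self):
        segs = sample_random_segments("AC", 100_000, seed=2)
        freq_a = sum(s.count("A") for s in segs) / 200_000
        assert freq_a == pytest.approx(0.5, abs=0.01)

    def test_reproducible_under_seed(self):
        t = "GPNGSGKSTVADLVKEA"
        assert sample_random_segments(t, 20, seed=7) == \
               sample_random_segments(t, 20, seed=7)


class TestEmpiricalPvalue:
    def test_survival_at_location_closed_form(self):
        fit = GumbelFit(mu=10.0, beta=2.0, n_samples=1000)
        assert pvalue_from_fit(fit, 10.0) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_identical_low_entropy_segments_significant(self):
        seg = "GPSGSGKSTLLRAIAGNELDAVLIV"
        _, p = empirical_pvalue(seg, seg, n=500, seed=3)
        assert p < 0.05

    def test_null_pvalues_roughly_uniform(self):
        """Unrelated random 30-mers give ~uniform p-values (small-n check;
        the full 500-pair calibration lives in the acceptance tests)."""
        rng = np.random.default_rng(21)
        pvals = []
        for k in range(150):
            a = "".join(rng.choice(list(AMINO_ACIDS), 30))
            b = "".join(rng.choice(list(AMINO_ACIDS), 30))
            _, p = empirical_pvalue(a, b, n=500, seed=5000 + k)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monotone_in_observed_score(self):
        fit = GumbelFit(mu=20.0, beta=3.0, n_samples=1000)
        ps = [pvalue_from_fit(fit, s) for s in np.linspace(0, 60, 30)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)

    def test_zero_variance_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue("WWWWWWWWWW", "AAAAAAAAAA", n=200, seed=0)


class TestFlankSimilarity:
    def _sd(self, left, match, right, did="d"):
        from themebridge.bridge import SegmentedDomain
        return SegmentedDomain(did, left, match, right)

    def test_empty_flanks_score_zero(self):
        a = self._sd("", "GGG", "")
        b = self._sd("", "GGG", "", "e")
        assert flank_similarity(a, b) == 0.0

    def test_identical_flanks_double_self_score(self):
        flank = "WCPLHMRDEKNQSTVALGIF"
        a = self._sd(flank, "GGG", flank)
        b = self._sd(flank, "GGG", flank, "e")
        self_score = smith_waterman(flank, flank).score
        assert flank_similarity(a, b) == 2 * self_score

    def test_unrelated_flanks_score_lower(self):
        rng = np.random.default_rng(9)
        flank = "WCPLHMRDEKNQSTVALGIF"
        rand = "".join(rng.choice(list(AMINO_ACIDS), 20))
        same = flank_similarity(self._sd(flank, "G", flank),
                                self._sd(flank, "G", flank, "e"))
        diff = flank_similarity(self._sd(flank, "G", flank),
                                self._sd(rand, "G", rand[::-1], "e"))
        assert diff < same


def _cand(theme, p, sim, dom_b="b"):
    aln = AlignmentResult("local", 50.0, (0, 10), (0, 10), (), 1.0)
    return BridgeCandidate(theme, "a", dom_b, aln, "SW", p, sim)


class TestRepresentatives:
    def test_ranking_by_pvalue_then_flank_dissimilarity(self):
        cands = [_cand("t", 0.001, 50.0, "b1"),
                 _cand("t", 0.003, 10.0, "b2"),
                 _cand("t", 0.003, 40.0, "b3")]
        kept = select_representatives(cands, k=2)
        assert [(c.match_pvalue, c.flank_similarity) for c in kept] == \
               [(0.001, 50.0), (0.003, 10.0)]

    def test_single_candidate_kept(self):
        assert len(select_representatives([_cand("t", 0.01, 5.0)], k=2)) == 1

    def test_permutation_invariant(self):
        cands = [_cand("t", p, s, f"b{i}") for i, (p, s) in enumerate(
            [(0.04, 3.0), (0.001, 9.0), (0.02, 1.0), (0.02, 0.5)])]
        a = select_representatives(cands, k=2)
        b = select_representatives(list(reversed(cands)), k=2)
        assert a == b

    def test_retention_boundary_is_strict(self):
        assert _cand("t", 0.049, 0.0).retained
        assert not _cand("t", 0.05, 0.0).retained
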