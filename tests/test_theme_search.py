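"""Profile construction, E-value calibration and the hit filters."""

import numpy as np
import pytest

from themebridge import (DomainRecord, ThemeAlignment, build_profile,
                         calibrate_evalue, evalue, find_bridging_themes,
                         fit_gumbel, passes_filters, scan_database,
                         uniform_background)
from themebridge._alphabet import ALPHABET, AMINO_ACIDS
from themebridge.theme_search import ThemeHit
from themebridge.synthetic import PlantedTheme, generate_theme_msa


class TestBuildProfile:
    def test_column_score_formula(self):
        """Hand evaluation: all-'G' column of 4 rows, pseudocount 1, uniform bg."""
        t = ThemeAlignment("t", ("G", "G", "G", "G"))
        p = build_profile(t, pseudocount=1.0, background=uniform_background())
        g = ALPHABET.index("G")
        expected_g = np.log2((4 + 1 * 0.05) / ((4 + 1) * 0.05))
        expected_other = np.log2((0 + 0.05) / (5 * 0.05))
        assert p.column_scores[0, g] == pytest.approx(expected_g)
        assert p.column_scores[0, ALPHABET.index("A")] == pytest.approx(expected_other)

    def test_width_matches_theme(self):
        t = ThemeAlignment("t", ("GKT", "GRT"))
        assert build_profile(t).width == 3

    def test_single_row_positive_on_observed(self):
        t = ThemeAlignment("t", ("GKT",))
        p = build_profile(t, pseudocount=0.5)
        for c, r in enumerate("GKT"):
            assert p.column_scores[c, ALPHABET.index(r)] > 0
        assert np.isfinite(p.column_scores[:, :20]).all()

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            build_profile(ThemeAlignment("t", ("GKT",)), pseudocount=0.0)

    def test_gap_characters_excluded_from_counts(self):
        t = ThemeAlignment("t", ("G-", "GA"))
        p = build_profile(t, pseudocount=1.0)
        a = ALPHABET.index("A")
        # column 1 has one non-gap row: count(A)=1, n_c=1
        assert p.column_scores[1, a] == pytest.approx(
            np.log2((1 + 0.05) / (2 * 0.05)))


def _random_db(rng, n=30, length=120):
    return [DomainRecord(f"d{i}", "2004" if i % 2 else "2003", "f",
                         "".join(rng.choice(list(AMINO_ACIDS), size=length)))
            for i in range(n)]


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        """MoM + ML fitting recovers Gumbel(10, 2) from 10000 samples."""
        rng = np.random.default_rng(5)
        samples = rng.gumbel(10.0, 2.0, size=10000)
        fit = fit_gumbel(samples)
        assert fit.mu == pytest.approx(10.0, abs=0.1)
        assert fit.beta == pytest.approx(2.0, abs=0.1)

    def test_evalue_monotone_and_limit(self):
        fit = fit_gumbel(np.random.default_rng(0).gumbel(12, 3, 1000))
        scores = np.linspace(-50, 80, 40)
        es = [evalue(fit, s, db_size=500) for s in scores]
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(es, es[1:]))
        assert evalue(fit, -1e9, db_size=500) == pytest.approx(500.0)

    def test_shuffle_null_reproducible(self):
        rng = np.random.default_rng(2)
        db = _random_db(rng)
        msa = generate_theme_msa(seed=3)
        p = build_profile(msa)
        f1 = calibrate_evalue(p, db, n_shuffles=200, seed=9)
        f2 = calibrate_evalue(p, db, n_shuffles=200, seed=9)
        assert f1 == f2

    def test_too_few_shuffles_rejected(self):
        db = _random_db(np.random.default_rng(0), n=2)
        p = build_profile(generate_theme_msa(seed=0))
        with pytest.raises(ValueError, match="n_shuffles"):
            calibrate_evalue(p, db, n_shuffles=10, seed=0)


class TestScan:
    def test_planted_consensus_is_top_hit(self):
        """A domain carrying the theme consensus verbatim tops the scan."""
        rng = np.random.default_rng(7)
        theme = PlantedTheme()
        db = _random_db(rng, n=25)
        planted_seq = ("".join(rng.choice(list(AMINO_ACIDS), 60)) + theme.core
                       + "".join(rng.choice(list(AMINO_ACIDS), 60)))
        db.append(DomainRecord("planted", "2004", "f", planted_seq))
        p = build_profile(generate_theme_msa(theme, seed=1))
        fit = calibrate_evalue(p, db, n_shuffles=300, seed=4)
        hits = scan_database(p, db, fit)
        assert hits and hits[0].domain_id == "planted"
        assert hits[0].coverage == 1.0
        assert hits[0].interval == (60, 60 + len(theme.core))

    def test_empty_database(self):
        p = build_profile(generate_theme_msa(seed=0))
        fit = fit_gumbel(np.random.default_rng(0).gumbel(10, 2, 500))
        assert scan_database(p, [], fit) == []


class TestFilters:
    @pytest.mark.parametrize("ev,cov,length,kept", [
        (1e-4, 0.90, 25, True),    # clears all three
        (1e-2, 0.90, 25, False),   # E-value too large
        (1e-3, 0.90, 25, False),   # E-value must be strictly below 1e-3
        (9.99e-4, 0.90, 25, True),
        (1e-4, 0.84, 25, False),   # coverage below 85%
        (1e-4, 0.85, 25, True),    # coverage threshold is inclusive
        (1e-4, 0.90, 19, False),   # shorter than 20 residues
        (1e-4, 0.90, 20, True),    # minimal length is inclusive
    ])
    def test_retention_thresholds_exact(self, ev, cov, length, kept):
        assert passes_filters(ev, cov, length) is kept
        hit = ThemeHit("t", "d", "2004", "f", (0, length), 50.0, ev, cov, length)
        assert hit.passes_filters is kept


class TestBridging:
    def _hit(self, theme, dom, lineage):
        return ThemeHit(theme, dom, lineage, "f", (0, 25), 50.0, 1e-5, 1.0, 25)

    def test_single_lineage_theme_excluded(self):
        hits = [self._hit("t1", "a1", "2004"), self._hit("t1", "a2", "2004")]
        assert find_bridging_themes(hits, "2004", "2003") == []

    def test_intersection_sizes(self):
        hits = [self._hit("t1", "a1", "2004")]
        hits += [self._hit("t1", f"b{i}", "2003") for i in range(57)]
        out = find_bridging_themes(hits, "2004", "2003")
        assert len(out) == 1
        assert (len(out[0].hits_lineage_A), len(out[0].hits_lineage_B)) == (1, 57)

    def test_empty_input(self):
        assert find_bridging_themes([], "2004", "2003") == []

    def test_unknown_lineage_label(self):
        hits = [self._hit("t1", "a1", "2004"), self._hit("t1", "b1", "2003")]
        with pytest.raises(ValueError, match="unknown lineage"):
            find_bridging_themes(hits, "2004", "9999",
                                 known_lineages={"2004", "2003"})

    def test_deterministic_order_by_theme_id(self):
        hits = []
        for t in ("tB", "tA"):
            hits += [self._hit(t, f"{t}a", "2004"), self._hit(t, f"{t}b", "2003")]
        out = find_bridging_themes(hits, "2004", "2003")
        assert [bt.theme_id for bt in out] == ["tA", "tB"]
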