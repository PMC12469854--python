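from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senosynergy.deg_sets import GeneSet
from senosynergy.enrichment import (
    AnnotationTerm,
    bh_adjust,
    enrich,
    hypergeom_upper_tail,
    read_gmt,
    results_to_frame,
)
from senosynergy.geneset_assembly import GeneUniverse


def exact_upper_tail(x, n, K, N):
    """Independent oracle: sum the exact pmf via binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, k) * comb(N - K, n - k) for k in range(x, min(n, K) + 1)) / total


class TestHypergeom:
    def test_worked_example(self):
        # enumeration: P(X>=2) with N=10, K=3, n=4 is (63 + 7)/210
        assert hypergeom_upper_tail(2, 4, 3, 10) == pytest.approx(70 / 210, abs=1e-12)

    def test_x_zero_is_one(self):
        assert hypergeom_upper_tail(0, 4, 3, 10) == 1.0

    def test_degenerate_population(self):
        assert hypergeom_upper_tail(3, 3, 3, 3) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_instance(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 3, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 3, 10)

    def test_matches_exact_enumeration_small_N(self):
        # exhaustive over all valid instances with N <= 12
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for x in range(min(n, K) + 1):
                        assert hypergeom_upper_tail(x, n, K, N) == pytest.approx(
                            exact_upper_tail(x, n, K, N), abs=1e-12
                        )

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_exact_enumeration_to_25(self, data):
        N = data.draw(st.integers(1, 25))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        x = data.draw(st.integers(0, min(n, K)))
        assert hypergeom_upper_tail(x, n, K, N) == pytest.approx(
            exact_upper_tail(x, n, K, N), abs=1e-12
        )


class TestBHAdjust:
    def test_hand_worked_stepup(self):
        # p(i) * m/i = [.04, .04, .04, .04]; already monotone
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_identity(self):
        assert bh_adjust([0.3]) == [0.3]

    def test_monotone_enforcement(self):
        # raw step-up values [0.09, 0.05] must be flattened from the top rank
        assert bh_adjust([0.03, 0.05]) == pytest.approx([0.05, 0.05])

    def test_capped_at_one(self):
        out = bh_adjust([0.9, 0.95, 1.0])
        assert all(v <= 1.0 for v in out)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        assert bh_adjust(pvals) == pytest.approx(list(expected), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, pvals, rnd):
        order = list(range(len(pvals)))
        rnd.shuffle(order)
        base = bh_adjust(pvals)
        shuffled = bh_adjust([pvals[i] for i in order])
        for out_pos, in_pos in enumerate(order):
            assert shuffled[out_pos] == pytest.approx(base[in_pos])


def term(tid, members, desc="d"):
    return AnnotationTerm(tid, desc, frozenset(members))


class TestEnrich:
    @pytest.fixture
    def universe(self):
        return GeneUniverse.from_ids([f"g{i:02d}" for i in range(20)])

    def test_count_and_filter(self, universe):
        study = GeneSet("s", {"g00", "g01", "g02", "g03"})
        terms = [
            term("t1", {"g00", "g01", "g02", "g03"}),
            term("t2", {"g00", "g10"}),
            term("t3", {"g10", "g11"}),  # disjoint from study -> filtered
        ]
        results = enrich(study, terms, universe)
        assert [r.term_id for r in results] == ["t1"]
        assert results[0].count == 4

    def test_min_count_one_keeps_single_hits(self, universe):
        study = GeneSet("s", {"g00"})
        results = enrich(study, [term("t", {"g00", "g01"})], universe, min_count=1)
        assert results[0].count == 1

    def test_pvalues_match_bruteforce(self, universe):
        # exhaustive oracle: enumerate all draws of size |study| from the universe
        study_genes = {"g00", "g01", "g02"}
        study = GeneSet("s", study_genes)
        terms = [
            term("t1", {"g00", "g01", "g05"}),
            term("t2", {"g02", "g06", "g07", "g08"}),
            term("t3", {"g00", "g01", "g02"}),
        ]
        results = enrich(study, terms, universe, min_count=1)
        for r in results:
            members = next(t.members for t in terms if t.term_id == r.term_id)
            hits = 0
            total = 0
            for draw in combinations(universe.genes, len(study_genes)):
                total += 1
                if len(set(draw) & members) >= r.count:
                    hits += 1
            assert r.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_bh_over_all_terms_not_just_reported(self, universe):
        study = GeneSet("s", {"g00", "g01"})
        reported = term("hit", {"g00", "g01"})
        filler = [term(f"f{i}", {"g10", "g11"}) for i in range(5)]
        only = enrich(study, [reported], universe)[0]
        with_filler = enrich(study, [reported, *filler], universe)[0]
        # six tested terms inflate the BH adjustment relative to one
        assert with_filler.p_adjusted >= only.p_adjusted

    def test_outside_universe_dropped(self, universe, caplog):
        study = GeneSet("s", {"g00", "g01", "NOT_A_GENE"})
        with caplog.at_level("WARNING"):
            results = enrich(study, [term("t", {"g00", "g01"})], universe)
        assert results[0].count == 2
        assert "outside the universe" in caplog.text

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            enrich(GeneSet("s", {"a"}), [], GeneUniverse([]))

    def test_ordering(self, universe):
        study = GeneSet("s", set(universe.genes[:6]))
        terms = [
            term("b2", {"g00", "g01"}),
            term("a2", {"g00", "g01"}),
            term("c3", {"g00", "g01", "g02"}),
        ]
        results = enrich(study, terms, universe)
        assert [r.term_id for r in results] == ["c3", "a2", "b2"]

    def test_adding_nonstudy_gene_never_decreases_p(self, universe):
        study = GeneSet("s", {"g00", "g01", "g02"})
        base = term("t", {"g00", "g01"})
        grown = term("t", {"g00", "g01", "g15"})
        p_base = enrich(study, [base], universe, min_count=1)[0].p_value
        p_grown = enrich(study, [grown], universe, min_count=1)[0].p_value
        assert p_grown >= p_base - 1e-15


class TestGMT:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("t1\tfirst term\tg1\tg2\tg3\nt2\tsecond\tg2\n")
        terms = read_gmt(p)
        assert terms[0].members == {"g1", "g2", "g3"}
        assert terms[1].description == "second"

    def test_duplicate_term_id(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("t1\td\tg1\nt1\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_short_line(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("t1\tdesc\n")
        with pytest.raises(ValueError, match="3 fields"):
            read_gmt(p)


def test_results_frame_slash_joined(small_universe):
    u = GeneUniverse.from_ids(["a", "b", "c", "d"])
    study = GeneSet("s", {"a", "b"})
    df = results_to_frame(enrich(study, [term("t", {"a", "b"})], u))
    assert df.loc[0, "Gene ID"] == "a/b"
    assert df.loc[0, "Count"] == 2
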