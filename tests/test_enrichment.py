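"""Enrichment ratio, exact hypergeometric tails, scoring and the ER matrix."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import edgesign as es
from edgesign.enrichment import (
    ContingencyCounts,
    lower_tail,
    upper_tail,
    write_er_matrix,
    write_pair_scores,
)


def enumerate_tail(N, M, n, m, upper):
    """Independent oracle: enumerate every n-subset of an N population
    whose first M members are 'successes' and count tail draws exactly."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        successes = sum(1 for i in draw if i < M)
        if (successes >= m) if upper else (successes <= m):
            hits += 1
    return Fraction(hits, total)


class TestEnrichmentRatio:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ContingencyCounts(10, 5, 4, 2), 1.0),      # m/M == n/N
            (ContingencyCounts(100, 40, 10, 8), 2.0),   # worked example
            (ContingencyCounts(100, 40, 10, 0), 0.0),   # zero numerator
        ],
    )
    def test_examples(self, counts, expected):
        assert es.enrichment_ratio(counts) == pytest.approx(expected)

    def test_degenerate_counts_error(self):
        with pytest.raises(ValueError):
            es.enrichment_ratio(ContingencyCounts(10, 0, 3, 0))
        with pytest.raises(ValueError):
            es.enrichment_ratio(ContingencyCounts(10, 4, 0, 0))

    def test_strictly_increasing_in_m(self):
        ers = [es.enrichment_ratio(ContingencyCounts(20, 10, 8, m)) for m in range(9)]
        assert all(a < b for a, b in zip(ers, ers[1:]))


class TestHypergeomPvalue:
    def test_upper_tail_worked_example(self):
        # N=10, M=4, n=3, m=2; ER = 5/3 >= 1 -> P(X >= 2) = 1/3
        p = es.hypergeom_pvalue(ContingencyCounts(10, 4, 3, 2))
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_lower_tail_worked_example(self):
        # m=0 -> ER < 1 -> P(X <= 0) = C(6,3)/C(10,3) = 1/6
        p = es.hypergeom_pvalue(ContingencyCounts(10, 4, 3, 0))
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_degenerate_population_m_equals_n(self):
        # M=N: X == n deterministically; upper tail at m=n is 1
        assert es.hypergeom_pvalue(ContingencyCounts(5, 5, 3, 3)) == pytest.approx(1.0)

    def test_er_exactly_one_takes_upper_branch(self):
        counts = ContingencyCounts(10, 5, 4, 2)  # ER == 1 exactly
        assert es.hypergeom_pvalue(counts) == pytest.approx(
            float(enumerate_tail(10, 5, 4, 2, upper=True)), abs=1e-12
        )

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(2, 9))
        M = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        m = data.draw(st.integers(max(0, n - (N - M)), min(n, M)))
        counts = ContingencyCounts(N, M, n, m)
        upper = Fraction(m, M) >= Fraction(n, N)
        expected = float(enumerate_tail(N, M, n, m, upper))
        assert es.hypergeom_pvalue(counts) == pytest.approx(expected, abs=1e-12)

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_tail_complementarity_and_range(self, data):
        N = data.draw(st.integers(2, 40))
        M = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        lo = max(0, n - (N - M))
        m = data.draw(st.integers(max(lo, 1), max(lo, 1, min(n, M))))
        counts = ContingencyCounts(N, M, n, min(m, min(n, M)))
        u = upper_tail(counts)
        l = lower_tail(ContingencyCounts(N, M, n, counts.m - 1)) if counts.m else 0.0
        assert 0.0 <= u <= 1.0
        assert u + l == pytest.approx(1.0, abs=1e-12)

    def test_upper_tail_nonincreasing_in_m(self):
        ps = [upper_tail(ContingencyCounts(30, 12, 10, m)) for m in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestPairExtraction:
    def test_cartesian_product(self, toy_catalog):
        pairs = es.extract_term_pairs(es.InteractionRecord("A", "B"), toy_catalog)
        assert pairs == {es.TermPair("t1", "t3", "go"), es.TermPair("t2", "t3", "go")}

    def test_unannotated_protein_gives_empty(self, toy_catalog):
        assert es.extract_term_pairs(es.InteractionRecord("E", "B"), toy_catalog) == frozenset()

    def test_undirected_canonical_order(self, toy_catalog):
        pairs = es.extract_term_pairs(
            es.InteractionRecord("B", "C"), toy_catalog, directed=False
        )
        assert pairs == {es.TermPair("t1", "t3", "go")}


class TestCountPairOccurrences:
    def test_toy_counts_match_enumeration(self, toy_catalog, toy_interactions):
        # pair (t1, t3): in A->B and C->B (both activation) => n=2, m=2
        # pair (t1, t4): in A->D (act) and C->D (inh) => n=2, m=1
        counts = es.count_pair_occurrences(toy_interactions, toy_catalog)
        assert counts[es.TermPair("t1", "t3", "go")] == ContingencyCounts(4, 3, 2, 2)
        assert counts[es.TermPair("t1", "t4", "go")] == ContingencyCounts(4, 3, 2, 1)

    def test_no_zero_support_entries_and_constant_totals(self, toy_catalog, toy_interactions):
        counts = es.count_pair_occurrences(toy_interactions, toy_catalog)
        assert all(c.n >= 1 for c in counts.values())
        assert {(c.N, c.M) for c in counts.values()} == {(4, 3)}

    def test_unlabeled_record_errors(self, toy_catalog):
        s = es.InteractionSet(records=[es.InteractionRecord("A", "B")])
        with pytest.raises(ValueError, match="unlabeled"):
            es.count_pair_occurrences(s, toy_catalog)


class TestScoreAllPairs:
    def test_empty_interactions_give_empty_table(self, toy_catalog):
        table = es.score_all_pairs(es.InteractionSet(), toy_catalog)
        assert len(table) == 0

    def test_single_tested_pair_q_equals_p(self):
        cat = es.AnnotationCatalog("go", {"A": {"x"}, "B": {"y"}})
        s = es.InteractionSet(
            records=[
                es.InteractionRecord("A", "B", "activation"),
                es.InteractionRecord("A", "B", "inhibition"),
            ]
        )
        table = es.score_all_pairs(s, cat)
        assert len(table) == 1
        assert table.scores[0].q_value == pytest.approx(table.scores[0].p_value)

    def test_planted_pair_flagged_significant(self):
        # one pair in all-and-only the 6 activation edges; 6 inhibition edges
        # share a different pair: counts (N=12, M=6, n=6, m=6) both sides
        entries = {}
        recs = []
        for i in range(6):
            entries[f"S{i}"] = {"a"}
            entries[f"T{i}"] = {"b"}
            recs.append(es.InteractionRecord(f"S{i}", f"T{i}", "activation"))
        for i in range(6):
            entries[f"U{i}"] = {"c"}
            entries[f"V{i}"] = {"d"}
            recs.append(es.InteractionRecord(f"U{i}", f"V{i}", "inhibition"))
        table = es.score_all_pairs(
            es.InteractionSet(records=recs), es.AnnotationCatalog("go", entries)
        )
        sig = {s.pair for s in table.significant_scores()}
        # P(X=6 | N=12, M=6, n=6) = 1/C(12,6) = 1/924; BH over 2 tests keeps both
        assert es.TermPair("a", "b", "go") in sig
        by_pair = {s.pair: s for s in table}
        assert by_pair[es.TermPair("a", "b", "go")].p_value == pytest.approx(1 / 924, abs=1e-12)

    def test_row_order_invariance(self, toy_catalog, toy_interactions):
        shuffled = es.InteractionSet(records=list(reversed(toy_interactions.records)))
        t1 = es.score_all_pairs(toy_interactions, toy_catalog)
        t2 = es.score_all_pairs(shuffled, toy_catalog)
        assert [(s.pair, s.er, s.p_value) for s in t1] == [(s.pair, s.er, s.p_value) for s in t2]

    def test_serialization_roundtrip_columns(self, tmp_path, toy_catalog, toy_interactions):
        table = es.score_all_pairs(toy_interactions, toy_catalog)
        path = str(tmp_path / "scores.tsv")
        n = write_pair_scores(table, path)
        lines = open(path).read().splitlines()
        assert n == len(table) and len(lines) == n + 1
        assert lines[0].split("\t")[:2] == ["left_term", "right_term"]


class TestErMatrix:
    def test_singleton(self):
        cat = es.AnnotationCatalog("go", {"A": {"x"}, "B": {"y"}})
        s = es.InteractionSet(
            records=[
                es.InteractionRecord("A", "B", "activation"),
                es.InteractionRecord("A", "B", "inhibition"),
            ]
        )
        m = es.er_matrix(es.score_all_pairs(s, cat))
        assert m.values.shape == (1, 1)
        assert m.row_order == [0] and m.col_order == [0]

    def test_values_match_direct_arithmetic(self, toy_catalog, toy_interactions):
        table = es.score_all_pairs(toy_interactions, toy_catalog)
        m = es.er_matrix(table)
        by_pair = {s.pair: s.er for s in table}
        for s_pair, er in by_pair.items():
            i = m.row_terms.index(s_pair.left)
            j = m.col_terms.index(s_pair.right)
            assert m.values[i, j] == pytest.approx(er)
        # untested cells are exactly zero
        tested = {(p.left, p.right) for p in by_pair}
        for i, left in enumerate(m.row_terms):
            for j, right in enumerate(m.col_terms):
                if (left, right) not in tested:
                    assert m.values[i, j] == 0.0

    def test_identical_rows_cluster_adjacent(self):
        entries = {"A": {"x1"}, "B": {"x2"}, "C": {"z"}, "T": {"y"}, "U": {"w"}}
        recs = []
        # x1 and x2 behave identically; z differs
        for left in ("A", "B"):
            recs += [
                es.InteractionRecord(left, "T", "activation"),
                es.InteractionRecord(left, "U", "inhibition"),
            ]
        recs += [
            es.InteractionRecord("C", "T", "inhibition"),
            es.InteractionRecord("C", "U", "activation"),
        ]
        table = es.score_all_pairs(
            es.InteractionSet(records=recs), es.AnnotationCatalog("go", entries)
        )
        m = es.er_matrix(table)
        i1 = m.row_order.index(m.row_terms.index("x1"))
        i2 = m.row_order.index(m.row_terms.index("x2"))
        assert abs(i1 - i2) == 1

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            es.er_matrix(es.PairScoreTable())

    def test_write_matrix_shape(self, tmp_path, toy_catalog, toy_interactions):
        m = es.er_matrix(es.score_all_pairs(toy_interactions, toy_catalog))
        path = str(tmp_path / "er.tsv")
        write_er_matrix(m, path)
        lines = open(path).read().splitlines()
        assert len(lines) == len(m.row_terms) + 1
        assert len(lines[1].split("\t")) == len(m.col_terms) + 1
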