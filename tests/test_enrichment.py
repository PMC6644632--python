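"""Hypergeometric ORA, BH adjustment, pooling, universe resolution."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from termnet.enrichment import (
    EnrichmentQuery,
    bh_adjust,
    bonferroni_adjust,
    enrichment_matrix,
    hypergeom_p,
    neg_log10_capped,
    resolve_universe,
    results_table,
    term_enrichment,
)
from termnet.resources import GeneSet, GeneSetResource
from termnet.synthetic import gene_symbols


def exact_tail(k, K, n, N):
    """Big-integer oracle: P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(num, math.comb(N, n))


class TestHypergeomP:
    @pytest.mark.parametrize(
        "k, K, n, N, expected",
        [
            (2, 3, 2, 10, 3 / 45),  # C(3,2)C(7,0)/C(10,2)
            (0, 5, 4, 20, 1.0),  # empty overlap: whole tail
            (5, 5, 5, 20, 1 / 15504),  # perfect overlap: 1/C(20,5)
        ],
    )
    def test_known_values(self, k, K, n, N, expected):
        assert hypergeom_p(k, K, n, N) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "args",
        [(3, 2, 5, 10), (1, 11, 2, 10), (1, 2, 11, 10), (-1, 2, 2, 10), (0, 0, 0, 0)],
    )
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            hypergeom_p(*args)

    def test_agrees_with_fisher_exact(self):
        # one-sided Fisher on the 2x2 table is the same tail probability
        for k, K, n, N in [(3, 8, 6, 30), (1, 4, 10, 25), (5, 5, 9, 40)]:
            table = [[k, n - k], [K - k, N - K - n + k]]
            fisher = stats.fisher_exact(table, alternative="greater")[1]
            assert hypergeom_p(k, K, n, N) == pytest.approx(fisher, rel=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exact_oracle_and_monotone_in_overlap(self, data):
        N = data.draw(st.integers(2, 50))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        lo, hi = max(0, K + n - N), min(K, n)
        prev = None
        for k in range(lo, hi + 1):
            p = hypergeom_p(k, K, n, N)
            assert p == pytest.approx(float(exact_tail(k, K, n, N)), rel=1e-12)
            if prev is not None:
                assert p <= prev + 1e-15  # non-increasing in overlap
            prev = p


def bh_oracle(p):
    """Independent step-up: sort, scale by m/rank, cumulative min, unsort."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_sorted_input_gives_non_decreasing_output(self):
        p = np.linspace(0.001, 0.9, 40)
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_independent_oracle_and_statsmodels(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), rtol=0, atol=0)
        from statsmodels.stats.multitest import multipletests

        sm_q = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, sm_q, rtol=1e-12, atol=1e-15)

    def test_order_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_bonferroni_hook(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01, 0.4]), [0.02, 0.8])


def _resource(name, sets):
    return GeneSetResource(name, [GeneSet(n, "", frozenset(g)) for n, g in sets.items()])


class TestTermEnrichment:
    def _fixture(self, seed=0, n_terms=10, term_size=8, universe_size=200):
        rng = np.random.default_rng(seed)
        universe = gene_symbols(universe_size)
        def draw():
            return {
                f"T{i}": set(rng.choice(universe, size=term_size, replace=False))
                for i in range(n_terms)
            }
        r1 = _resource("r1", draw())
        r2 = _resource("r2", {f"S{i}": g for i, (_, g) in enumerate(draw().items())})
        return r1, r2, frozenset(universe)

    def test_pooled_correction_spans_all_resources(self):
        """Two resources of 10 terms -> one BH correction over 20 p-values."""
        r1, r2, universe = self._fixture()
        query = EnrichmentQuery("q", frozenset(list(r1["T0"].genes)[:5] + sorted(universe)[:10]), universe)
        results, _ = term_enrichment(query, [r1, r2], min_term_size=1, max_term_size=500)
        assert len(results) == 20
        expected_q = bh_adjust([r.p_value for r in results])
        np.testing.assert_allclose([r.q_value for r in results], expected_q)

    def test_pooled_q_geq_single_resource_q(self):
        r1, r2, universe = self._fixture(seed=5)
        query = EnrichmentQuery("q", frozenset(sorted(universe)[:25]), universe)
        pooled, _ = term_enrichment(query, [r1, r2], min_term_size=1)
        single, _ = term_enrichment(query, [r1], min_term_size=1)
        single_q = {r.term: r.q_value for r in single}
        for r in pooled:
            if r.resource == "r1":
                assert r.q_value >= single_q[r.term] - 1e-15

    def test_query_equal_to_universe_gives_p_one_everywhere(self):
        r1, _, universe = self._fixture()
        query = EnrichmentQuery("all", universe, universe)
        results, _ = term_enrichment(query, [r1], min_term_size=1)
        assert all(r.p_value == 1.0 for r in results)

    def test_single_term_bh_identity(self):
        universe = frozenset(gene_symbols(40))
        genes = frozenset(sorted(universe)[:8])
        res = _resource("r", {"only": set(sorted(universe)[:10])})
        query = EnrichmentQuery("q", genes, universe)
        results, _ = term_enrichment(query, [res], min_term_size=1)
        (r,) = results
        assert r.q_value == pytest.approx(r.p_value)

    def test_size_filter_reported_and_all_filtered_is_error(self):
        universe = frozenset(gene_symbols(100))
        res = _resource("r", {"small": set(sorted(universe)[:2]), "ok": set(sorted(universe)[:20])})
        query = EnrichmentQuery("q", frozenset(sorted(universe)[:10]), universe)
        results, skip = term_enrichment(query, [res], min_term_size=5, max_term_size=500)
        assert len(results) == 1 and skip.too_small == 1
        with pytest.raises(ValueError, match="filtered out"):
            term_enrichment(query, [res], min_term_size=50, max_term_size=500)

    def test_result_reproducible_from_stored_counts(self):
        r1, r2, universe = self._fixture(seed=9)
        query = EnrichmentQuery("q", frozenset(sorted(universe)[:30]), universe)
        results, _ = term_enrichment(query, [r1, r2], min_term_size=1)
        for r in results:
            assert r.p_value == hypergeom_p(
                r.n_overlap, r.n_term_in_universe, r.n_query, r.n_universe
            )

    def test_query_outside_universe_dropped_with_warning(self):
        universe = frozenset({"A", "B", "C", "D"})
        with pytest.warns(UserWarning, match="absent from universe"):
            q = EnrichmentQuery.from_genes("q", {"A", "E"}, universe)
        assert q.genes == frozenset({"A"})
        with pytest.raises(ValueError, match="no genes in the universe"), pytest.warns(UserWarning):
            EnrichmentQuery.from_genes("q", {"Z"}, universe)


class TestEnrichmentMatrix:
    def _planted(self):
        universe = gene_symbols(500)
        term = set(universe[:40])
        res = _resource("r", {"hit": term, **{f"bg{i}": set(universe[50 + 10 * i : 60 + 10 * i]) for i in range(6)}})
        query_genes = frozenset(universe[:30])  # 30/30 inside 'hit'
        return res, frozenset(universe), query_genes

    def test_capping_contract(self):
        assert neg_log10_capped(1e-12, cap=10.0) == 10.0
        assert neg_log10_capped(1.0, cap=10.0) == 0.0
        assert neg_log10_capped(0.0, cap=10.0) == 10.0
        assert neg_log10_capped(1e-3, cap=10.0) == pytest.approx(3.0)

    def test_identical_queries_give_identical_columns(self):
        res, universe, qg = self._planted()
        q1 = EnrichmentQuery("a", qg, universe)
        q2 = EnrichmentQuery("b", qg, universe)
        m = enrichment_matrix([q1, q2], [res], min_term_size=1)
        np.testing.assert_array_equal(m.values["a"].to_numpy(), m.values["b"].to_numpy())

    def test_rows_filtered_and_ordered_by_best_q(self):
        res, universe, qg = self._planted()
        q = EnrichmentQuery("q", qg, universe)
        m = enrichment_matrix([q], [res], min_term_size=1, q_threshold=0.05)
        assert list(m.values.index)[0] == "hit"
        assert (m.q_values.min(axis=1) <= 0.05).all()
        qs = m.q_values.min(axis=1).to_numpy()
        assert np.all(np.diff(qs) >= 0)

    def test_no_significant_terms_yields_empty_matrix_warning(self):
        universe = frozenset(gene_symbols(1000))
        res = _resource("r", {"t": set(sorted(universe)[:10])})
        q = EnrichmentQuery("q", frozenset(sorted(universe)[-10:]), universe)
        with pytest.warns(UserWarning, match="matrix is empty"):
            m = enrichment_matrix([q], [res], min_term_size=1)
        assert m.empty

    def test_global_pooling_widens_correction(self):
        res, universe, qg = self._planted()
        q1 = EnrichmentQuery("a", qg, universe)
        q2 = EnrichmentQuery("b", frozenset(sorted(universe)[-30:]), universe)
        per = enrichment_matrix([q1, q2], [res], min_term_size=1, pool="per_query")
        glob = enrichment_matrix([q1, q2], [res], min_term_size=1, pool="global")
        # the global pool has 2x the tests; q can only stay or rise for the hit
        assert glob.q_values.loc["hit", "a"] >= per.q_values.loc["hit", "a"] - 1e-15

    def test_results_table_schema(self):
        res, universe, qg = self._planted()
        q = EnrichmentQuery("q", qg, universe)
        results, _ = term_enrichment(q, [res], min_term_size=1)
        df = results_table(results)
        assert list(df.columns) == [
            "term", "resource", "query", "n_overlap", "n_term", "n_query",
            "n_universe", "overlap_genes", "p", "q", "neg_log10_q_capped",
        ]
        hit = df[df.term == "hit"].iloc[0]
        assert hit.n_overlap == 30 and hit.overlap_genes.count(",") == 29


class TestResolveUniverse:
    def test_resource_union(self):
        r1 = _resource("a", {"t": {"A", "B"}})
        r2 = _resource("b", {"t": {"B", "C"}})
        assert resolve_universe("resource_union", [r1, r2]) == frozenset({"A", "B", "C"})

    def test_user_list_and_query_union(self):
        assert resolve_universe("user_list", user_genes={"A", "B"}) == frozenset({"A", "B"})
        assert resolve_universe("query_union", query_gene_lists=[{"A"}, {"B"}]) == frozenset({"A", "B"})

    def test_empty_or_invalid(self):
        with pytest.raises(ValueError):
            resolve_universe("user_list")
        with pytest.raises(ValueError, match="empty"):
            resolve_universe("resource_union", [])
        with pytest.raises(ValueError, match="unknown"):
            resolve_universe("everything")
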