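"""Hypergeometric ORA: exact tail, BH adjustment, ranking conventions."""

import math
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonet.enrichment import (
    GeneSetCollection,
    bh_adjust,
    enrich,
    hypergeom_pvalue,
    top_terms,
)
from phytonet.errors import InputError


def tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """Independent oracle: enumerate every n-subset of an N-universe."""
    hits_dist = {}
    for draw in combinations(range(N), n):
        h = sum(1 for x in draw if x < K)
        hits_dist[h] = hits_dist.get(h, 0) + 1
    total = math.comb(N, n)
    return sum(c for h, c in hits_dist.items() if h >= k) / total


@pytest.mark.parametrize(
    "k, K, n, N, expected",
    [
        (0, 5, 5, 10, 1.0),                       # P(X >= 0) is always 1
        (5, 5, 5, 10, 1 / 252),                   # C(5,5)*C(5,0)/C(10,5)
        (2, 3, 3, 6, 0.5),                        # 10 of the 20 draws have >= 2 hits
        (5, 20, 5, 1000, math.comb(20, 5) / math.comb(1000, 5)),
    ],
)
def test_hypergeom_known_values(k, K, n, N, expected):
    assert hypergeom_pvalue(k, K, n, N) == pytest.approx(expected, rel=1e-10)


def test_hypergeom_rejects_impossible_counts():
    for bad in [(6, 5, 5, 10), (1, 5, 5, 4), (-1, 5, 5, 10), (3, 2, 5, 10)]:
        with pytest.raises(InputError):
            hypergeom_pvalue(*bad)


def test_hypergeom_matches_enumeration_small_universes():
    """Spot-check the exact tail against full enumeration (N <= 9 here;
    the exhaustive N <= 12 sweep lives in the acceptance suite)."""
    for N in (5, 7, 9):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                        tail_by_enumeration(k, K, n, N), abs=1e-12
                    )


@settings(deadline=None, max_examples=100)
@given(st.data())
def test_tail_nonincreasing_in_k(data):
    N = data.draw(st.integers(2, 60))
    K = data.draw(st.integers(1, N))
    n = data.draw(st.integers(1, N))
    ps = [hypergeom_pvalue(k, K, n, N) for k in range(min(K, n) + 1)]
    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_step_up_example(self):
        # q = min over j>=rank of p_(j)*m/j: all collapse to 0.04 here
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(InputError):
                bh_adjust(bad)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_q_monotone_in_p_order(self, ps):
        qs = bh_adjust(ps)
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        sorted_q = [qs[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(sorted_q, sorted_q[1:]))
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
        assert all(q <= 1.0 + 1e-12 for q in qs)


def _collection(sets, universe=None, name="test"):
    return GeneSetCollection.from_sets(name, sets, universe=universe)


class TestEnrich:
    def test_full_single_set_is_not_significant(self):
        genes = [f"G{i}" for i in range(10)]
        coll = _collection({"s1": ("only set", genes)})
        results, _ = enrich(genes, coll)
        assert results[0].p_value == pytest.approx(1.0)

    def test_disjoint_set_gives_p_one(self):
        coll = _collection(
            {"s1": ("a", ["G1", "G2"]), "s2": ("b", ["G3", "G4"])},
        )
        results, _ = enrich(["G3", "G4"], coll)
        by_id = {r.term_id: r for r in results}
        assert by_id["s1"].k == 0 and by_id["s1"].p_value == 1.0

    def test_unmapped_query_genes_reported(self):
        coll = _collection({"s1": ("a", ["G1", "G2", "G3"])})
        results, report = enrich(["G1", "G2", "GX"], coll)
        assert report.n_mapped == 2 and report.n_unmapped == 1
        assert report.unmapped == ["GX"]
        assert results[0].n == 2

    def test_counts_are_consistent(self):
        universe = [f"G{i}" for i in range(50)]
        coll = _collection(
            {"s1": ("a", universe[:20]), "s2": ("b", universe[15:40])},
            universe=universe,
        )
        results, _ = enrich(universe[:10], coll)
        for r in results:
            assert r.k <= min(r.K, r.n)
            assert r.q_value >= r.p_value - 1e-12

    def test_nothing_mapped_is_an_error(self):
        coll = _collection({"s1": ("a", ["G1"])})
        with pytest.raises(InputError):
            enrich(["ZZ9"], coll)

    def test_min_set_size_excludes_small_sets(self):
        coll = _collection({"s1": ("a", ["G1"]), "s2": ("b", ["G1", "G2", "G3"])})
        results, _ = enrich(["G1"], coll, min_set_size=2)
        assert [r.term_id for r in results] == ["s2"]


class TestTopTerms:
    def _results(self, pvalues):
        genes = [f"G{i}" for i in range(100)]
        coll = _collection(
            {f"s{i:03d}": (f"term {i}", genes) for i in range(len(pvalues))},
        )
        results, _ = enrich(genes[:5], coll)
        for r, p in zip(results, pvalues):
            r.p_value = p
        return results

    def test_alpha_filter_dominates_k(self):
        results = self._results([0.01, 0.02, 0.04] + [0.5] * 17)
        assert len(top_terms(results, alpha=0.05, k=15)) == 3

    def test_truncates_to_k(self):
        results = self._results([0.001 * (i + 1) for i in range(30)])
        top = top_terms(results, alpha=0.05, k=15)
        assert len(top) == 15

    def test_strict_inequality_at_alpha(self):
        results = self._results([0.05, 0.049])
        kept = top_terms(results, alpha=0.05)
        assert [r.p_value for r in kept] == [0.049]

    def test_ties_break_by_term_id(self):
        results = self._results([0.01, 0.01, 0.01])
        ids = [r.term_id for r in top_terms(results)]
        assert ids == sorted(ids)
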