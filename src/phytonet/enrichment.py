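"""Over-representation analysis (ORA) of a gene list against GMT collections.

For a query of ``n`` genes drawn from a universe of ``N``, and an annotated
set containing ``K`` universe genes of which ``k`` are in the query, the
enrichment p-value is the exact one-sided hypergeometric tail

    P(X >= k),   X ~ Hypergeometric(N, K, n)

computed exactly (no normal approximation). Benjamini–Hochberg q-values are
reported per collection; the default reporting convention keeps terms with
raw ``p < alpha`` (strict) and truncates to the top ``k`` by ascending p,
ties broken by term id.

Query genes outside the collection universe are dropped before testing and
reported, so the effective query size ``n`` is always consistent with ``N``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .catalog import normalize_symbol
from .errors import InputError

DEFAULT_ALPHA = 0.05
DEFAULT_TOP_K = 15

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "EnrichReport",
    "hypergeom_pvalue",
    "bh_adjust",
    "enrich",
    "top_terms",
    "DEFAULT_ALPHA",
    "DEFAULT_TOP_K",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a common universe.

    ``sets`` maps term_id -> (term_name, member symbols). The universe
    defaults to the union of all sets, matching the convention of testing
    against the annotated background; a wider genome background can be
    supplied explicitly.
    """

    name: str
    sets: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        name: str,
        sets: Mapping[str, tuple[str, Iterable[str]]],
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        norm_sets: dict[str, tuple[str, frozenset[str]]] = {}
        for term_id, (term_name, members) in sets.items():
            syms = frozenset(normalize_symbol(s) for s in members)
            if not syms:
                raise InputError(f"gene set {term_id!r} is empty")
            norm_sets[term_id] = (term_name, syms)
        if universe is None:
            uni: frozenset[str] = frozenset().union(
                *(s for _, s in norm_sets.values())
            ) if norm_sets else frozenset()
        else:
            uni = frozenset(normalize_symbol(s) for s in universe)
            for term_id, (_, syms) in norm_sets.items():
                if not syms <= uni:
                    raise InputError(
                        f"gene set {term_id!r} contains symbols outside the universe"
                    )
        return cls(name=name, sets=dict(norm_sets), universe=uni)


@dataclass
class EnrichmentResult:
    """One gene-set test: overlap counts, hypergeometric p, BH q."""

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float = float("nan")


@dataclass
class EnrichReport:
    """Query-mapping bookkeeping for one collection."""

    collection: str
    n_query: int
    n_mapped: int
    n_unmapped: int
    unmapped: list[str] = field(default_factory=list)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` set size, ``n`` query size, ``k`` observed
    overlap. ``k = 0`` gives exactly 1.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)):
            raise InputError(f"hypergeom_pvalue: {name} must be an integer, got {v!r}")
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N) or not (0 <= k <= min(K, n)):
        raise InputError(
            f"hypergeom_pvalue: impossible counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted p-values, clipped
    to 1 and mapped back to the original positions.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("bh_adjust: p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    min_set_size: int = 2,
) -> tuple[list[EnrichmentResult], EnrichReport]:
    """Test every set in a collection for over-representation of ``query``.

    Returns one result per set with ``K >= min_set_size``, ranked by
    (p, term_id), plus a report of how many query genes mapped into the
    collection universe. Raises if no query gene maps at all.
    """
    raw_query = {normalize_symbol(s) for s in query}
    if not raw_query:
        raise InputError("enrich: empty query gene set")
    mapped = raw_query & collection.universe
    unmapped = sorted(raw_query - collection.universe)
    if not mapped:
        raise InputError(
            f"enrich: no query gene maps into the {collection.name!r} universe"
        )
    n = len(mapped)
    N = len(collection.universe)
    results: list[EnrichmentResult] = []
    for term_id in sorted(collection.sets):
        term_name, members = collection.sets[term_id]
        K = len(members)
        if K < min_set_size:
            continue
        k = len(mapped & members)
        p = hypergeom_pvalue(k, K, n, N)
        results.append(
            EnrichmentResult(
                term_id=term_id, term_name=term_name, k=k, K=K, n=n, N=N, p_value=p
            )
        )
    if results:
        qvals = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    report = EnrichReport(
        collection=collection.name,
        n_query=len(raw_query),
        n_mapped=n,
        n_unmapped=len(unmapped),
        unmapped=unmapped,
    )
    return results, report


def top_terms(
    results: Sequence[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_TOP_K,
    by: str = "p",
) -> list[EnrichmentResult]:
    """Keep terms with p (or q) strictly below ``alpha``; return the top ``k``.

    Sorted ascending by the chosen statistic, ties broken by term id. An
    empty result is allowed (nothing significant) — callers may warn.
    """
    if by == "p":
        key = lambda r: (r.p_value, r.term_id)  # noqa: E731
        sig = [r for r in results if r.p_value < alpha]
    elif by == "q":
        key = lambda r: (r.q_value, r.term_id)  # noqa: E731
        sig = [r for r in results if r.q_value < alpha]
    else:
        raise InputError(f"top_terms: unknown ranking statistic {by!r}")
    return sorted(sig, key=key)[:k]
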