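"""Disease-gene catalogs: normalization, merging and intersection.

Gene lists from different disease databases arrive with inconsistent casing,
stray whitespace and internal duplicates. Symbols are canonicalized by
trimming and uppercasing only — no alias or nomenclature resolution is
attempted, which keeps the operation dependency-free and auditable (alias
mapping is a documented extension point). A catalog keeps both its raw line
count and its deduplicated symbol set, so that merge reports can state how
many duplicates were deleted.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from itertools import combinations

from .errors import InputError

__all__ = ["GeneCatalog", "MergeReport", "normalize_symbol", "merge_catalogs", "intersect_targets"]


def normalize_symbol(raw: str) -> str:
    """Canonicalize a gene symbol: trim surrounding whitespace, uppercase.

    Internal whitespace is rejected — a symbol containing spaces is almost
    always a parsing accident upstream, not a real identifier.
    """
    if not isinstance(raw, str):
        raise InputError(f"gene symbol must be a string, got {type(raw).__name__}")
    sym = raw.strip()
    if not sym:
        raise InputError("empty or whitespace-only gene symbol")
    if any(ch.isspace() for ch in sym):
        raise InputError(f"gene symbol {raw!r} contains internal whitespace")
    return sym.upper()


@dataclass(frozen=True)
class GeneCatalog:
    """A labeled, deduplicated set of normalized gene symbols.

    ``raw_count`` is the number of entries before deduplication; database
    exports routinely repeat symbols, so ``raw_count >= len(symbols)``.
    """

    source: str
    symbols: frozenset[str]
    raw_count: int

    @classmethod
    def from_symbols(cls, raw_symbols: Iterable[str], source: str) -> "GeneCatalog":
        normalized = [normalize_symbol(s) for s in raw_symbols]
        return cls(source=source, symbols=frozenset(normalized), raw_count=len(normalized))

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class MergeReport:
    """Per-source counts and overlaps of one catalog merge."""

    per_source: dict[str, int] = field(default_factory=dict)
    per_source_raw: dict[str, int] = field(default_factory=dict)
    union_count: int = 0
    total_raw: int = 0
    duplicates_removed: int = 0
    pairwise_overlap: dict[str, int] = field(default_factory=dict)


def merge_catalogs(catalogs: Sequence[GeneCatalog]) -> tuple[GeneCatalog, MergeReport]:
    """Union a list of catalogs into one deduplicated catalog.

    Returns the merged catalog (source label ``"merged"``) and a report with
    per-source unique and raw counts, the pairwise overlap between every
    source pair, and the number of duplicate entries removed relative to the
    summed raw counts.
    """
    if not catalogs:
        raise InputError("merge_catalogs requires at least one catalog")
    union: set[str] = set()
    report = MergeReport()
    for cat in catalogs:
        union |= cat.symbols
        report.per_source[cat.source] = len(cat.symbols)
        report.per_source_raw[cat.source] = cat.raw_count
        report.total_raw += cat.raw_count
    for a, b in combinations(catalogs, 2):
        report.pairwise_overlap[f"{a.source}|{b.source}"] = len(a.symbols & b.symbols)
    report.union_count = len(union)
    report.duplicates_removed = report.total_raw - report.union_count
    merged = GeneCatalog(source="merged", symbols=frozenset(union), raw_count=report.total_raw)
    return merged, report


def intersect_targets(compound_targets: Iterable[str], disease: GeneCatalog) -> list[str]:
    """Intersect compound-target symbols with a disease catalog.

    Both operands are normalized before intersecting; the result is sorted
    for deterministic downstream ordering. Empty operands signal an upstream
    failure and raise; a genuinely disjoint pair returns an empty list with a
    warning.
    """
    targets = {normalize_symbol(s) for s in compound_targets}
    if not targets:
        raise InputError("intersect_targets: empty compound-target set")
    if not disease.symbols:
        raise InputError("intersect_targets: empty disease catalog")
    common = sorted(targets & disease.symbols)
    if not common:
        warnings.warn(
            "compound targets and disease catalog are disjoint", stacklevel=2
        )
    return common
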