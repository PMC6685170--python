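"""Target fishing: filtering scored compound→target predictions.

Each predicted interaction carries two confidence scores from independent
classifiers — a random-forest (RF) score and a support-vector-machine (SVM)
score, both in [0, 1]. An interaction is retained only when both models agree
it is plausible: ``rf >= rf_min`` and ``svm >= svm_min`` (defaults 0.7 and
0.8, both inclusive). Duplicate (compound, target) pairs collapse to the
maximum score per channel before filtering, which makes filtering and
deduplication commute.

Compounds left with no retained interaction are "orphans" and are excluded
from all downstream networks.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace

from .adme import CompoundRecord
from .catalog import normalize_symbol
from .errors import InputError

DEFAULT_RF_MIN = 0.7
DEFAULT_SVM_MIN = 0.8

__all__ = [
    "InteractionRecord",
    "dedup_interactions",
    "filter_interactions",
    "partition_orphans",
    "DEFAULT_RF_MIN",
    "DEFAULT_SVM_MIN",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One scored compound→target prediction."""

    compound_id: str
    target_symbol: str
    rf_score: float
    svm_score: float


def _validate(records: Sequence[InteractionRecord]) -> None:
    for i, rec in enumerate(records):
        for channel, score in (("rf", rec.rf_score), ("svm", rec.svm_score)):
            if not (0.0 <= score <= 1.0):
                raise InputError(
                    f"row {i}: {channel} score {score} outside [0, 1] "
                    f"({rec.compound_id} -> {rec.target_symbol})"
                )


def dedup_interactions(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Collapse duplicate (compound, target) pairs, keeping the max score per channel.

    Target symbols are normalized first, so case variants of one symbol
    collapse together. Output order follows first appearance of each pair.
    """
    merged: dict[tuple[str, str], InteractionRecord] = {}
    for rec in records:
        key = (rec.compound_id, normalize_symbol(rec.target_symbol))
        prev = merged.get(key)
        if prev is None:
            merged[key] = replace(rec, target_symbol=key[1])
        else:
            merged[key] = replace(
                prev,
                rf_score=max(prev.rf_score, rec.rf_score),
                svm_score=max(prev.svm_score, rec.svm_score),
            )
    return list(merged.values())


def filter_interactions(
    records: Sequence[InteractionRecord],
    rf_min: float = DEFAULT_RF_MIN,
    svm_min: float = DEFAULT_SVM_MIN,
) -> list[InteractionRecord]:
    """Keep interactions with ``rf >= rf_min`` and ``svm >= svm_min``.

    Scores are validated to lie in [0, 1] (error messages carry the row
    number); duplicates are collapsed to max scores before applying the
    cutoffs.
    """
    _validate(records)
    return [
        rec
        for rec in dedup_interactions(records)
        if rec.rf_score >= rf_min and rec.svm_score >= svm_min
    ]


def partition_orphans(
    compounds: Sequence[CompoundRecord | str],
    edges: Sequence[InteractionRecord],
) -> tuple[list, list]:
    """Split screened compounds into (connected, orphans) by retained edges.

    ``compounds`` may be records or bare ids. Every edge must reference a
    known compound id; the two output lists preserve input order and
    partition the input exactly.
    """
    ids = [c.compound_id if isinstance(c, CompoundRecord) else c for c in compounds]
    known = set(ids)
    with_edges: set[str] = set()
    for rec in edges:
        if rec.compound_id not in known:
            raise InputError(
                f"interaction references unknown compound_id {rec.compound_id!r}"
            )
        with_edges.add(rec.compound_id)
    connected = [c for c, i in zip(compounds, ids) if i in with_edges]
    orphans = [c for c, i in zip(compounds, ids) if i not in with_edges]
    return connected, orphans
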