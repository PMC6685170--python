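"""ADME screening of herbal-compound tables.

Compounds enter the pipeline as records carrying two precomputed
pharmacokinetic scores: oral bioavailability (OB, a percentage) and
drug-likeness (DL, a Tanimoto similarity in [0, 1] between the compound's
molecular-property vector and the average property vector of an approved-drug
library). The screen keeps compounds with ``OB >= ob_min`` and
``DL >= dl_min`` (both thresholds inclusive); a whitelist can force named
compounds through regardless of their scores, mirroring the common practice
of retaining pharmacologically well-attested ingredients that narrowly fail
the in-silico filter.

When DL is not supplied it can be computed from a descriptor vector via
:func:`drug_likeness`, given a reference profile (the mean descriptor vector
of the drug library).
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

DEFAULT_OB_MIN = 30.0
DEFAULT_DL_MIN = 0.18

__all__ = [
    "CompoundRecord",
    "ReferenceProfile",
    "ScreeningReport",
    "tanimoto_similarity",
    "drug_likeness",
    "screen_compounds",
    "DEFAULT_OB_MIN",
    "DEFAULT_DL_MIN",
]


@dataclass
class CompoundRecord:
    """One herb ingredient with its pharmacokinetic scores.

    Parameters
    ----------
    compound_id : str
        Opaque unique key within a table.
    name : str
        Free-text compound name.
    ob : float or None
        Oral bioavailability in percent (0-100); None when unknown.
    dl : float or None
        Drug-likeness score in [0, 1]; None when unknown.
    descriptors : ndarray or None
        Optional molecular-property vector; all records of one table must
        share a single dimension.
    whitelisted : bool
        Force this compound through the screen regardless of scores.
    """

    compound_id: str
    name: str = ""
    ob: float | None = None
    dl: float | None = None
    descriptors: np.ndarray | None = None
    whitelisted: bool = False

    def __post_init__(self) -> None:
        if self.descriptors is not None:
            self.descriptors = np.asarray(self.descriptors, dtype=float)
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise InputError(
                f"compound {self.compound_id!r}: DL score {self.dl} outside [0, 1]"
            )


@dataclass
class ReferenceProfile:
    """Mean molecular-property vector of a reference drug library."""

    mean_descriptors: np.ndarray
    library_name: str = "reference"

    def __post_init__(self) -> None:
        self.mean_descriptors = np.asarray(self.mean_descriptors, dtype=float)
        if self.mean_descriptors.ndim != 1 or self.mean_descriptors.size == 0:
            raise InputError("reference profile must be a non-empty 1-d vector")


def tanimoto_similarity(a, b) -> float:
    """Tanimoto coefficient ``(a.b) / (|a|^2 + |b|^2 - a.b)``.

    Defined for real-valued non-negative vectors of equal dimension; on binary
    vectors it reduces to the Jaccard index of the two support sets. Returns a
    value in [0, 1], equal to 1 exactly when ``a == b`` (non-zero).

    Raises
    ------
    InputError
        On dimension mismatch, negative components, or when both vectors are
        all-zero (the coefficient is undefined there; we refuse rather than
        silently return 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise InputError("tanimoto_similarity expects 1-d vectors")
    if a.shape != b.shape:
        raise InputError(
            f"dimension mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    if (a < 0).any() or (b < 0).any():
        raise InputError("tanimoto_similarity requires non-negative components")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        raise InputError("tanimoto similarity undefined: both vectors are all-zero")
    return dot / denom


def drug_likeness(
    compound: CompoundRecord, ref: ReferenceProfile, *, overwrite: bool = False
) -> float:
    """Compute DL as the Tanimoto similarity to a reference drug profile.

    Stores the result on ``compound.dl`` unless a value is already present
    and ``overwrite`` is False (the computed score is still returned).
    """
    if compound.descriptors is None:
        raise InputError(
            f"compound {compound.compound_id!r} has no descriptor vector; "
            "cannot compute drug-likeness"
        )
    if compound.descriptors.shape != ref.mean_descriptors.shape:
        raise InputError(
            f"compound {compound.compound_id!r}: descriptor dimension "
            f"{compound.descriptors.shape[0]} does not match reference "
            f"dimension {ref.mean_descriptors.shape[0]}"
        )
    score = tanimoto_similarity(compound.descriptors, ref.mean_descriptors)
    if compound.dl is None or overwrite:
        compound.dl = score
    return score


@dataclass
class ScreeningReport:
    """Audit trail of one screening run; count fields always sum to n_input."""

    n_input: int
    n_pass_threshold: int
    n_whitelisted_in: int
    n_excluded: int
    ob_min: float
    dl_min: float
    reasons: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_pass_threshold": self.n_pass_threshold,
                "n_whitelisted_in": self.n_whitelisted_in,
                "n_excluded": self.n_excluded,
                "ob_min": self.ob_min,
                "dl_min": self.dl_min,
                "reasons": self.reasons,
            },
            indent=2,
            sort_keys=True,
        )

    def to_text(self) -> str:
        lines = [
            f"compounds screened : {self.n_input}",
            f"passed OB>={self.ob_min:g} and DL>={self.dl_min:g} : {self.n_pass_threshold}",
            f"whitelisted in     : {self.n_whitelisted_in}",
            f"excluded           : {self.n_excluded}",
        ]
        return "\n".join(lines)


def screen_compounds(
    table: Sequence[CompoundRecord],
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
    whitelist: Iterable[str] = (),
) -> tuple[list[CompoundRecord], ScreeningReport]:
    """Filter a compound table by OB and DL thresholds (inclusive).

    A compound passes when ``ob >= ob_min`` and ``dl >= dl_min``. Compounds
    whose id is in ``whitelist`` (or flagged ``whitelisted``) are retained
    unconditionally and may have missing scores. Returns the passing records
    in input order together with a :class:`ScreeningReport` whose per-compound
    ``reasons`` explain every decision.
    """
    whitelist = set(whitelist)
    seen: set[str] = set()
    for rec in table:
        if rec.compound_id in seen:
            raise InputError(f"duplicate compound_id {rec.compound_id!r} in table")
        seen.add(rec.compound_id)

    passing: list[CompoundRecord] = []
    reasons: dict[str, str] = {}
    n_pass = n_white = n_excl = 0
    for rec in table:
        wl = rec.whitelisted or rec.compound_id in whitelist
        if rec.ob is None or rec.dl is None:
            if not wl:
                missing = "OB" if rec.ob is None else "DL"
                raise InputError(
                    f"compound {rec.compound_id!r} has missing {missing} and is "
                    "not whitelisted"
                )
            by_threshold = False
        else:
            by_threshold = rec.ob >= ob_min and rec.dl >= dl_min
        if by_threshold:
            n_pass += 1
            reasons[rec.compound_id] = "pass"
            passing.append(rec)
        elif wl:
            n_white += 1
            reasons[rec.compound_id] = "whitelist"
            passing.append(rec)
        else:
            n_excl += 1
            fails = []
            if rec.ob < ob_min:
                fails.append(f"OB {rec.ob:g} < {ob_min:g}")
            if rec.dl < dl_min:
                fails.append(f"DL {rec.dl:g} < {dl_min:g}")
            reasons[rec.compound_id] = "; ".join(fails)
    report = ScreeningReport(
        n_input=len(table),
        n_pass_threshold=n_pass,
        n_whitelisted_in=n_white,
        n_excluded=n_excl,
        ob_min=ob_min,
        dl_min=dl_min,
        reasons=reasons,
    )
    return passing, report
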