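"""Readers and writers for the pipeline's plain-text formats.

Tables are CSV or TSV (delimiter chosen by extension: ``.csv`` → comma,
anything else → tab), UTF-8, decimal point. Gene lists are one symbol per
line or a TSV with a ``symbol`` column; gene-set collections use the
standard GMT layout (term_id <TAB> term_name <TAB> gene1 <TAB> gene2 ...).
All writers emit sorted, newline-normalized output so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .adme import CompoundRecord
from .catalog import GeneCatalog, normalize_symbol
from .enrichment import EnrichmentResult, GeneSetCollection
from .errors import InputError
from .fishing import InteractionRecord

__all__ = [
    "read_compound_table",
    "write_compound_table",
    "read_interaction_table",
    "write_interaction_table",
    "read_gene_list",
    "write_gene_list",
    "read_ppi_table",
    "write_ppi_table",
    "read_gmt",
    "write_gmt",
    "write_enrichment_table",
    "sha256_file",
]

_TRUE_STRINGS = {"1", "true", "yes", "y"}


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _opt_float(value, path, row, col) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}, row {row}: bad {col} value {value!r}") from exc


def read_compound_table(path) -> list[CompoundRecord]:
    """Read a compound table: columns compound_id, name, ob, dl [, whitelisted, d1..dk]."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"compound_id", "ob", "dl"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    desc_cols = sorted(
        (c for c in df.columns if c.startswith("d") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        descriptors = None
        if desc_cols:
            descriptors = np.array([float(row[c]) for c in desc_cols])
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]).strip(),
                name=str(row.get("name", "") or ""),
                ob=_opt_float(row["ob"], path, i, "ob"),
                dl=_opt_float(row["dl"], path, i, "dl"),
                descriptors=descriptors,
                whitelisted=str(row.get("whitelisted", "") or "").strip().lower()
                in _TRUE_STRINGS,
            )
        )
    return records


def write_compound_table(records: Sequence[CompoundRecord], path) -> None:
    dim = 0
    for rec in records:
        if rec.descriptors is not None:
            dim = len(rec.descriptors)
            break
    cols = ["compound_id", "name", "ob", "dl", "whitelisted"] + [
        f"d{i + 1}" for i in range(dim)
    ]
    rows = []
    for rec in records:
        row = {
            "compound_id": rec.compound_id,
            "name": rec.name,
            "ob": "" if rec.ob is None else f"{rec.ob:.6g}",
            "dl": "" if rec.dl is None else f"{rec.dl:.6g}",
            "whitelisted": "true" if rec.whitelisted else "false",
        }
        if dim:
            for i, v in enumerate(rec.descriptors):
                row[f"d{i + 1}"] = f"{v:.6g}"
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep=_sep(path), index=False, lineterminator="\n"
    )


def read_interaction_table(path) -> list[InteractionRecord]:
    """Read compound→target predictions: compound_id, target_symbol, rf_score, svm_score."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"compound_id", "target_symbol", "rf_score", "svm_score"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rf = _opt_float(row.rf_score, path, i, "rf_score")
        svm = _opt_float(row.svm_score, path, i, "svm_score")
        if rf is None or svm is None:
            raise InputError(f"{path}, row {i}: missing RF/SVM score")
        records.append(
            InteractionRecord(
                compound_id=str(row.compound_id).strip(),
                target_symbol=str(row.target_symbol).strip(),
                rf_score=rf,
                svm_score=svm,
            )
        )
    return records


def write_interaction_table(records: Sequence[InteractionRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "target_symbol": r.target_symbol,
                "rf_score": f"{r.rf_score:.6g}",
                "svm_score": f"{r.svm_score:.6g}",
            }
            for r in records
        ],
        columns=["compound_id", "target_symbol", "rf_score", "svm_score"],
    ).to_csv(path, sep=_sep(path), index=False, lineterminator="\n")


def read_gene_list(path, source: str) -> GeneCatalog:
    """Read a disease-gene list (one symbol per line, or TSV with a symbol column).

    Blank lines and ``#`` comments are skipped; the catalog records the raw
    entry count before deduplication.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise InputError(f"{path}: no gene symbols found")
    header = lines[0].split("\t")
    if "symbol" in [h.strip().lower() for h in header]:
        col = [h.strip().lower() for h in header].index("symbol")
        raw = [ln.split("\t")[col] for ln in lines[1:]]
    else:
        raw = [ln.split("\t")[0] for ln in lines]
    return GeneCatalog.from_symbols(raw, source=source)


def write_gene_list(symbols: Iterable[str], path, source: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if source is not None:
            fh.write(f"# source: {source}\n")
        for sym in sorted(set(symbols)):
            fh.write(sym + "\n")


def read_ppi_table(path) -> list[tuple[str, str, float]]:
    """Read a STRING-style PPI export: node_a, node_b, combined_score.

    A header line is detected by a non-numeric third field and skipped.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("," if str(path).lower().endswith(".csv") else "\t")
            if len(parts) < 3:
                raise InputError(f"{path}, line {i}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError:
                if i == 1:  # header
                    continue
                raise InputError(f"{path}, line {i}: malformed score {parts[2]!r}")
            rows.append((parts[0].strip(), parts[1].strip(), score))
    if not rows:
        raise InputError(f"{path}: no PPI edges found")
    return rows


def write_ppi_table(rows: Iterable[tuple[str, str, float]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_a\tnode_b\tcombined_score\n")
        for a, b, score in rows:
            fh.write(f"{a}\t{b}\t{score:.6g}\n")


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file: term_id <TAB> term_name <TAB> genes..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(
                    f"{path}, line {i}: GMT line needs id, name and >=1 gene"
                )
            term_id, term_name, genes = parts[0], parts[1], parts[2:]
            if term_id in sets:
                raise InputError(f"{path}, line {i}: duplicate term id {term_id!r}")
            sets[term_id] = (term_name, [g for g in genes if g.strip()])
    if not sets:
        raise InputError(f"{path}: empty GMT file")
    return GeneSetCollection.from_sets(name or Path(path).stem, sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term_id in sorted(collection.sets):
            term_name, members = collection.sets[term_id]
            fh.write("\t".join([term_id, term_name, *sorted(members)]) + "\n")


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": f"{r.p_value:.6g}",
                "q_value": f"{r.q_value:.6g}",
            }
            for r in results
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "q_value"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
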