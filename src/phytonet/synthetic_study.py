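"""Synthetic study-shaped fixture tables.

The original screen's supplementary tables (compound list, compound–target
pairs, disease catalogs, PPI export, annotation sets) are not redistributable,
so this module constructs a fully synthetic stand-in whose *summary
statistics* match the published run of the pipeline exactly:

* 202 raw compounds → 65 pass the ADME thresholds, 2 whitelisted salvage
  compounds → 67 candidates, of which 5 are orphans → 62 connected;
* a bipartite network of 163 nodes (62 compounds + 101 targets) and 1322
  edges, with the two flagship compounds at degrees 40 and 35, the three
  most-promiscuous targets at degrees 58, 55 and 50, and exactly 19
  compounds above degree 30 (class mean 1322/62 = 21.32);
* two disease catalogs of 5730 (with internal duplicate lines) and 153 raw
  entries whose deduplicated union holds 5617 symbols, 72 of them compound
  targets;
* a PPI table that, filtered at confidence > 0.4 against the 72 common
  targets, yields 70 nodes and 571 edges with ten hub nodes at degrees
  44, 43, 40, 39, 39, 38, 38, 37, 35, 34 (one common target has only
  sub-threshold interactions, one never appears);
* gene-set collections in which 68 of the 72 common targets map into the
  pathway universe and the three top pathways hit 22, 17 and 12 targets.

Every identifier is synthetic (C####, T###, D#####...); no real compound or
gene names are used. Degree sequences are realized with Havel–Hakimi
constructions, so the tables are deterministic given the seed (the seed only
jitters scores, never counts).
"""

from __future__ import annotations

import zlib
from pathlib import Path

import networkx as nx
import numpy as np
from networkx.algorithms import bipartite as nx_bipartite

from .adme import CompoundRecord
from .catalog import GeneCatalog
from .enrichment import GeneSetCollection
from .fishing import InteractionRecord
from . import io as pio

__all__ = ["build_study_fixture", "write_study_dataset"]

# bipartite degree sequences (both sum to 1322)
_COMPOUND_DEGREES = [40, 35] + [31] * 17 + [17] * 32 + [16] * 11
_TARGET_DEGREES = [58, 55, 50] + [12] * 81 + [11] * 17
# PPI degree sequence (70 nodes, sum 1142 = 2*571); first ten are the hubs
_HUB_DEGREES = [44, 43, 40, 39, 39, 38, 38, 37, 35, 34]
_PPI_DEGREES = _HUB_DEGREES + [13] * 35 + [12] * 25


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(b"study-fixture")])


def _compounds(rng: np.random.Generator) -> list[CompoundRecord]:
    records = []
    for i in range(1, 66):  # 65 threshold passers
        records.append(
            CompoundRecord(
                f"C{i:04d}",
                name=f"ingredient-{i:04d}",
                ob=round(30.0 + 70.0 * float(rng.random()), 2),
                dl=round(0.18 + 0.82 * float(rng.random()), 3),
            )
        )
    for i in range(66, 201):  # 135 failures (alternate failure modes)
        if i % 3 == 0:
            ob, dl = 29.9 * float(rng.random()), 0.18 + 0.82 * float(rng.random())
        elif i % 3 == 1:
            ob, dl = 30.0 + 70.0 * float(rng.random()), 0.17 * float(rng.random())
        else:
            ob, dl = 29.9 * float(rng.random()), 0.17 * float(rng.random())
        records.append(
            CompoundRecord(
                f"C{i:04d}", name=f"ingredient-{i:04d}", ob=round(ob, 2), dl=round(dl, 3)
            )
        )
    for i in (201, 202):  # whitelisted salvage: fail OB, well-attested elsewhere
        records.append(
            CompoundRecord(
                f"C{i:04d}",
                name=f"salvage-ingredient-{i:04d}",
                ob=round(5.0 + 20.0 * float(rng.random()), 2),
                dl=round(0.2 + 0.6 * float(rng.random()), 3),
                whitelisted=True,
            )
        )
    return records


def _bipartite_edges() -> list[tuple[str, str]]:
    """Realize the compound/target degree sequences as a simple bipartite graph."""
    aseq, bseq = _COMPOUND_DEGREES, _TARGET_DEGREES
    g = nx_bipartite.havel_hakimi_graph(aseq, bseq)
    # node 0..61 = compound slots, 62..162 = target slots
    connected_ids = [f"C{i:04d}" for i in range(1, 61)] + ["C0201", "C0202"]
    target_ids = [f"T{i:03d}" for i in range(1, 102)]
    # map by degree rank within each side so pinned degrees land on pinned ids
    comp_nodes = sorted(range(len(aseq)), key=lambda v: (-g.degree(v), v))
    comp_slots = sorted(range(len(aseq)), key=lambda v: (-aseq[v], v))
    tgt_nodes = sorted(
        range(len(aseq), len(aseq) + len(bseq)), key=lambda v: (-g.degree(v), v)
    )
    tgt_slots = sorted(range(len(bseq)), key=lambda v: (-bseq[v], v))
    mapping: dict[int, str] = {}
    for node, slot in zip(comp_nodes, comp_slots):
        mapping[node] = connected_ids[slot]
    for node, slot in zip(tgt_nodes, tgt_slots):
        mapping[node] = target_ids[slot]
    # the construction must realize the sequences exactly
    realized_a = sorted((g.degree(v) for v in range(len(aseq))), reverse=True)
    realized_b = sorted(
        (g.degree(v) for v in range(len(aseq), len(aseq) + len(bseq))), reverse=True
    )
    assert realized_a == sorted(aseq, reverse=True)
    assert realized_b == sorted(bseq, reverse=True)
    return sorted((mapping[u], mapping[v]) if mapping[u][0] == "C" else (mapping[v], mapping[u])
                  for u, v in g.edges())


def _interactions(rng: np.random.Generator) -> list[InteractionRecord]:
    rows = []
    for cid, tsym in _bipartite_edges():
        rf = round(0.70 + 0.29 * float(rng.random()), 3)
        svm = round(0.80 + 0.19 * float(rng.random()), 3)
        rows.append(InteractionRecord(cid, tsym, rf, svm))
    # orphan candidates: predictions exist but fail the dual-score rule
    for i, cid in enumerate(f"C{j:04d}" for j in range(61, 66)):
        rows.append(InteractionRecord(cid, f"T{(i % 101) + 1:03d}", 0.5, 0.9))
        rows.append(InteractionRecord(cid, f"T{((i + 7) % 101) + 1:03d}", 0.8, 0.6))
    # duplicated pairs with lower scores, to exercise max-collapse
    for rec in rows[:3]:
        rows.append(
            InteractionRecord(
                rec.compound_id, rec.target_symbol, rec.rf_score - 0.05, rec.svm_score - 0.05
            )
        )
    return rows


def _disease_lists() -> tuple[list[str], list[str]]:
    """Raw entry lists for the two disease sources.

    Source A: 5564 unique symbols (72 common targets + 5492 fillers), padded
    with 166 duplicate lines to a raw count of 5730. Source B: 153 unique
    symbols, 100 shared with source A. Union: 5617.
    """
    common_targets = [f"T{i:03d}" for i in range(1, 73)]
    filler_a = [f"D{i:05d}" for i in range(1, 5493)]
    a_unique = common_targets + filler_a  # 5564
    a_raw = a_unique + filler_a[:166]  # 5730 raw lines
    shared = common_targets[:2] + filler_a[:98]  # 100 shared with A
    b_only = [f"E{i:05d}" for i in range(1, 54)]  # 53 unique to B
    b_raw = shared + b_only  # 153
    return a_raw, b_raw


def _ppi_rows(rng: np.random.Generator) -> list[tuple[str, str, float]]:
    seq = sorted(_PPI_DEGREES, reverse=True)
    g = nx.havel_hakimi_graph(seq)
    assert sorted((d for _, d in g.degree()), reverse=True) == seq
    # hub slots: T004..T012 plus T001 (the most-hit bipartite target)
    hub_ids = ["T004", "T005", "T006", "T007", "T008", "T001", "T009", "T010", "T011", "T012"]
    other_ids = [f"T{i:03d}" for i in range(1, 71) if f"T{i:03d}" not in hub_ids]
    ordered_ids = hub_ids + other_ids  # by desired degree rank
    nodes_by_rank = sorted(g.nodes(), key=lambda v: (-g.degree(v), v))
    mapping = {node: ordered_ids[i] for i, node in enumerate(nodes_by_rank)}
    rows = []
    for u, v in g.edges():
        a, b = sorted((mapping[u], mapping[v]))
        rows.append((a, b, round(0.41 + 0.58 * float(rng.random()), 3)))
    rows.sort()
    # T071: present only below the confidence cutoff; T072 never appears
    rows.append(("T004", "T071", 0.25))
    rows.append(("T050", "T071", 0.3))
    # noise the builder must discard: a self-loop and a duplicate pair
    rows.append(("T004", "T004", 0.99))
    rows.append((rows[0][0], rows[0][1], 0.45))
    return rows


def _pathway_collection() -> GeneSetCollection:
    """99 pathway-like sets; 68 of the 72 common targets are in the universe."""
    mapped = [f"T{i:03d}" for i in range(1, 69)]  # T069..T072 unmapped
    filler = [f"K{i:05d}" for i in range(1, 2000 - len(mapped) + 1)]
    universe = mapped + filler
    sets: dict[str, tuple[str, list[str]]] = {}
    top_hits = [22, 17, 12]
    sizes = [80, 70, 60]
    for i, (h, size) in enumerate(zip(top_hits, sizes), start=1):
        sets[f"P{i:04d}"] = (
            f"pathway-{i:04d}",
            mapped[:h] + filler[i * 100 : i * 100 + size - h],
        )
    for i in range(4, 19):  # 15 more clearly enriched pathways
        sets[f"P{i:04d}"] = (
            f"pathway-{i:04d}",
            mapped[i : i + 8] + filler[i * 50 : i * 50 + 32],
        )
    for i in range(19, 100):  # background pathways, no planted overlap
        start = 200 + i * 17
        sets[f"P{i:04d}"] = (f"pathway-{i:04d}", filler[start : start + 40])
    return GeneSetCollection.from_sets("pathways", sets, universe=universe)


def _go_collection(branch: str, offset: int) -> GeneSetCollection:
    """60 GO-like sets per branch over a universe containing all 72 targets."""
    targets = [f"T{i:03d}" for i in range(1, 73)]
    filler = [f"{branch.upper()}{i:05d}" for i in range(1, 1500 - 72 + 1)]
    universe = targets + filler
    sets: dict[str, tuple[str, list[str]]] = {}
    enriched_hits = [20, 16, 12, 10] + [8] * 12  # 16 enriched terms
    for i, h in enumerate(enriched_hits, start=1):
        sets[f"{branch.upper()}{i:04d}"] = (
            f"{branch} term {i:04d}",
            targets[(i + offset) % 40 : (i + offset) % 40 + h]
            + filler[i * 40 : i * 40 + 40 - h],
        )
    for i in range(len(enriched_hits) + 1, 61):
        start = 700 + i * 11
        sets[f"{branch.upper()}{i:04d}"] = (
            f"{branch} term {i:04d}",
            filler[start : start + 35],
        )
    return GeneSetCollection.from_sets(branch, sets, universe=universe)


def build_study_fixture(seed: int = 0) -> dict:
    """Construct all synthetic study-shaped inputs in memory.

    Returns a dict with keys ``compounds`` (202 records), ``interactions``
    (scored rows incl. sub-threshold decoys), ``disease_a`` / ``disease_b``
    (GeneCatalog), ``ppi_rows`` and ``collections`` (GO BP/MF/CC + pathways).
    The seed jitters scores only; every count is fixed by construction.
    """
    rng = _rng(seed)
    a_raw, b_raw = _disease_lists()
    return {
        "compounds": _compounds(rng),
        "interactions": _interactions(rng),
        "disease_a": GeneCatalog.from_symbols(a_raw, source="diseaseA"),
        "disease_b": GeneCatalog.from_symbols(b_raw, source="diseaseB"),
        "disease_a_raw": a_raw,
        "disease_b_raw": b_raw,
        "ppi_rows": _ppi_rows(rng),
        "collections": {
            "go_bp": _go_collection("bp", 0),
            "go_mf": _go_collection("mf", 3),
            "go_cc": _go_collection("cc", 6),
            "pathways": _pathway_collection(),
        },
    }


def write_study_dataset(outdir, seed: int = 0) -> dict:
    """Write the fixture to ``outdir`` in the pipeline's input formats."""
    fixture = build_study_fixture(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_compound_table(fixture["compounds"], outdir / "compounds.tsv")
    pio.write_interaction_table(fixture["interactions"], outdir / "interactions.tsv")
    # raw lists are written as-is (duplicates included) to mimic DB exports
    for key, fname in (("disease_a_raw", "disease_a.txt"), ("disease_b_raw", "disease_b.txt")):
        with open(outdir / fname, "w", encoding="utf-8", newline="\n") as fh:
            for sym in fixture[key]:
                fh.write(sym + "\n")
    pio.write_ppi_table(fixture["ppi_rows"], outdir / "ppi.tsv")
    for label, coll in fixture["collections"].items():
        pio.write_gmt(coll, outdir / f"{label}.gmt")
    return fixture
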