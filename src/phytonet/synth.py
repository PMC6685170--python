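"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates one of the five external data sources the pipeline
normally consumes (compound property tables, scored compound→target
predictions, disease-gene catalogs, a scored PPI edge table, GMT gene-set
collections) and emits a machine-readable truth record sufficient to score
the downstream stage exactly: how many compounds truly pass the ADME screen,
which interactions truly survive the dual-score filter (hence which
compounds are orphans), how many compound targets sit inside the disease
union, which PPI nodes were wired as hubs, and which gene set was planted
as enriched.

Reproducibility contract: the same :class:`SynthSpec` (seed included)
produces byte-identical output files. Each generator draws from its own
pseudo-random stream, derived from the master seed by a stable label hash,
so adding a generator never perturbs the others.

Gene symbols are synthesized as ``G000001``-style identifiers; no real gene
names appear, so no accidental biological claims are made.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.stats import beta as beta_dist

from .adme import CompoundRecord, DEFAULT_DL_MIN, DEFAULT_OB_MIN
from .catalog import GeneCatalog
from .enrichment import GeneSetCollection
from .errors import SynthSpecError
from .fishing import DEFAULT_RF_MIN, DEFAULT_SVM_MIN, InteractionRecord
from . import io as pio

__all__ = [
    "SynthSpec",
    "gen_compound_table",
    "gen_interactions",
    "gen_disease_catalog",
    "gen_ppi",
    "gen_genesets",
    "write_synth_dataset",
]


def _rng(seed: int, label: str) -> np.random.Generator:
    # stable labeled sub-stream: master seed + crc32 of the label
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(label.encode())])


def _symbol(i: int) -> str:
    return f"G{i:06d}"


@dataclass
class SynthSpec:
    """Study-scale parameters for the synthetic dataset.

    Defaults echo the scale of a single-herb screen: ~200 raw compounds of
    which roughly a third clear the ADME thresholds, ~100 predictable
    targets, a disease catalog an order of magnitude larger than the target
    list with ~70% of targets inside it, a PPI over the common targets with
    a few wired-in hubs, and gene-set collections with one planted enriched
    term at three-fold over-representation.
    """

    seed: int = 0
    # compounds
    n_compounds: int = 200
    frac_pass_ob: float = 0.5
    frac_pass_dl: float = 0.65
    descriptor_dim: int = 16
    # interactions
    n_targets: int = 100
    edge_density: float = 0.21
    orphan_frac: float = 0.07
    decoy_density: float = 0.05
    rf_alpha: float = 9.0
    rf_beta: float = 2.0
    svm_alpha: float = 12.0
    svm_beta: float = 2.0
    decoy_alpha: float = 2.0
    decoy_beta: float = 5.0
    # disease catalogs
    n_disease_genes: int = 1000
    overlap_frac: float = 0.7
    disease_shared_frac: float = 0.3
    # PPI
    ppi_model: str = "scale_free"
    planted_hub_count: int = 3
    ppi_frac_low: float = 0.25
    # gene sets
    n_sets: int = 50
    planted_set_effect: float = 4.0
    universe_size: int = 1000

    def __post_init__(self) -> None:
        fracs = {
            "frac_pass_ob": self.frac_pass_ob,
            "frac_pass_dl": self.frac_pass_dl,
            "edge_density": self.edge_density,
            "orphan_frac": self.orphan_frac,
            "decoy_density": self.decoy_density,
            "overlap_frac": self.overlap_frac,
            "disease_shared_frac": self.disease_shared_frac,
            "ppi_frac_low": self.ppi_frac_low,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise SynthSpecError(f"{name}={v} must lie in [0, 1]")
        counts = {
            "n_compounds": self.n_compounds,
            "descriptor_dim": self.descriptor_dim,
            "n_targets": self.n_targets,
            "n_disease_genes": self.n_disease_genes,
            "planted_hub_count": self.planted_hub_count + 1,  # 0 allowed
            "n_sets": self.n_sets,
            "universe_size": self.universe_size,
        }
        for name, v in counts.items():
            if v <= 0:
                raise SynthSpecError(f"{name} must be positive")
        if self.ppi_model not in ("scale_free", "configuration"):
            raise SynthSpecError(f"unknown ppi_model {self.ppi_model!r}")
        if self.planted_set_effect < 1.0:
            raise SynthSpecError("planted_set_effect must be >= 1")


def gen_compound_table(spec: SynthSpec) -> tuple[list[CompoundRecord], dict]:
    """Draw a compound table whose expected ADME pass fraction is controlled.

    OB is a two-component mixture across the 30% threshold (a compound
    passes OB with probability ``frac_pass_ob``), DL likewise across 0.18;
    the two are independent, so the expected joint pass fraction is their
    product. Binary descriptor vectors of the requested dimension are
    attached.
    """
    rng = _rng(spec.seed, "compounds")
    n = spec.n_compounds
    pass_ob = rng.random(n) < spec.frac_pass_ob
    pass_dl = rng.random(n) < spec.frac_pass_dl
    u_ob = rng.random(n)
    u_dl = rng.random(n)
    ob = np.where(pass_ob, 30.0 + 70.0 * u_ob, 30.0 * u_ob)
    dl = np.where(pass_dl, 0.18 + 0.82 * u_dl, 0.18 * u_dl)
    descriptors = rng.integers(0, 2, size=(n, spec.descriptor_dim))
    records = [
        CompoundRecord(
            compound_id=f"C{i + 1:04d}",
            name=f"compound-{i + 1:04d}",
            ob=round(float(ob[i]), 4),
            dl=round(float(dl[i]), 4),
            descriptors=descriptors[i].astype(float),
        )
        for i in range(n)
    ]
    n_pass = int(
        sum(1 for r in records if r.ob >= DEFAULT_OB_MIN and r.dl >= DEFAULT_DL_MIN)
    )
    truth = {
        "n_compounds": n,
        "n_pass_threshold": n_pass,
        "pass_ids": [
            r.compound_id
            for r in records
            if r.ob >= DEFAULT_OB_MIN and r.dl >= DEFAULT_DL_MIN
        ],
    }
    return records, truth


def gen_interactions(
    spec: SynthSpec, compounds: list[CompoundRecord]
) -> tuple[list[InteractionRecord], dict]:
    """Draw scored compound→target predictions with known ground truth.

    True edges exist only between screen-passing compounds and targets
    (density ``edge_density``); their RF/SVM scores come from high-mode Beta
    distributions, so both cutoffs are cleared with the probability recorded
    in the truth as ``p_true``. A fraction ``orphan_frac`` of passing
    compounds is denied true edges entirely, planting orphans. Decoy rows
    with low-mode scores are sprinkled over all compounds. The truth lists
    the edges that actually clear both cutoffs and the resulting orphans.
    """
    rng = _rng(spec.seed, "interactions")
    targets = [_symbol(i + 1) for i in range(spec.n_targets)]
    candidates = [
        r for r in compounds if r.ob >= DEFAULT_OB_MIN and r.dl >= DEFAULT_DL_MIN
    ]
    records: list[InteractionRecord] = []
    true_edges: list[tuple[str, str]] = []
    for rec in candidates:
        if rng.random() < spec.orphan_frac:
            continue
        hit = rng.random(spec.n_targets) < spec.edge_density
        for j in np.flatnonzero(hit):
            rf = float(rng.beta(spec.rf_alpha, spec.rf_beta))
            svm = float(rng.beta(spec.svm_alpha, spec.svm_beta))
            records.append(
                InteractionRecord(rec.compound_id, targets[j], round(rf, 4), round(svm, 4))
            )
            true_edges.append((rec.compound_id, targets[j]))
    for rec in compounds:
        hit = rng.random(spec.n_targets) < spec.decoy_density
        for j in np.flatnonzero(hit):
            rf = float(rng.beta(spec.decoy_alpha, spec.decoy_beta))
            svm = float(rng.beta(spec.decoy_alpha, spec.decoy_beta))
            records.append(
                InteractionRecord(rec.compound_id, targets[j], round(rf, 4), round(svm, 4))
            )
    retained = sorted(
        {
            (r.compound_id, r.target_symbol)
            for r in records
            if r.rf_score >= DEFAULT_RF_MIN and r.svm_score >= DEFAULT_SVM_MIN
        }
    )
    retained_compounds = {c for c, _ in retained}
    orphans = sorted(
        r.compound_id for r in candidates if r.compound_id not in retained_compounds
    )
    p_true = float(
        beta_dist.sf(DEFAULT_RF_MIN, spec.rf_alpha, spec.rf_beta)
        * beta_dist.sf(DEFAULT_SVM_MIN, spec.svm_alpha, spec.svm_beta)
    )
    truth = {
        "n_candidates": len(candidates),
        "p_true": p_true,
        "true_edges": sorted(true_edges),
        "retained_edges": retained,
        "retained_targets": sorted({t for _, t in retained}),
        "orphans": orphans,
        "n_connected": len(candidates) - len(orphans),
    }
    return records, truth


def gen_disease_catalog(
    spec: SynthSpec, compound_target_symbols: list[str]
) -> tuple[list[GeneCatalog], dict]:
    """Build two overlapping disease-gene catalogs with a planted target overlap.

    Exactly ``round(overlap_frac * |targets|)`` compound-target symbols are
    placed inside the disease union (of total size ``n_disease_genes``);
    ``disease_shared_frac`` of the union is shared between the two sources so
    merging exercises deduplication.
    """
    rng = _rng(spec.seed, "disease")
    targets = sorted(set(compound_target_symbols))
    n_common = round(spec.overlap_frac * len(targets))
    if n_common > spec.n_disease_genes:
        raise SynthSpecError(
            f"overlap_frac demands {n_common} genes but the disease union "
            f"holds only {spec.n_disease_genes}"
        )
    common = sorted(rng.choice(targets, size=n_common, replace=False).tolist())
    n_filler = spec.n_disease_genes - n_common
    filler = [_symbol(spec.n_targets + 1 + i) for i in range(n_filler)]
    union = common + filler
    order = rng.permutation(len(union))
    shuffled = [union[i] for i in order]
    n_shared = round(spec.disease_shared_frac * len(union))
    shared = shuffled[:n_shared]
    rest = shuffled[n_shared:]
    half = len(rest) // 2
    cat_a = GeneCatalog.from_symbols(shared + rest[:half], source="diseaseA")
    cat_b = GeneCatalog.from_symbols(shared + rest[half:], source="diseaseB")
    truth = {
        "n_union": len(union),
        "n_common": n_common,
        "common": common,
        "n_shared_between_sources": n_shared,
    }
    return [cat_a, cat_b], truth


def gen_ppi(spec: SynthSpec, node_symbols: list[str]) -> tuple[list, dict]:
    """Wire a scored PPI edge table over the given nodes, planting hubs.

    The base topology is scale-free (preferential attachment) or a Poisson
    configuration model. Confidence scores put ``ppi_frac_low`` of
    non-hub edges below the 0.4 cutoff; edges touching a planted hub always
    score above it. Hubs are then re-wired (adding high-confidence edges)
    until each strictly exceeds twice the mean degree of the retained
    (confidence > 0.4) graph, so hub detection downstream must recover them.
    """
    rng = _rng(spec.seed, "ppi")
    nodes = sorted(set(node_symbols))
    n = len(nodes)
    if n < spec.planted_hub_count + 2:
        raise SynthSpecError(
            f"need at least {spec.planted_hub_count + 2} nodes, got {n}"
        )
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if spec.ppi_model == "scale_free":
        base = nx.barabasi_albert_graph(n, m=min(3, n - 1), seed=nx_seed)
    else:
        degs = rng.poisson(5, size=n) + 1
        if degs.sum() % 2:
            degs[0] += 1
        base = nx.Graph(nx.configuration_model(degs.tolist(), seed=nx_seed))
        base.remove_edges_from(nx.selfloop_edges(base))
    relabel = {i: nodes[i] for i in range(n)}
    base = nx.relabel_nodes(base, relabel)
    hubs = sorted(
        rng.choice(nodes, size=spec.planted_hub_count, replace=False).tolist()
    )
    hub_set = set(hubs)

    def high() -> float:
        return round(0.41 + 0.58 * float(rng.random()), 3)

    def low() -> float:
        return round(0.05 + 0.35 * float(rng.random()), 3)

    conf: dict[tuple[str, str], float] = {}
    for a, b in base.edges():
        key = (a, b) if a < b else (b, a)
        if a in hub_set or b in hub_set:
            conf[key] = high()
        else:
            conf[key] = low() if rng.random() < spec.ppi_frac_low else high()

    def retained_graph() -> nx.Graph:
        g = nx.Graph()
        for (a, b), c in conf.items():
            if c > 0.4:
                g.add_edge(a, b)
        return g

    for _ in range(100 * n + 1000):
        g = retained_graph()
        if g.number_of_edges() == 0:
            break
        thr = 2.0 * (2.0 * g.number_of_edges() / g.number_of_nodes())
        weak = [h for h in hubs if (g.degree(h) if h in g else 0) <= thr]
        if not weak:
            break
        h = weak[0]
        neigh = set(g[h]) if h in g else set()
        choices = [v for v in nodes if v != h and v not in neigh]
        if not choices:
            raise SynthSpecError(f"cannot wire hub {h}: saturated")
        v = choices[int(rng.integers(0, len(choices)))]
        key = (h, v) if h < v else (v, h)
        conf[key] = high()
    else:
        raise SynthSpecError("unsatisfiable planted-hub demand")

    rows = [(a, b, c) for (a, b), c in sorted(conf.items())]
    g = retained_graph()
    truth = {
        "planted_hubs": hubs,
        "n_nodes_retained": g.number_of_nodes(),
        "n_edges_retained": g.number_of_edges(),
    }
    return rows, truth


def gen_genesets(
    spec: SynthSpec, query_genes: list[str], label: str = "genesets"
) -> tuple[GeneSetCollection, dict]:
    """Generate a GMT collection with one planted over-represented set.

    Random sets are drawn over a universe containing the query; the planted
    set's overlap with the query is ``planted_set_effect`` times the
    expectation ``n*K/N`` of a random set of the same size.
    """
    rng = _rng(spec.seed, label)
    query = sorted(set(query_genes))
    n = len(query)
    if spec.universe_size < n:
        raise SynthSpecError(
            f"universe_size {spec.universe_size} smaller than query ({n})"
        )
    filler = [_symbol(50000 + i + 1) for i in range(spec.universe_size - n)]
    universe = query + filler
    non_query = filler
    N = len(universe)

    sets: dict[str, tuple[str, list[str]]] = {}
    planted_id = "S0001"
    K_p = min(50, N)
    expected = n * K_p / N
    hits = int(round(spec.planted_set_effect * expected))
    if hits > min(n, K_p):
        raise SynthSpecError(
            f"planted_set_effect {spec.planted_set_effect} unachievable: "
            f"needs {hits} query hits, at most {min(n, K_p)} possible"
        )
    members = rng.choice(query, size=hits, replace=False).tolist()
    members += rng.choice(non_query, size=K_p - hits, replace=False).tolist()
    sets[planted_id] = (f"{label} planted set", members)
    for i in range(2, spec.n_sets + 1):
        size = int(rng.integers(20, 81))
        sets[f"S{i:04d}"] = (
            f"{label} random set {i}",
            rng.choice(universe, size=size, replace=False).tolist(),
        )
    collection = GeneSetCollection.from_sets(label, sets, universe=universe)
    truth = {
        "planted_term": planted_id,
        "planted_hits": hits,
        "expected_hits": expected,
        "planted_set_size": K_p,
    }
    return collection, truth


def write_synth_dataset(spec: SynthSpec, outdir) -> dict:
    """Generate all five inputs plus truth files under ``outdir``.

    Files: compounds.tsv, interactions.tsv, disease_a.txt, disease_b.txt,
    ppi.tsv, go_bp.gmt / go_mf.gmt / go_cc.gmt / kegg.gmt, truth.json and
    synthspec.json. Returns the combined truth dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds, truth_c = gen_compound_table(spec)
    interactions, truth_i = gen_interactions(spec, compounds)
    catalogs, truth_d = gen_disease_catalog(spec, truth_i["retained_targets"])
    merged_symbols = catalogs[0].symbols | catalogs[1].symbols
    common = sorted(set(truth_i["retained_targets"]) & merged_symbols)
    ppi_rows, truth_p = gen_ppi(spec, common) if len(common) >= spec.planted_hub_count + 2 else ([], {})
    collections = {}
    truth_g = {}
    for label in ("go_bp", "go_mf", "go_cc", "kegg"):
        coll, t = gen_genesets(spec, common, label=label)
        collections[label] = coll
        truth_g[label] = t

    pio.write_compound_table(compounds, outdir / "compounds.tsv")
    pio.write_interaction_table(interactions, outdir / "interactions.tsv")
    pio.write_gene_list(catalogs[0].symbols, outdir / "disease_a.txt", source="diseaseA")
    pio.write_gene_list(catalogs[1].symbols, outdir / "disease_b.txt", source="diseaseB")
    if ppi_rows:
        pio.write_ppi_table(ppi_rows, outdir / "ppi.tsv")
    for label, coll in collections.items():
        pio.write_gmt(coll, outdir / f"{label}.gmt")

    truth = {
        "compounds": truth_c,
        "interactions": truth_i,
        "disease": truth_d,
        "n_common": len(common),
        "common": common,
        "ppi": truth_p,
        "genesets": truth_g,
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    with open(outdir / "synthspec.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(spec), fh, indent=2, sort_keys=True)
    return truth
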