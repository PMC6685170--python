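"""End-to-end pipeline orchestration.

Runs the stages in order — ADME screen → target fishing → disease-catalog
merge/intersection → network analysis (bipartite + PPI) → over-representation
analysis — from a single validated configuration, writing every stage output
under one directory plus a consolidated JSON report. The report carries, per
stage, the input/output counts (the compound → candidate → connected →
target → common-target chain), the thresholds applied, degree summaries, the
hub list, the top enriched terms per collection, and a content hash of every
written file, so identical inputs provably give identical runs.

Stages whose inputs are absent (or that are toggled off) are marked
``skipped``; stages that do not depend on them still run. All randomness in
the package lives in the synthetic generators — the analysis stages here are
deterministic by contract.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import io as pio
from .adme import DEFAULT_DL_MIN, DEFAULT_OB_MIN, screen_compounds
from .catalog import intersect_targets, merge_catalogs
from .enrichment import DEFAULT_ALPHA, DEFAULT_TOP_K, enrich, top_terms
from .errors import InputError
from .fishing import DEFAULT_RF_MIN, DEFAULT_SVM_MIN, filter_interactions, partition_orphans
from .network import (
    DEFAULT_HUB_MULTIPLIER,
    DEFAULT_PPI_SCORE_MIN,
    build_bipartite,
    build_ppi,
    class_degree_summary,
    detect_hubs,
    export_network,
)

logger = logging.getLogger("phytonet")

__all__ = ["DiseaseListInput", "PipelineConfig", "PipelineReport", "run_pipeline", "load_config"]


class DiseaseListInput(BaseModel):
    path: str
    source: str


class PipelineConfig(BaseModel):
    """Every input path and every threshold of one pipeline run."""

    compound_table: str
    interaction_table: str
    disease_lists: list[DiseaseListInput] = Field(default_factory=list)
    ppi_table: str | None = None
    genesets: dict[str, str] = Field(default_factory=dict)
    outdir: str = "phytonet_out"

    ob_min: float = DEFAULT_OB_MIN
    dl_min: float = DEFAULT_DL_MIN
    whitelist: list[str] = Field(default_factory=list)
    rf_min: float = DEFAULT_RF_MIN
    svm_min: float = DEFAULT_SVM_MIN
    ppi_score_min: float = DEFAULT_PPI_SCORE_MIN
    hub_multiplier: float = DEFAULT_HUB_MULTIPLIER
    compound_degree_min: float | None = 30.0
    enrich_alpha: float = DEFAULT_ALPHA
    top_k: int = DEFAULT_TOP_K
    min_set_size: int = 2

    enable_network: bool = True
    enable_enrichment: bool = True
    seed: int = 0


class ScreenStage(BaseModel):
    status: str = "ok"
    n_input: int = 0
    n_pass_threshold: int = 0
    n_whitelisted_in: int = 0
    n_candidates: int = 0
    n_excluded: int = 0
    ob_min: float = DEFAULT_OB_MIN
    dl_min: float = DEFAULT_DL_MIN


class FishStage(BaseModel):
    status: str = "ok"
    n_input_rows: int = 0
    n_filtered_edges: int = 0
    n_orphans: int = 0
    n_connected: int = 0
    n_targets: int = 0
    rf_min: float = DEFAULT_RF_MIN
    svm_min: float = DEFAULT_SVM_MIN


class DiseaseStage(BaseModel):
    status: str = "ok"
    per_source: dict[str, int] = Field(default_factory=dict)
    per_source_raw: dict[str, int] = Field(default_factory=dict)
    union_count: int = 0
    duplicates_removed: int = 0
    n_common_targets: int = 0


class HubEntry(BaseModel):
    node: str
    degree: int


class NetworkStage(BaseModel):
    status: str = "ok"
    bipartite_compound_nodes: int = 0
    bipartite_target_nodes: int = 0
    bipartite_nodes: int = 0
    bipartite_edges: int = 0
    mean_compound_degree: float = 0.0
    mean_target_degree: float = 0.0
    compound_degree_min: float | None = None
    n_compounds_above_degree_min: int | None = None
    ppi_score_min: float = DEFAULT_PPI_SCORE_MIN
    ppi_nodes: int = 0
    ppi_edges: int = 0
    ppi_mean_degree: float = 0.0
    hub_multiplier: float = DEFAULT_HUB_MULTIPLIER
    hub_threshold: float = 0.0
    hubs: list[HubEntry] = Field(default_factory=list)
    ppi_excluded_no_interaction: list[str] = Field(default_factory=list)
    ppi_excluded_not_found: list[str] = Field(default_factory=list)


class TermEntry(BaseModel):
    term_id: str
    term_name: str
    k: int
    K: int
    p_value: float
    q_value: float


class EnrichCollectionSummary(BaseModel):
    collection: str
    n_terms_tested: int
    n_mapped: int
    n_unmapped: int
    n_significant: int
    top_terms: list[TermEntry] = Field(default_factory=list)


class EnrichStage(BaseModel):
    status: str = "ok"
    alpha: float = DEFAULT_ALPHA
    top_k: int = DEFAULT_TOP_K
    collections: list[EnrichCollectionSummary] = Field(default_factory=list)


class PipelineReport(BaseModel):
    """Consolidated, schema-validated record of one pipeline run."""

    phytonet_version: str = "0.1.0"
    screen: ScreenStage = Field(default_factory=ScreenStage)
    fish: FishStage = Field(default_factory=FishStage)
    disease: DiseaseStage = Field(default_factory=DiseaseStage)
    network: NetworkStage = Field(default_factory=NetworkStage)
    enrichment: EnrichStage = Field(default_factory=EnrichStage)
    output_hashes: dict[str, str] = Field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a mapping")
    return PipelineConfig(**data)


def _check_paths(config: PipelineConfig) -> None:
    paths = [config.compound_table, config.interaction_table]
    paths += [d.path for d in config.disease_lists]
    if config.ppi_table:
        paths.append(config.ppi_table)
    paths += list(config.genesets.values())
    for p in paths:
        if not Path(p).exists():
            raise InputError(f"input path does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all configured stages; write outputs and report under outdir."""
    _check_paths(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()
    written: list[Path] = []

    # --- stage: ADME screen -------------------------------------------------
    logger.info("stage screen: reading %s", config.compound_table)
    compounds = pio.read_compound_table(config.compound_table)
    candidates, screen_report = screen_compounds(
        compounds, config.ob_min, config.dl_min, config.whitelist
    )
    report.screen = ScreenStage(
        n_input=screen_report.n_input,
        n_pass_threshold=screen_report.n_pass_threshold,
        n_whitelisted_in=screen_report.n_whitelisted_in,
        n_candidates=len(candidates),
        n_excluded=screen_report.n_excluded,
        ob_min=config.ob_min,
        dl_min=config.dl_min,
    )
    assert report.screen.n_candidates == (
        report.screen.n_pass_threshold + report.screen.n_whitelisted_in
    )
    pio.write_compound_table(candidates, outdir / "candidates.tsv")
    (outdir / "screening_report.json").write_text(screen_report.to_json() + "\n")
    written += [outdir / "candidates.tsv", outdir / "screening_report.json"]
    logger.info("stage screen: %d/%d candidates", len(candidates), len(compounds))

    # --- stage: target fishing ---------------------------------------------
    interactions = pio.read_interaction_table(config.interaction_table)
    known_ids = {c.compound_id for c in candidates}
    relevant = [r for r in interactions if r.compound_id in known_ids]
    filtered = filter_interactions(relevant, config.rf_min, config.svm_min)
    connected, orphans = partition_orphans(candidates, filtered)
    target_symbols = sorted({r.target_symbol for r in filtered})
    report.fish = FishStage(
        n_input_rows=len(interactions),
        n_filtered_edges=len(filtered),
        n_orphans=len(orphans),
        n_connected=len(connected),
        n_targets=len(target_symbols),
        rf_min=config.rf_min,
        svm_min=config.svm_min,
    )
    assert report.fish.n_connected + report.fish.n_orphans == report.screen.n_candidates
    pio.write_interaction_table(filtered, outdir / "filtered_interactions.tsv")
    pio.write_gene_list(
        (c.compound_id for c in orphans), outdir / "orphans.tsv", source="orphans"
    )
    written += [outdir / "filtered_interactions.tsv", outdir / "orphans.tsv"]
    logger.info(
        "stage fish: %d edges, %d connected, %d orphans",
        len(filtered), len(connected), len(orphans),
    )

    # --- stage: disease catalog ---------------------------------------------
    common: list[str] = []
    if config.disease_lists:
        catalogs = [
            pio.read_gene_list(d.path, source=d.source) for d in config.disease_lists
        ]
        merged, merge_report = merge_catalogs(catalogs)
        common = intersect_targets(target_symbols, merged)
        report.disease = DiseaseStage(
            per_source=merge_report.per_source,
            per_source_raw=merge_report.per_source_raw,
            union_count=merge_report.union_count,
            duplicates_removed=merge_report.duplicates_removed,
            n_common_targets=len(common),
        )
        pio.write_gene_list(merged.symbols, outdir / "merged_catalog.tsv", source="merged")
        pio.write_gene_list(common, outdir / "common_targets.tsv", source="common")
        written += [outdir / "merged_catalog.tsv", outdir / "common_targets.tsv"]
        logger.info("stage disease: union %d, common %d", merge_report.union_count, len(common))
    else:
        report.disease = DiseaseStage(status="skipped")
        logger.info("stage disease: skipped (no disease lists)")

    # --- stage: network analysis --------------------------------------------
    if config.enable_network and filtered:
        bip = build_bipartite(connected, filtered)
        comp_summary = class_degree_summary(bip, "compound", config.compound_degree_min)
        tgt_summary = class_degree_summary(bip, "target")
        assert len(bip.target_nodes) == len(target_symbols)
        net_stage = NetworkStage(
            bipartite_compound_nodes=len(bip.compound_nodes),
            bipartite_target_nodes=len(bip.target_nodes),
            bipartite_nodes=bip.n_nodes,
            bipartite_edges=bip.n_edges,
            mean_compound_degree=comp_summary.mean_degree,
            mean_target_degree=tgt_summary.mean_degree,
            compound_degree_min=config.compound_degree_min,
            n_compounds_above_degree_min=comp_summary.n_above_min,
            ppi_score_min=config.ppi_score_min,
            hub_multiplier=config.hub_multiplier,
        )
        export_network(bip, "sif", outdir / "bipartite.sif")
        export_network(bip, "graphml", outdir / "bipartite.graphml")
        deg_rows = [
            {"node": n, "class": "compound", "degree": d}
            for n, d in sorted(comp_summary.per_node_degree.items())
        ] + [
            {"node": n, "class": "target", "degree": d}
            for n, d in sorted(tgt_summary.per_node_degree.items())
        ]
        pd.DataFrame(deg_rows).to_csv(
            outdir / "bipartite_degrees.tsv", sep="\t", index=False, lineterminator="\n"
        )
        written += [
            outdir / "bipartite.sif",
            outdir / "bipartite.graphml",
            outdir / "bipartite_degrees.tsv",
        ]
        logger.info(
            "stage network: bipartite %d nodes / %d edges", bip.n_nodes, bip.n_edges
        )

        if config.ppi_table and common:
            ppi_rows = pio.read_ppi_table(config.ppi_table)
            ppi, ppi_report = build_ppi(ppi_rows, config.ppi_score_min, common)
            hub_report = detect_hubs(ppi, config.hub_multiplier)
            assert ppi.n_nodes <= len(common)
            net_stage.ppi_nodes = ppi.n_nodes
            net_stage.ppi_edges = ppi.n_edges
            net_stage.ppi_mean_degree = hub_report.mean_degree
            net_stage.hub_threshold = hub_report.threshold
            net_stage.hubs = [HubEntry(node=n, degree=d) for n, d in hub_report.hubs]
            net_stage.ppi_excluded_no_interaction = ppi_report.excluded_no_interaction
            net_stage.ppi_excluded_not_found = ppi_report.excluded_not_found
            export_network(ppi, "sif", outdir / "ppi.sif")
            export_network(ppi, "graphml", outdir / "ppi.graphml")
            (outdir / "hubs.json").write_text(hub_report.to_json() + "\n")
            written += [outdir / "ppi.sif", outdir / "ppi.graphml", outdir / "hubs.json"]
            logger.info(
                "stage network: PPI %d nodes / %d edges, %d hubs over %.2f",
                ppi.n_nodes, ppi.n_edges, len(hub_report.hubs), hub_report.threshold,
            )
        report.network = net_stage
    else:
        report.network = NetworkStage(status="skipped")
        logger.info("stage network: skipped")

    # --- stage: enrichment ----------------------------------------------------
    query = common if common else target_symbols
    if config.enable_enrichment and config.genesets and query:
        enr_stage = EnrichStage(alpha=config.enrich_alpha, top_k=config.top_k)
        for label, gmt_path in sorted(config.genesets.items()):
            collection = pio.read_gmt(gmt_path, name=label)
            results, enr_report = enrich(query, collection, config.min_set_size)
            top = top_terms(results, config.enrich_alpha, config.top_k)
            enr_stage.collections.append(
                EnrichCollectionSummary(
                    collection=label,
                    n_terms_tested=len(results),
                    n_mapped=enr_report.n_mapped,
                    n_unmapped=enr_report.n_unmapped,
                    n_significant=sum(
                        1 for r in results if r.p_value < config.enrich_alpha
                    ),
                    top_terms=[
                        TermEntry(
                            term_id=r.term_id,
                            term_name=r.term_name,
                            k=r.k,
                            K=r.K,
                            p_value=r.p_value,
                            q_value=r.q_value,
                        )
                        for r in top
                    ],
                )
            )
            pio.write_enrichment_table(results, outdir / f"enrichment_{label}.tsv")
            pio.write_enrichment_table(top, outdir / f"top_{label}.tsv")
            written += [outdir / f"enrichment_{label}.tsv", outdir / f"top_{label}.tsv"]
            logger.info(
                "stage enrich[%s]: %d terms, %d mapped, %d significant",
                label, len(results), enr_report.n_mapped,
                enr_stage.collections[-1].n_significant,
            )
        report.enrichment = enr_stage
    else:
        report.enrichment = EnrichStage(status="skipped")
        logger.info("stage enrich: skipped")

    report.output_hashes = {p.name: pio.sha256_file(p) for p in sorted(written)}
    (outdir / "report.json").write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    return report
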