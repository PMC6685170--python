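"""Compound–target and protein–protein interaction networks.

Two graph objects drive all degree statistics:

* :class:`BipartiteNetwork` — the simple bipartite graph linking screened
  compounds to their retained targets. The mean degree of a node class is
  ``|edges| / |class|`` (each edge contributes one endpoint per class).
* :class:`PPINetwork` — the undirected protein–protein interaction graph,
  built from a scored edge table (STRING-style export) by keeping edges with
  combined confidence strictly above a cutoff (default 0.4). Scores on the
  0–1000 integer dialect are auto-detected and rescaled to [0, 1].

Hubs follow the two-times-mean-degree rule: with mean degree ``2E/N``, a hub
is any node whose degree strictly exceeds ``2 * (2E/N)``. Exports to SIF and
GraphML are byte-stable (nodes and edges sorted) for interchange with
network-visualization tools.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx

from .adme import CompoundRecord
from .catalog import normalize_symbol
from .errors import InputError
from .fishing import InteractionRecord

DEFAULT_PPI_SCORE_MIN = 0.4
DEFAULT_HUB_MULTIPLIER = 2.0

__all__ = [
    "BipartiteNetwork",
    "PPINetwork",
    "DegreeSummary",
    "PPIBuildReport",
    "HubReport",
    "build_bipartite",
    "class_degree_summary",
    "build_ppi",
    "detect_hubs",
    "export_network",
    "DEFAULT_PPI_SCORE_MIN",
    "DEFAULT_HUB_MULTIPLIER",
]


@dataclass(frozen=True)
class BipartiteNetwork:
    """Simple bipartite compound–target graph.

    Self-loops are impossible by construction (the classes are disjoint);
    the degree-sum handshake ``sum(compound degrees) = sum(target degrees)
    = |edges|`` is asserted at build time.
    """

    compound_nodes: frozenset[str]
    target_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.compound_nodes & self.target_nodes:
            raise InputError("compound and target node sets must be disjoint")
        for c, t in self.edges:
            if c not in self.compound_nodes or t not in self.target_nodes:
                raise InputError(f"edge ({c!r}, {t!r}) has an unknown endpoint")

    @property
    def n_nodes(self) -> int:
        return len(self.compound_nodes) + len(self.target_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        if node in self.compound_nodes:
            return sum(1 for c, _ in self.edges if c == node)
        if node in self.target_nodes:
            return sum(1 for _, t in self.edges if t == node)
        raise InputError(f"unknown node {node!r}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for c in sorted(self.compound_nodes):
            g.add_node(c, kind="compound")
        for t in sorted(self.target_nodes):
            g.add_node(t, kind="target")
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple PPI graph; edge keys are sorted symbol pairs."""

    confidences: dict[tuple[str, str], float]
    score_min: float = DEFAULT_PPI_SCORE_MIN

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for pair in self.confidences for n in pair)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.confidences)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.confidences)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), conf in sorted(self.confidences.items()):
            g.add_edge(a, b, confidence=conf)
        return g


@dataclass
class DegreeSummary:
    """Per-node degrees plus the class/graph mean."""

    per_node_degree: dict[str, int]
    mean_degree: float
    n_nodes: int
    n_edges: int
    degree_min: float | None = None
    n_above_min: int | None = None


@dataclass
class PPIBuildReport:
    """What the confidence filter kept and what it excluded."""

    n_input_rows: int
    n_edges: int
    n_nodes: int
    score_min: float
    rescaled_from_0_1000: bool
    excluded_no_interaction: list[str] = field(default_factory=list)
    excluded_not_found: list[str] = field(default_factory=list)


@dataclass
class HubReport:
    """Hub nodes under the two-times-mean-degree rule."""

    hubs: list[tuple[str, int]]
    threshold: float
    mean_degree: float
    multiplier: float
    per_node_degree: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_degree": self.mean_degree,
                "multiplier": self.multiplier,
                "threshold": self.threshold,
                "hubs": [{"node": n, "degree": d} for n, d in self.hubs],
            },
            indent=2,
        )


def build_bipartite(
    compounds: Sequence[CompoundRecord | str],
    edges: Sequence[InteractionRecord],
) -> BipartiteNetwork:
    """Assemble the bipartite network from connected compounds and filtered edges."""
    if not edges:
        raise InputError("cannot build a bipartite network from an empty edge list")
    ids = frozenset(
        c.compound_id if isinstance(c, CompoundRecord) else c for c in compounds
    )
    edge_set = set()
    targets = set()
    for rec in edges:
        if rec.compound_id not in ids:
            raise InputError(
                f"edge references unknown compound_id {rec.compound_id!r}"
            )
        sym = normalize_symbol(rec.target_symbol)
        targets.add(sym)
        edge_set.add((rec.compound_id, sym))
    net = BipartiteNetwork(
        compound_nodes=ids, target_nodes=frozenset(targets), edges=frozenset(edge_set)
    )
    # degree-sum handshake: each edge has exactly one endpoint per class
    assert sum(net.degree(c) for c in net.compound_nodes) == net.n_edges
    assert sum(net.degree(t) for t in net.target_nodes) == net.n_edges
    return net


def class_degree_summary(
    net: BipartiteNetwork,
    node_class: str,
    degree_min: float | None = None,
) -> DegreeSummary:
    """Degree statistics over one bipartite class ("compound" or "target").

    The class mean equals ``|edges| / |class|``. When ``degree_min`` is given
    the summary also counts nodes with degree strictly above it.
    """
    if node_class == "compound":
        nodes = net.compound_nodes
        idx = 0
    elif node_class == "target":
        nodes = net.target_nodes
        idx = 1
    else:
        raise InputError(f"unknown node class {node_class!r}")
    if not nodes:
        raise InputError(f"node class {node_class!r} is empty")
    degrees = dict.fromkeys(sorted(nodes), 0)
    for edge in net.edges:
        degrees[edge[idx]] += 1
    mean = net.n_edges / len(nodes)
    n_above = None
    if degree_min is not None:
        n_above = sum(1 for d in degrees.values() if d > degree_min)
    return DegreeSummary(
        per_node_degree=degrees,
        mean_degree=mean,
        n_nodes=len(nodes),
        n_edges=net.n_edges,
        degree_min=degree_min,
        n_above_min=n_above,
    )


def _rescale_scores(rows: list[tuple[str, str, float]]) -> tuple[list, bool]:
    # STRING exports use either 0-1 floats or 0-1000 integer combined scores
    if any(score > 1.0 for _, _, score in rows):
        return [(a, b, score / 1000.0) for a, b, score in rows], True
    return rows, False


def build_ppi(
    edge_table: Iterable[tuple[str, str, float]],
    score_min: float = DEFAULT_PPI_SCORE_MIN,
    node_filter: Iterable[str] | None = None,
) -> tuple[PPINetwork, PPIBuildReport]:
    """Build the PPI graph from scored pairs, keeping confidence > score_min.

    Self-loops are dropped, duplicate pairs collapse to the maximum
    confidence, and when ``node_filter`` is given only edges with both
    endpoints in the filter survive. Filter symbols that end up with no
    retained edge are reported as excluded — split into those that appeared
    in the table (all their edges were filtered away) and those never seen.
    """
    rows: list[tuple[str, str, float]] = []
    for i, row in enumerate(edge_table):
        try:
            a, b, score = row
            score = float(score)
        except (TypeError, ValueError) as exc:
            raise InputError(f"row {i}: malformed PPI row {row!r}") from exc
        if score < 0:
            raise InputError(f"row {i}: negative confidence score {score}")
        rows.append((normalize_symbol(a), normalize_symbol(b), score))
    n_input = len(rows)
    rows, rescaled = _rescale_scores(rows)
    for i, (_, _, score) in enumerate(rows):
        if score > 1.0:
            raise InputError(f"row {i}: confidence score {score} outside [0, 1]")

    filt = None if node_filter is None else {normalize_symbol(s) for s in node_filter}
    seen_in_table: set[str] = set()
    confidences: dict[tuple[str, str], float] = {}
    for a, b, score in rows:
        seen_in_table.update((a, b))
        if a == b:
            continue
        if filt is not None and (a not in filt or b not in filt):
            continue
        if score <= score_min:
            continue
        key = (a, b) if a < b else (b, a)
        confidences[key] = max(confidences.get(key, 0.0), score)
    if not confidences:
        raise InputError(
            f"no PPI edges retained at confidence > {score_min:g}; "
            "the network would be empty"
        )
    net = PPINetwork(confidences=confidences, score_min=score_min)
    retained_nodes = net.nodes
    excluded_no_int: list[str] = []
    excluded_not_found: list[str] = []
    if filt is not None:
        for sym in sorted(filt - retained_nodes):
            (excluded_no_int if sym in seen_in_table else excluded_not_found).append(sym)
    report = PPIBuildReport(
        n_input_rows=n_input,
        n_edges=net.n_edges,
        n_nodes=net.n_nodes,
        score_min=score_min,
        rescaled_from_0_1000=rescaled,
        excluded_no_interaction=excluded_no_int,
        excluded_not_found=excluded_not_found,
    )
    # handshake on the undirected simple graph
    degs = _ppi_degrees(net)
    assert sum(degs.values()) == 2 * net.n_edges
    return net, report


def _ppi_degrees(net: PPINetwork) -> dict[str, int]:
    degrees = dict.fromkeys(sorted(net.nodes), 0)
    for a, b in net.confidences:
        degrees[a] += 1
        degrees[b] += 1
    return degrees


def detect_hubs(
    net: PPINetwork, multiplier: float = DEFAULT_HUB_MULTIPLIER
) -> HubReport:
    """Find hub nodes: degree strictly greater than ``multiplier * mean``.

    Mean degree is ``2E/N`` on the simple undirected graph. Hubs are returned
    sorted by degree descending, ties broken alphabetically.
    """
    if net.n_edges == 0:
        raise InputError("detect_hubs requires a network with at least one edge")
    degrees = _ppi_degrees(net)
    mean = 2.0 * net.n_edges / net.n_nodes
    threshold = multiplier * mean
    hubs = sorted(
        ((n, d) for n, d in degrees.items() if d > threshold),
        key=lambda nd: (-nd[1], nd[0]),
    )
    return HubReport(
        hubs=hubs,
        threshold=threshold,
        mean_degree=mean,
        multiplier=multiplier,
        per_node_degree=degrees,
    )


def export_network(
    net: BipartiteNetwork | PPINetwork, fmt: str, path
) -> None:
    """Write a network as SIF or GraphML (byte-stable: sorted nodes/edges).

    SIF uses relation ``ct`` for compound–target edges and ``pp`` for PPIs.
    GraphML nodes carry ``kind`` (compound/target, bipartite only) and
    ``degree``; PPI edges carry their ``confidence``.
    """
    if net.n_edges == 0:
        raise InputError("refusing to export an empty network")
    if fmt == "sif":
        if isinstance(net, BipartiteNetwork):
            lines = [f"{c}\tct\t{t}" for c, t in sorted(net.edges)]
        else:
            lines = [f"{a}\tpp\t{b}" for a, b in sorted(net.edges)]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")
    elif fmt == "graphml":
        g = net.to_networkx()
        degs = dict(g.degree())
        nx.set_node_attributes(g, degs, "degree")
        with open(path, "wb") as fh:
            for line in nx.generate_graphml(g, named_key_ids=True):
                fh.write(line.encode("utf-8") + b"\n")
    else:
        raise InputError(f"unknown export format {fmt!r} (expected 'sif' or 'graphml')")
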