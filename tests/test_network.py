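"""Bipartite/PPI construction, degree statistics, hub detection, exports."""

import networkx as nx
import numpy as np
import pytest

from phytonet.errors import InputError
from phytonet.fishing import InteractionRecord
from phytonet.network import (
    PPINetwork,
    build_bipartite,
    build_ppi,
    class_degree_summary,
    detect_hubs,
    export_network,
)

R = InteractionRecord


class TestBipartite:
    def test_k23_counts(self, k23_network):
        assert k23_network.n_nodes == 5
        assert k23_network.n_edges == 6

    def test_empty_edges_rejected(self):
        with pytest.raises(InputError, match="empty"):
            build_bipartite(["c1"], [])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(InputError, match="unknown"):
            build_bipartite(["c1"], [R("c9", "T1", 0.9, 0.9)])

    def test_class_degree_summary_k23(self, k23_network):
        comp = class_degree_summary(k23_network, "compound")
        tgt = class_degree_summary(k23_network, "target")
        assert sorted(comp.per_node_degree.values()) == [3, 3]
        assert comp.mean_degree == pytest.approx(3.0)
        assert sorted(tgt.per_node_degree.values()) == [2, 2, 2]
        # degree-sum handshake: each class sums to |edges|
        assert sum(comp.per_node_degree.values()) == k23_network.n_edges
        assert sum(tgt.per_node_degree.values()) == k23_network.n_edges

    def test_single_compound_mean(self):
        edges = [R("c1", f"T{i}", 0.9, 0.9) for i in range(7)]
        net = build_bipartite(["c1"], edges)
        assert class_degree_summary(net, "compound").mean_degree == pytest.approx(7.0)

    def test_unknown_class_rejected(self, k23_network):
        with pytest.raises(InputError, match="class"):
            class_degree_summary(k23_network, "protein")

    def test_degree_threshold_count(self, k23_network):
        summary = class_degree_summary(k23_network, "compound", degree_min=2.5)
        assert summary.n_above_min == 2
        assert class_degree_summary(k23_network, "compound", 3).n_above_min == 0


class TestBuildPPI:
    def test_strict_cutoff_and_self_loops(self):
        rows = [("A", "B", 0.41), ("A", "C", 0.40), ("B", "B", 0.99)]
        net, report = build_ppi(rows, score_min=0.4)
        assert net.edges == {("A", "B")}
        assert report.n_edges == 1

    def test_node_filter_drops_outside_edges(self):
        rows = [("A", "B", 0.9), ("A", "C", 0.9)]
        net, _ = build_ppi(rows, node_filter={"A", "B"})
        assert net.edges == {("A", "B")}

    def test_string_0_1000_scores_autodetected(self):
        rows = [("A", "B", 410.0), ("A", "C", 400.0)]
        net, report = build_ppi(rows)
        assert report.rescaled_from_0_1000
        assert net.edges == {("A", "B")}

    def test_duplicate_pairs_keep_max_confidence(self):
        net, _ = build_ppi([("A", "B", 0.5), ("B", "A", 0.8)])
        assert net.confidences[("A", "B")] == 0.8

    def test_excluded_symbols_partitioned(self):
        rows = [("A", "B", 0.9), ("A", "C", 0.1)]
        net, report = build_ppi(rows, node_filter={"A", "B", "C", "D"})
        assert report.excluded_no_interaction == ["C"]  # seen, all edges filtered
        assert report.excluded_not_found == ["D"]       # never in the table
        assert net.n_nodes == 2

    def test_empty_result_is_an_error(self):
        with pytest.raises(InputError, match="no PPI edges"):
            build_ppi([("A", "B", 0.1)])

    def test_malformed_row_reports_position(self):
        with pytest.raises(InputError, match="row 1"):
            build_ppi([("A", "B", 0.9), ("A", None, None)])

    def test_raising_cutoff_never_adds_edges(self):
        rng = np.random.default_rng(7)
        rows = [
            (f"N{rng.integers(0, 15)}", f"N{rng.integers(0, 15)}", float(rng.random()))
            for _ in range(200)
        ]
        prev = None
        for cutoff in (0.1, 0.3, 0.5, 0.7):
            try:
                net, _ = build_ppi(rows, score_min=cutoff)
                n_edges = net.n_edges
                degs = {n: sum(1 for e in net.edges if n in e) for n in net.nodes}
            except InputError:
                n_edges, degs = 0, {}
            if prev is not None:
                assert n_edges <= prev[0]
                for n, d in degs.items():
                    assert d <= prev[1].get(n, 0)
            prev = (n_edges, degs)


class TestHubs:
    def test_star_graph(self, star_ppi):
        report = detect_hubs(star_ppi)
        assert report.mean_degree == pytest.approx(1.8)
        assert report.threshold == pytest.approx(3.6)
        assert report.hubs == [("HUB", 9)]

    def test_regular_graph_has_no_hubs(self):
        g = nx.cycle_graph(8)
        conf = {tuple(sorted((f"N{a}", f"N{b}"))): 0.9 for a, b in g.edges()}
        report = detect_hubs(PPINetwork(confidences=conf))
        assert report.hubs == []

    def test_threshold_is_multiplier_times_mean(self, star_ppi):
        report = detect_hubs(star_ppi, multiplier=3.0)
        assert report.threshold == pytest.approx(3.0 * report.mean_degree)
        mean = 2 * star_ppi.n_edges / star_ppi.n_nodes
        assert report.mean_degree == pytest.approx(
            np.mean(list(report.per_node_degree.values()))
        ) == pytest.approx(mean)

    def test_empty_network_rejected(self):
        with pytest.raises(InputError):
            detect_hubs(PPINetwork(confidences={}))

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_under_relabeling(self, seed):
        """Hub detection is a graph-isomorphism invariant."""
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        conf = {tuple(sorted((f"N{a:02d}", f"N{b:02d}"))): 0.9 for a, b in g.edges()}
        base = detect_hubs(PPINetwork(confidences=conf))
        perm = rng.permutation(30)
        relabel = {f"N{i:02d}": f"M{perm[i]:02d}" for i in range(30)}
        conf2 = {
            tuple(sorted((relabel[a], relabel[b]))): c for (a, b), c in conf.items()
        }
        permuted = detect_hubs(PPINetwork(confidences=conf2))
        assert {(relabel[n], d) for n, d in base.hubs} == set(permuted.hubs)
        assert base.threshold == pytest.approx(permuted.threshold)

    def test_handshake_on_random_graphs(self):
        for seed in range(90):
            g = nx.gnp_random_graph(20, 0.2, seed=seed)
            if g.number_of_edges() == 0:
                continue
            conf = {tuple(sorted((f"N{a}", f"N{b}"))): 0.9 for a, b in g.edges()}
            net = PPINetwork(confidences=conf)
            report = detect_hubs(net)
            assert sum(report.per_node_degree.values()) == 2 * net.n_edges


class TestExport:
    def test_sif_one_line_per_edge(self, k23_network, tmp_path):
        path = tmp_path / "net.sif"
        export_network(k23_network, "sif", path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 6
        assert all(line.split("\t")[1] == "ct" for line in lines)

    def test_graphml_round_trip(self, k23_network, tmp_path):
        path = tmp_path / "net.graphml"
        export_network(k23_network, "graphml", path)
        g = nx.read_graphml(path)
        assert set(g.nodes()) == k23_network.compound_nodes | k23_network.target_nodes
        assert {tuple(sorted(e)) for e in g.edges()} == {
            tuple(sorted(e)) for e in k23_network.edges
        }

    def test_byte_stable(self, k23_network, tmp_path):
        p1, p2 = tmp_path / "a.sif", tmp_path / "b.graphml"
        export_network(k23_network, "sif", p1)
        export_network(k23_network, "graphml", p2)
        first = (p1.read_bytes(), p2.read_bytes())
        export_network(k23_network, "sif", p1)
        export_network(k23_network, "graphml", p2)
        assert (p1.read_bytes(), p2.read_bytes()) == first

    def test_ppi_export_carries_confidence(self, star_ppi, tmp_path):
        path = tmp_path / "ppi.graphml"
        export_network(star_ppi, "graphml", path)
        g = nx.read_graphml(path)
        assert all("confidence" in d for _, _, d in g.edges(data=True))

    def test_empty_network_not_written(self, tmp_path):
        with pytest.raises(InputError):
            export_network(PPINetwork(confidences={}), "sif", tmp_path / "x.sif")
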