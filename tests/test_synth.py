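"""Synthetic-data generators: determinism, truth-file fidelity, planted structure."""

import pytest

from phytonet.adme import screen_compounds
from phytonet.enrichment import enrich
from phytonet.errors import SynthSpecError
from phytonet.fishing import filter_interactions, partition_orphans
from phytonet.io import read_gmt, write_gmt
from phytonet.network import build_ppi, detect_hubs
from phytonet.synth import (
    SynthSpec,
    gen_compound_table,
    gen_disease_catalog,
    gen_genesets,
    gen_interactions,
    gen_ppi,
    write_synth_dataset,
)
from phytonet.catalog import intersect_targets, merge_catalogs


class TestCompoundGenerator:
    def test_pass_fraction_near_nominal(self):
        spec = SynthSpec(seed=7, n_compounds=100, frac_pass_ob=0.3, frac_pass_dl=1.0)
        records, truth = gen_compound_table(spec)
        passing, _ = screen_compounds(records)
        assert len(passing) == truth["n_pass_threshold"]
        # binomial(100, 0.3): allow ~4 sd around the mean
        assert 12 <= len(passing) <= 48

    def test_zero_fraction_boundary(self):
        spec = SynthSpec(seed=3, frac_pass_ob=0.0)
        records, truth = gen_compound_table(spec)
        assert truth["n_pass_threshold"] == 0
        assert len(screen_compounds(records)[0]) == 0

    def test_deterministic_given_seed(self):
        spec = SynthSpec(seed=11)
        r1, t1 = gen_compound_table(spec)
        r2, t2 = gen_compound_table(SynthSpec(seed=11))
        assert t1 == t2
        assert [(a.compound_id, a.ob, a.dl) for a in r1] == [
            (b.compound_id, b.ob, b.dl) for b in r2
        ]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(SynthSpecError):
            SynthSpec(frac_pass_ob=1.5)


class TestInteractionGenerator:
    def test_truth_matches_filter_output(self):
        spec = SynthSpec(seed=2)
        compounds, _ = gen_compound_table(spec)
        records, truth = gen_interactions(spec, compounds)
        filtered = filter_interactions(records)
        assert sorted({(r.compound_id, r.target_symbol) for r in filtered}) == truth[
            "retained_edges"
        ]

    def test_orphans_match_truth(self):
        spec = SynthSpec(seed=4)
        compounds, _ = gen_compound_table(spec)
        records, truth = gen_interactions(spec, compounds)
        candidates, _ = screen_compounds(compounds)
        filtered = filter_interactions(records)
        _, orphans = partition_orphans(candidates, filtered)
        assert sorted(c.compound_id for c in orphans) == truth["orphans"]
        assert truth["n_connected"] + len(truth["orphans"]) == truth["n_candidates"]

    def test_zero_density_orphans_everything(self):
        spec = SynthSpec(seed=5, edge_density=0.0, decoy_density=0.0, orphan_frac=0.0)
        compounds, _ = gen_compound_table(spec)
        records, truth = gen_interactions(spec, compounds)
        assert records == []
        assert truth["orphans"] and truth["n_connected"] == 0


class TestDiseaseGenerator:
    def test_intersection_count_is_exact(self):
        spec = SynthSpec(seed=6, overlap_frac=0.5)
        targets = [f"G{i:06d}" for i in range(1, 101)]
        catalogs, truth = gen_disease_catalog(spec, targets)
        merged, _ = merge_catalogs(catalogs)
        common = intersect_targets(targets, merged)
        assert len(common) == truth["n_common"] == 50
        assert common == truth["common"]

    def test_zero_overlap_is_disjoint(self):
        spec = SynthSpec(seed=6, overlap_frac=0.0)
        targets = [f"G{i:06d}" for i in range(1, 51)]
        catalogs, truth = gen_disease_catalog(spec, targets)
        merged, _ = merge_catalogs(catalogs)
        assert truth["n_common"] == 0
        assert not (set(targets) & merged.symbols)

    def test_full_source_redundancy(self):
        spec = SynthSpec(seed=6, disease_shared_frac=1.0)
        catalogs, _ = gen_disease_catalog(spec, [f"G{i:06d}" for i in range(1, 31)])
        assert catalogs[0].symbols == catalogs[1].symbols

    def test_unsatisfiable_overlap_rejected(self):
        spec = SynthSpec(seed=6, n_disease_genes=10, overlap_frac=1.0)
        with pytest.raises(SynthSpecError):
            gen_disease_catalog(spec, [f"G{i:06d}" for i in range(1, 101)])


class TestPPIGenerator:
    @pytest.mark.parametrize("model", ["scale_free", "configuration"])
    def test_planted_hubs_always_detected(self, model):
        nodes = [f"G{i:06d}" for i in range(1, 71)]
        for seed in range(5):
            spec = SynthSpec(seed=seed, ppi_model=model, planted_hub_count=3)
            rows, truth = gen_ppi(spec, nodes)
            net, _ = build_ppi(rows)
            hubs = {n for n, _ in detect_hubs(net).hubs}
            assert set(truth["planted_hubs"]) <= hubs

    def test_too_few_nodes_rejected(self):
        spec = SynthSpec(seed=0, planted_hub_count=3)
        with pytest.raises(SynthSpecError):
            gen_ppi(spec, ["G000001", "G000002", "G000003"])


class TestGenesetGenerator:
    def test_extreme_effect_ranks_first(self):
        query = [f"G{i:06d}" for i in range(1, 41)]
        spec = SynthSpec(seed=9, planted_set_effect=10.0, universe_size=500)
        coll, truth = gen_genesets(spec, query)
        results, _ = enrich(query, coll)
        assert results[0].term_id == truth["planted_term"]

    def test_unachievable_effect_rejected(self):
        query = [f"G{i:06d}" for i in range(1, 401)]
        spec = SynthSpec(seed=9, planted_set_effect=10.0, universe_size=500)
        with pytest.raises(SynthSpecError):
            gen_genesets(spec, query)

    def test_gmt_round_trip(self, tmp_path):
        query = [f"G{i:06d}" for i in range(1, 41)]
        coll, _ = gen_genesets(SynthSpec(seed=1), query)
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert {tid: members for tid, (_, members) in back.sets.items()} == {
            tid: members for tid, (_, members) in coll.sets.items()
        }


def test_dataset_byte_identical_across_runs(tmp_path):
    spec = SynthSpec(seed=13)
    write_synth_dataset(spec, tmp_path / "a")
    write_synth_dataset(SynthSpec(seed=13), tmp_path / "b")
    files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
    assert files_a == sorted(p.name for p in (tmp_path / "b").iterdir())
    for name in files_a:
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes(), name
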