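"""End-to-end bundles, cross-CLD comparison and the command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from cldnet.cld_io import export_graph, export_variable_key
from cldnet.cli import main
from cldnet.report import (AnalysisConfig, analyze, analyze_graph, compare,
                           normalize_name)
from cldnet.synthetic_data import cld_like, er_directed


@pytest.fixture(scope="module")
def cld_files(tmp_path_factory):
    g = cld_like(seed=7)
    d = tmp_path_factory.mktemp("cld7")
    (d / "key.csv").write_text(export_variable_key(g))
    (d / "edges.csv").write_text(export_graph(g, "edge-csv"))
    return d / "key.csv", d / "edges.csv"


class TestAnalyze:
    def test_bundle_is_internally_consistent(self, cld_files):
        key, edges = cld_files
        cfg = AnalysisConfig(seed=1, restarts=5, loops_max_length=3)
        bundle = analyze(key, edges, cfg)
        rep = bundle.global_report
        assert (rep.n_nodes, rep.n_edges, rep.n_isolates) == (114, 209, 1)
        assert rep.modularity == bundle.partition.modularity
        assert len(bundle.centrality) == 114
        assert bundle.loops
        assert bundle.provenance["config"]["seed"] == 1
        assert bundle.provenance["inputs"]["key_sha256"]

    def test_written_outputs_and_idempotence(self, cld_files, tmp_path):
        key, edges = cld_files
        cfg = AnalysisConfig(seed=2, restarts=5)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        analyze(key, edges, cfg, out_dir=out1)
        analyze(key, edges, cfg, out_dir=out2)
        for fname in ("global.json", "global.csv", "centrality.csv",
                      "partition.json", "partition.csv", "provenance.json"):
            assert (out1 / fname).read_bytes() == (out2 / fname).read_bytes()
        rep = json.loads((out1 / "global.json").read_text())
        assert rep["n_nodes"] == 114

    def test_missing_edge_file_is_clean_error(self, cld_files, tmp_path):
        key, _ = cld_files
        from cldnet.cld_io import MissingInputError
        with pytest.raises(MissingInputError):
            analyze(key, tmp_path / "absent.csv", AnalysisConfig())

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text("seed: 9\nrestarts: 3\nvariant: directed\n")
        cfg = AnalysisConfig.from_yaml(cfg_path, restarts=4)
        assert (cfg.seed, cfg.restarts, cfg.variant) == (9, 4, "directed")
        cfg_path.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            AnalysisConfig.from_yaml(cfg_path)


class TestCompare:
    def test_self_comparison(self):
        bundle = analyze_graph(cld_like(seed=4), AnalysisConfig(seed=0, restarts=5))
        rep = compare([bundle, bundle])
        assert rep.n_matched == 114
        numeric = rep.deltas.drop(columns=["cld"]).to_numpy(dtype=float)
        assert np.allclose(numeric, 0.0)
        for rho in rep.rank_correlations.values():
            assert rho == pytest.approx(1.0)

    def test_zero_match_error(self):
        cfgs = AnalysisConfig(seed=0, restarts=2)
        b1 = analyze_graph(er_directed(10, 20, seed=1), cfgs)
        b2 = analyze_graph(er_directed(10, 20, seed=2), cfgs)
        with pytest.raises(ValueError, match="matched"):
            compare([b1, b2])

    def test_unmatched_names_listed_both_sides(self):
        cfg = AnalysisConfig(seed=0, restarts=3)
        b1 = analyze_graph(cld_like(seed=1), cfg)
        b2 = analyze_graph(cld_like(seed=2), cfg)
        # align a subset of names across the maps: comparison runs on those
        g2 = b2.graph
        shared = {v: b1.graph.name(v) for v in list(g2.nodes())[:50]}
        from cldnet.cld_io import CLDGraph, Variable, CausalLink
        renamed = CLDGraph([Variable(v, shared.get(v, g2.name(v))) for v in g2.nodes()],
                           list(g2.edges()))
        b2r = analyze_graph(renamed, cfg)
        rep = compare([b1, b2r])
        assert rep.n_matched == 50
        assert len(rep.unmatched[0]) == 64 and len(rep.unmatched[1]) == 64

    def test_needs_two_bundles(self):
        b = analyze_graph(cld_like(seed=1), AnalysisConfig(seed=0, restarts=2))
        with pytest.raises(ValueError):
            compare([b])


class TestNameNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("Junk-Food  Consumption!", "junk food consumption"),
        ("  Level of\tPhysical Activity ", "level of physical activity"),
        ("CLUB (SIZE)", "club size"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_name(raw) == expected


class TestCli:
    def test_generate_analyze_compare_pipeline(self, tmp_path):
        runner = CliRunner()
        for seed, d in ((1, "g1"), (1, "g2")):
            res = runner.invoke(main, ["generate", "--kind", "cld_like",
                                       "--seed", str(seed), "--name-prefix", "cld",
                                       "-o", str(tmp_path / d)])
            assert res.exit_code == 0, res.output
        for d in ("g1", "g2"):
            res = runner.invoke(main, [
                "analyze", str(tmp_path / d / "key.csv"), str(tmp_path / d / "edges.csv"),
                "-o", str(tmp_path / d / "out"), "--seed", "0", "--restarts", "3",
                "--export", "graphml"])
            assert res.exit_code == 0, res.output
            assert (tmp_path / d / "out" / "graph.graphml").exists()
        res = runner.invoke(main, ["compare", str(tmp_path / "g1" / "out"),
                                   str(tmp_path / "g2" / "out"),
                                   "-o", str(tmp_path / "cmp.json")])
        assert res.exit_code == 0, res.output
        payload = json.loads((tmp_path / "cmp.json").read_text())
        assert payload["n_matched"] == 114

    def test_analyze_missing_file_exit_code(self, tmp_path):
        (tmp_path / "key.csv").write_text("id,name\n1,A\n2,B\n")
        res = CliRunner().invoke(main, ["analyze", str(tmp_path / "key.csv"),
                                        str(tmp_path / "key.csv"), "-o",
                                        str(tmp_path / "out")])
        # a key file used as an edge list is a validation error, not a crash
        assert res.exit_code == 2

    def test_strict_mode_escalates_duplicate_edges(self, tmp_path):
        (tmp_path / "key.csv").write_text("id,name\n1,A\n2,B\n")
        (tmp_path / "edges.csv").write_text("source,target\n1,2\n1,2\n")
        runner = CliRunner()
        ok = runner.invoke(main, ["analyze", str(tmp_path / "key.csv"),
                                  str(tmp_path / "edges.csv"), "-o", str(tmp_path / "o1"),
                                  "--restarts", "1"])
        assert ok.exit_code == 0, ok.output
        strict = runner.invoke(main, ["analyze", str(tmp_path / "key.csv"),
                                      str(tmp_path / "edges.csv"), "-o", str(tmp_path / "o2"),
                                      "--strict", "--restarts", "1"])
        assert strict.exit_code == 2
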