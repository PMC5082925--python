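"""Parsing, validation and export of CLD key / edge-list files."""

import logging
import xml.etree.ElementTree as ET

import pytest
from hypothesis import given, strategies as st

from cldnet.cld_io import (CausalLink, Dialect, EdgeListError, EmptyGraphError,
                           MissingInputError, SelfLoopError, UnknownFormatError,
                           Variable, VariableKeyError, build_graph, export_graph,
                           export_variable_key, read_edge_list, read_variable_key)
from cldnet.synthetic_data import er_directed

from conftest import make_graph


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadVariableKey:
    def test_two_row_file(self, tmp_path):
        p = write(tmp_path, "key.csv", "id,name\n1,Exercise\n2,Diet\n")
        vs = read_variable_key(p)
        assert vs == [Variable(1, "Exercise"), Variable(2, "Diet")]

    def test_order_preserved_and_headerless(self, tmp_path):
        p = write(tmp_path, "key.csv", "5,Eggs\n2,Milk\n9,Bread\n")
        vs = read_variable_key(p, Dialect(header=False))
        assert [v.id for v in vs] == [5, 2, 9]

    @pytest.mark.parametrize("body,err", [
        ("id,name\n1,A\n1,B\n", VariableKeyError),        # duplicate id
        ("id,name\n1,A\n2, a \n", VariableKeyError),      # duplicate normalized name
        ("id,name\nx,A\n", VariableKeyError),             # non-integer id
        ("id,name\n0,A\n", VariableKeyError),             # non-positive id
        ("id,name\n1,\n", VariableKeyError),              # empty name
    ])
    def test_malformed_rows_raise_typed_errors(self, tmp_path, body, err):
        with pytest.raises(err):
            read_variable_key(write(tmp_path, "key.csv", body))

    def test_missing_file(self, tmp_path):
        with pytest.raises(MissingInputError):
            read_variable_key(tmp_path / "nope.csv")

    def test_named_columns(self, tmp_path):
        p = write(tmp_path, "key.csv", "label,vid\nRain,3\n")
        vs = read_variable_key(p, Dialect(id_col="vid", name_col="label"))
        assert vs == [Variable(3, "Rain")]


class TestReadEdgeList:
    def test_basic(self, tmp_path):
        p = write(tmp_path, "e.csv", "source,target\n1,2\n2,3\n")
        assert read_edge_list(p) == [CausalLink(1, 2), CausalLink(2, 3)]

    def test_duplicate_rows_collapse_with_warning(self, tmp_path, caplog):
        p = write(tmp_path, "e.csv", "source,target\n1,2\n1,2\n")
        with caplog.at_level(logging.WARNING, logger="cldnet"):
            links = read_edge_list(p)
        assert links == [CausalLink(1, 2)]
        assert any("duplicate" in r.message for r in caplog.records)

    def test_self_loop_row_rejected_naming_the_row(self, tmp_path):
        p = write(tmp_path, "e.csv", "source,target\n1,2\n3,3\n")
        with pytest.raises(SelfLoopError, match="3"):
            read_edge_list(p)

    def test_non_integer_endpoint(self, tmp_path):
        p = write(tmp_path, "e.csv", "source,target\n1,two\n")
        with pytest.raises(EdgeListError):
            read_edge_list(p)

    def test_polarity_column(self, tmp_path):
        p = write(tmp_path, "e.csv", "source,target,sign\n1,2,+\n2,3,-\n3,4,\n")
        links = read_edge_list(p, polarity_column="sign")
        assert [l.polarity for l in links] == ["positive", "negative", "unknown"]

    def test_polarity_defaults_to_unknown(self, tmp_path):
        p = write(tmp_path, "e.csv", "source,target,sign\n1,2,+\n")
        assert read_edge_list(p)[0].polarity == "unknown"


class TestBuildGraph:
    def test_isolate_retained(self):
        g = build_graph([Variable(i, f"v{i}") for i in (1, 2, 3)], [CausalLink(1, 2)])
        assert (g.n_nodes, g.n_edges) == (3, 1)
        assert g.isolates() == [3]

    def test_unknown_endpoint_added_unlabelled(self, caplog):
        with caplog.at_level(logging.WARNING, logger="cldnet"):
            g = build_graph([Variable(1, "a"), Variable(2, "b")],
                            [CausalLink(1, 999)])
        assert g.name(999) == "unlabelled-999"
        assert any("999" in r.message for r in caplog.records)

    def test_empty_variable_list(self):
        with pytest.raises(EmptyGraphError):
            build_graph([], [])


class TestExport:
    def test_edge_csv_single_row(self):
        g = make_graph(2, [(1, 2)])
        text = export_graph(g, "edge-csv")
        lines = text.strip().splitlines()
        assert lines[0] == "source,target,polarity"
        assert lines[1:] == ["1,2,unknown"]

    def test_graphml_node_count_and_names(self, cld_graph):
        root = ET.fromstring(export_graph(cld_graph, "graphml"))
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        nodes = root.findall(".//g:node", ns)
        edges = root.findall(".//g:edge", ns)
        assert len(nodes) == 114 and len(edges) == 209
        names = [n.find("g:data", ns).text for n in nodes]
        assert all(names)

    def test_dot_contains_all_arcs(self):
        g = make_graph(3, [(1, 2), (2, 3)])
        dot = export_graph(g, "dot")
        assert "n1 -> n2" in dot and "n2 -> n3" in dot

    def test_unknown_format(self):
        with pytest.raises(UnknownFormatError):
            export_graph(make_graph(2, [(1, 2)]), "gexf")


class TestRoundTrip:
    def test_synthetic_graph_round_trips(self, tmp_path):
        g = er_directed(50, 120, seed=11)
        ep = write(tmp_path, "edges.csv", export_graph(g, "edge-csv"))
        kp = write(tmp_path, "key.csv", export_variable_key(g))
        g2 = build_graph(read_variable_key(kp), read_edge_list(ep, polarity_column="polarity"))
        assert set(g2.edges()) == set(g.edges())
        assert g2.names() == g.names()

    @given(seed=st.integers(0, 10_000))
    def test_edge_csv_round_trip_property(self, tmp_path_factory, seed):
        g = er_directed(12, 30, seed=seed)
        tmp = tmp_path_factory.mktemp("rt")
        ep = tmp / "edges.csv"
        ep.write_text(export_graph(g, "edge-csv"))
        links = read_edge_list(ep, polarity_column="polarity")
        assert set(links) == set(g.edges())
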