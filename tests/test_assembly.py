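"""Network assembly: table loading, union merge, seed subnetwork, components."""

import logging

import networkx as nx
import numpy as np
import pytest

from hfnet import assembly
from hfnet.assembly import (
    ComponentDecomposition,
    Interaction,
    SeedSet,
    decompose_components,
    load_interaction_table,
    load_seed_list,
    merge_union,
    normalize_symbol,
    seed_subnetwork,
    write_edge_list,
)

from oracles import count_components_union_find


def write_table(path, rows):
    path.write_text("".join("\t".join(r) + "\n" for r in rows))
    return path


class TestNormalization:
    def test_uppercase_strip(self):
        assert normalize_symbol("  fn1 ") == "FN1"

    def test_idempotent(self):
        for s in ("fn1", " Itgb1 ", "TNF"):
            once = normalize_symbol(s)
            assert normalize_symbol(once) == once

    def test_alias_mapping(self):
        aliases = {"NT-PROBNP": "NPPB"}
        assert normalize_symbol("nt-probnp ", aliases) == "NPPB"


class TestInteraction:
    def test_unordered_equality(self):
        assert Interaction("B", "A") == Interaction("A", "B")

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            Interaction("A", "A")


class TestLoadInteractionTable:
    def test_single_row(self, tmp_path):
        p = write_table(tmp_path / "t.tsv", [("FN1", "ITGB1", "hprd")])
        table = load_interaction_table(p)
        assert table == [Interaction("FN1", "ITGB1", frozenset({"hprd"}))]

    def test_symmetric_rows_dedup_in_merge(self, tmp_path):
        p = write_table(tmp_path / "t.tsv", [("a", "b"), ("b", "a")])
        g = merge_union([load_interaction_table(p)])
        assert g.number_of_edges() == 1

    def test_self_pair_dropped_and_logged(self, tmp_path, caplog):
        p = write_table(tmp_path / "t.tsv", [("a", "a"), ("a", "b")])
        with caplog.at_level(logging.WARNING):
            table = load_interaction_table(p)
        assert len(table) == 1
        assert "1 self-pair" in caplog.text

    def test_header_detected(self, tmp_path):
        p = write_table(tmp_path / "t.tsv",
                        [("protein_a", "protein_b", "source"), ("FN1", "ITGB1", "hprd")])
        assert len(load_interaction_table(p)) == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_interaction_table(tmp_path / "absent.tsv")

    def test_too_few_columns_names_line(self, tmp_path):
        p = (tmp_path / "t.tsv")
        p.write_text("FN1\tITGB1\nlonely\n")
        with pytest.raises(assembly.InteractionTableError, match=":2"):
            load_interaction_table(p)

    def test_empty_symbol_names_line(self, tmp_path):
        p = (tmp_path / "t.tsv")
        p.write_text("FN1\t \t\n")
        with pytest.raises(assembly.InteractionTableError, match=":1"):
            load_interaction_table(p)

    def test_default_source_is_file_stem(self, tmp_path):
        p = write_table(tmp_path / "biogrid.tsv", [("a", "b")])
        assert load_interaction_table(p)[0].sources == frozenset({"biogrid"})


class TestMergeUnion:
    def test_union_semantics_and_source_merge(self):
        t1 = [Interaction("a", "b", frozenset({"hprd"}))]
        t2 = [Interaction("a", "b", frozenset({"mint"}))]
        t3 = [Interaction("b", "c", frozenset({"mint"}))]
        g = merge_union([t1, t2, t3])
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert g["a"]["b"]["sources"] == {"hprd", "mint"}

    def test_triangle_edge_count(self):
        k3 = [Interaction(a, b) for a, b in [("x", "y"), ("y", "z"), ("x", "z")]]
        assert merge_union([k3]).number_of_edges() == 3

    def test_random_tables_union_oracle(self):
        rng = np.random.default_rng(7)
        nodes = [f"P{i}" for i in range(8)]

        def draw(n):
            pairs = set()
            while len(pairs) < n:
                a, b = rng.choice(nodes, size=2, replace=False)
                pairs.add(tuple(sorted((a, b))))
            return pairs

        shared = draw(4)
        t1 = shared | draw(6)
        t2 = shared | draw(6)
        expected = len(t1 | t2)
        g = merge_union([[Interaction(a, b) for a, b in t1],
                         [Interaction(a, b) for a, b in t2]])
        assert g.number_of_edges() == expected

    def test_idempotent(self):
        t = [Interaction("a", "b"), Interaction("b", "c")]
        g1, g2 = merge_union([t]), merge_union([t, t])
        assert nx.utils.graphs_equal(g1, g2)

    def test_empty_union_errors(self):
        with pytest.raises(ValueError):
            merge_union([[]])


class TestSeedSet:
    def test_union_counts(self):
        s = SeedSet.from_iterables(["a", "b", "c"], ["c", "d"])
        assert s.seeds == {"A", "B", "C", "D"}
        assert len(s.seeds) <= len(s.biomarkers) + len(s.candidates)


class TestSeedSubnetwork:
    def test_path_seed_center_both_modes(self):
        g = nx.path_graph(["a", "b", "c"])
        for mode in ("induced", "seed-incident"):
            sub = seed_subnetwork(g, {"b"}, mode=mode)
            assert set(sub.nodes) == {"a", "b", "c"}
            assert sub.number_of_edges() == 2

    def test_triangle_plus_pendant(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        induced = seed_subnetwork(g, {"a"}, mode="induced")
        assert set(induced.nodes) == {"a", "b", "c"}
        assert set(map(frozenset, induced.edges)) == {
            frozenset(p) for p in [("a", "b"), ("a", "c"), ("b", "c")]}
        incident = seed_subnetwork(g, {"a"}, mode="seed-incident")
        assert set(map(frozenset, incident.edges)) == {
            frozenset(p) for p in [("a", "b"), ("a", "c")]}

    def test_isolated_seed_kept_and_flagged(self, caplog):
        g = nx.Graph([("a", "b")])
        g.add_node("z")
        with caplog.at_level(logging.WARNING):
            sub = seed_subnetwork(g, {"z", "a"})
        assert "z" in sub.nodes and sub.degree("z") == 0

    def test_absent_seeds_reported_not_fatal(self, caplog):
        g = nx.Graph([("a", "b")])
        with caplog.at_level(logging.WARNING):
            sub = seed_subnetwork(g, {"a", "missing"})
        assert "missing" in caplog.text.lower()
        assert set(sub.nodes) == {"a", "b"}

    def test_no_seed_present_errors(self):
        with pytest.raises(ValueError):
            seed_subnetwork(nx.Graph([("a", "b")]), {"zz"})

    @pytest.mark.parametrize("seed", range(5))
    def test_incident_edges_subset_of_induced(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(25, 0.15, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        seeds = set(rng.choice(sorted(g.nodes), size=4, replace=False))
        inc = seed_subnetwork(g, seeds, mode="seed-incident")
        ind = seed_subnetwork(g, seeds, mode="induced")
        assert set(map(frozenset, inc.edges)) <= set(map(frozenset, ind.edges))


class TestDecomposeComponents:
    def test_two_triangle_tie_break(self):
        g = nx.Graph([("x", "y"), ("y", "z"), ("x", "z"),
                      ("a", "b"), ("b", "c"), ("a", "c")])
        d = decompose_components(g)
        # equal size and edges: lexicographically smallest member wins
        assert set(d.core.nodes) == {"a", "b", "c"}
        assert len(d.islands) == 1

    def test_k5_plus_isolated_edge(self):
        g = nx.complete_graph(["a", "b", "c", "d", "e"])
        g.add_edge("y", "z")
        d = decompose_components(g)
        assert set(d.core.nodes) == {"a", "b", "c", "d", "e"}
        assert [set(i.nodes) for i in d.islands] == [{"y", "z"}]

    def test_singletons_excluded_from_islands(self):
        g = nx.Graph([("a", "b")])
        g.add_node("s")
        d = decompose_components(g)
        assert d.islands == [] and d.singletons == ["s"]

    @pytest.mark.parametrize("seed", range(8))
    def test_component_count_matches_union_find(self, seed):
        g = nx.gnp_random_graph(50, 0.02, seed=seed)  # sub-critical density
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        d = decompose_components(g)
        found = 1 + len(d.islands) + len(d.singletons)
        assert found == count_components_union_find(list(g.nodes), list(g.edges))

    @pytest.mark.parametrize("seed", range(5))
    def test_node_and_edge_conservation(self, seed):
        g = nx.gnp_random_graph(40, 0.05, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        d = decompose_components(g)
        parts = [d.core] + d.islands
        n_nodes = sum(p.number_of_nodes() for p in parts) + len(d.singletons)
        n_edges = sum(p.number_of_edges() for p in parts)
        assert n_nodes == g.number_of_nodes()
        assert n_edges == g.number_of_edges()

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            decompose_components(nx.Graph())


class TestDeterministicOutput:
    def test_edge_list_byte_identical(self, tmp_path):
        t = [Interaction("b", "a", frozenset({"x"})),
             Interaction("c", "b", frozenset({"y", "x"}))]
        p1, p2 = tmp_path / "e1.tsv", tmp_path / "e2.tsv"
        write_edge_list(merge_union([t]), p1)
        write_edge_list(merge_union([list(reversed(t))]), p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_load_seed_list_comments(tmp_path):
    p = tmp_path / "seeds.txt"
    p.write_text("# biomarkers\nfn1\n itgb1  # adhesion\n\nTNF\n")
    assert load_seed_list(p) == {"FN1", "ITGB1", "TNF"}
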