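"""Interactome loading, edge costs, and weighted betweenness."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathrank.network import (
    PathwayNetwork,
    assign_costs,
    dual_scope_annotate,
    edge_cost,
    extract_subnetwork,
    load_interactome,
    rank_by_betweenness,
    weighted_betweenness,
)
from pathrank.preprocess import DomainError, InputError

from conftest import brute_force_betweenness


def de_frame(p_adj_of, logfc=1.0):
    genes = sorted(p_adj_of)
    return pd.DataFrame(
        {
            "logfc": [logfc] * len(genes),
            "p_adj": [p_adj_of[g] for g in genes],
            "rank": np.arange(1, len(genes) + 1),
        },
        index=pd.Index(genes, name="gene"),
    )


def unit_graph(edges):
    g = nx.Graph()
    g.add_edges_from((u, v, {"cost": 1.0}) for u, v in edges)
    return g


class TestLoadInteractome:
    def write(self, tmp_path, rows):
        path = tmp_path / "string.tsv"
        path.write_text("node1\tnode2\tcombined_score\n" + "".join(r + "\n" for r in rows))
        return path

    def test_cutoff_filters_edges(self, tmp_path):
        path = self.write(tmp_path, ["a\tb\t400", "b\tc\t700", "c\td\t900"])
        assert load_interactome(path, score_cutoff=700).number_of_edges() == 2
        assert load_interactome(path, score_cutoff=0).number_of_edges() == 3

    def test_self_loop_dropped(self, tmp_path):
        path = self.write(tmp_path, ["a\ta\t900", "a\tb\t900"])
        g = load_interactome(path, score_cutoff=0)
        assert list(g.edges) == [("a", "b")]

    def test_duplicate_edge_keeps_max_score(self, tmp_path):
        path = self.write(tmp_path, ["a\tb\t500", "b\ta\t800"])
        g = load_interactome(path, score_cutoff=0)
        assert g.edges["a", "b"]["combined_score"] == 800

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = self.write(tmp_path, ["a\tb\t500", "broken"])
        with pytest.raises(InputError, match=":3"):
            load_interactome(path)

    def test_case_insensitive_matching(self, tmp_path):
        path = self.write(tmp_path, ["Vegfa\tSrc\t900"])
        g = load_interactome(path, score_cutoff=0, case_insensitive=True)
        assert set(g.nodes) == {"VEGFA", "SRC"}


class TestExtractSubnetwork:
    def test_induced_edges_only(self):
        g = unit_graph([("a", "b"), ("b", "c"), ("c", "d")])
        pn = extract_subnetwork(g, {"a", "b", "c"}, "s")
        assert set(pn.graph.edges) == {("a", "b"), ("b", "c")}

    def test_disjoint_members_yield_empty_network(self):
        g = unit_graph([("a", "b")])
        pn = extract_subnetwork(g, {"x", "y"}, "s")
        assert pn.graph.number_of_nodes() == 0

    def test_all_members_reproduce_interactome(self):
        g = unit_graph([("a", "b"), ("b", "c")])
        pn = extract_subnetwork(g, {"a", "b", "c"}, "s")
        assert nx.utils.graphs_equal(pn.graph, g)

    def test_isolated_member_kept_as_degree_zero(self):
        g = unit_graph([("a", "b"), ("c", "d")])
        pn = extract_subnetwork(g, {"a", "b", "c"}, "s")
        assert pn.graph.degree["c"] == 0


class TestEdgeCost:
    def test_analytic_example(self):
        log_gm, cost = edge_cost(0.01, 0.0001)
        assert log_gm == pytest.approx(-3.0)
        assert cost == pytest.approx(0.001)

    def test_unit_pvalues(self):
        log_gm, cost = edge_cost(1.0, 1.0)
        assert log_gm == 0.0 and cost == 1.0

    def test_symmetry_both_transforms(self):
        assert edge_cost(0.03, 0.4) == edge_cost(0.4, 0.03)
        assert edge_cost(0.03, 0.4, "shifted_log", min_log_gm=-5.0) == edge_cost(
            0.4, 0.03, "shifted_log", min_log_gm=-5.0
        )

    def test_monotone_in_significance(self):
        # lowering an endpoint p never increases the cost
        for transform, kwargs in [("gm", {}), ("shifted_log", {"min_log_gm": -10.0})]:
            costs = [
                edge_cost(p, 0.2, transform, **kwargs)[1]
                for p in (1.0, 0.5, 0.1, 0.01, 1e-6)
            ]
            assert all(a >= b for a, b in zip(costs, costs[1:]))

    def test_rejects_out_of_domain(self):
        with pytest.raises(DomainError):
            edge_cost(0.0, 0.5)
        with pytest.raises(DomainError):
            edge_cost(0.5, 1.5)


class TestWeightedBetweenness:
    def test_path_graph_center(self):
        g = unit_graph([("a", "b"), ("b", "c")])
        node_bt, edge_bt = weighted_betweenness(g)
        assert node_bt == {"a": 0.0, "b": 1.0, "c": 0.0}
        assert edge_bt[("a", "b")] == 2.0  # pairs (a,b) and (a,c)

    def test_star_center_counts_leaf_pairs(self):
        g = unit_graph([("hub", leaf) for leaf in "abcd"])
        node_bt, _ = weighted_betweenness(g)
        assert node_bt["hub"] == 6.0  # C(4,2)

    def test_four_cycle_splits_pairs(self):
        g = unit_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        node_bt, _ = weighted_betweenness(g)
        assert all(v == pytest.approx(0.5) for v in node_bt.values())

    def test_disconnected_pairs_contribute_nothing(self):
        g = unit_graph([("a", "b"), ("b", "c")])
        g.add_node("z")
        node_bt, _ = weighted_betweenness(g)
        assert node_bt["z"] == 0.0 and node_bt["b"] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=seed)
        for u, v in g.edges:
            g.edges[u, v]["cost"] = float(rng.uniform(0.1, 2.0))
        node_bt, edge_bt = weighted_betweenness(g)
        node_ref, edge_ref = brute_force_betweenness(g)
        for v in g.nodes:
            assert node_bt[v] == pytest.approx(node_ref[v], abs=1e-9)
        for e in edge_ref:
            assert edge_bt[e] == pytest.approx(edge_ref[e], abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_unit_costs_match_networkx_unweighted(self, seed):
        g = nx.gnp_random_graph(15, 0.25, seed=seed)
        nx.set_edge_attributes(g, 1.0, "cost")
        node_bt, edge_bt = weighted_betweenness(g)
        node_ref = nx.betweenness_centrality(g, normalized=False)
        edge_ref = nx.edge_betweenness_centrality(g, normalized=False)
        for v in g.nodes:
            assert node_bt[v] == pytest.approx(node_ref[v], abs=1e-9)
        for e, val in edge_ref.items():
            assert edge_bt[tuple(sorted(e))] == pytest.approx(val, abs=1e-9)

    def test_nonpositive_cost_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", cost=0.0)
        with pytest.raises(DomainError):
            weighted_betweenness(g)

    def test_significant_corridor_attracts_paths(self):
        # two corridors between the same endpoints; the significant one
        # carries all the betweenness
        g = nx.Graph()
        corridor1 = ["s", "m1", "m2", "t"]
        corridor2 = ["s", "n1", "n2", "t"]
        g.add_edges_from(zip(corridor1, corridor1[1:]))
        g.add_edges_from(zip(corridor2, corridor2[1:]))
        p_adj = {"s": 0.5, "t": 0.5, "m1": 0.001, "m2": 0.001, "n1": 0.9, "n2": 0.9}
        assign_costs(g, de_frame(p_adj))
        node_bt, _ = weighted_betweenness(g)
        assert min(node_bt["m1"], node_bt["m2"]) > max(node_bt["n1"], node_bt["n2"])


class TestDualScopeAnnotate:
    def build(self):
        g = nx.Graph()
        g.add_edges_from(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "e")],
            combined_score=500,
        )
        de = de_frame({n: 0.1 for n in "abcde"})
        return g, de

    def test_whole_interactome_pathway_scopes_coincide(self):
        g, de = self.build()
        pn = extract_subnetwork(g, set(g.nodes), "all")
        dual_scope_annotate(g, [pn], de)
        for node in pn.graph.nodes:
            assert pn.graph.nodes[node]["betweenness_pathway"] == pytest.approx(
                pn.graph.nodes[node]["betweenness_global"]
            )

    def test_degree_zero_node_has_zero_both_scopes(self):
        g, de = self.build()
        g.add_node("x")
        de = de_frame({**{n: 0.1 for n in "abcde"}, "x": 0.1})
        pn = extract_subnetwork(g, {"a", "x"}, "s")
        dual_scope_annotate(g, [pn], de)
        assert pn.graph.nodes["x"]["betweenness_pathway"] == 0.0
        assert pn.graph.nodes["x"]["betweenness_global"] == 0.0

    def test_pathway_betweenness_can_exceed_global(self):
        # b bridges a-c inside the pathway, but the full graph offers a
        # cheaper detour around b, so pathway scope > global scope
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "d"), ("d", "c")])
        p_adj = {"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.0001}
        de = de_frame(p_adj)
        pn = extract_subnetwork(g, {"a", "b", "c"}, "s")
        dual_scope_annotate(g, [pn], de)
        assert (
            pn.graph.nodes["b"]["betweenness_pathway"]
            > pn.graph.nodes["b"]["betweenness_global"]
        )

    def test_gene_missing_from_de_table_gets_unit_p(self):
        g, de = self.build()
        g.add_edge("a", "zz", combined_score=500)
        pn = extract_subnetwork(g, set(g.nodes), "s")
        dual_scope_annotate(g, [pn], de)
        assert pn.graph.nodes["zz"]["p_adj"] == 1.0


class TestRankByBetweenness:
    def test_star_center_first(self):
        g = unit_graph([("hub", leaf) for leaf in "abcd"])
        de = de_frame({n: 0.5 for n in g.nodes})
        pn = extract_subnetwork(g, set(g.nodes), "s")
        dual_scope_annotate(g, [pn], de)
        assert rank_by_betweenness(pn)[0] == "hub"

    def test_all_isolated_orders_by_p_then_id(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y", "z"])
        pn = PathwayNetwork("s", g)
        pn.graph.nodes["x"].update(p_adj=0.5, betweenness_pathway=0.0)
        pn.graph.nodes["y"].update(p_adj=0.1, betweenness_pathway=0.0)
        pn.graph.nodes["z"].update(p_adj=0.5, betweenness_pathway=0.0)
        assert rank_by_betweenness(pn) == ["y", "x", "z"]

    def test_output_is_permutation_of_nodes(self):
        g = unit_graph([("a", "b"), ("b", "c")])
        de = de_frame({n: 0.5 for n in g.nodes})
        pn = extract_subnetwork(g, set(g.nodes), "s")
        dual_scope_annotate(g, [pn], de)
        assert sorted(rank_by_betweenness(pn)) == sorted(g.nodes)
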