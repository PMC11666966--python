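"""Hub metrics against closed forms and independent oracles."""

from __future__ import annotations

import random
from itertools import combinations

import pytest

from conftest import graph_from_edges, make_edge, random_graph, to_networkx
from netpharm.ppi_centrality import (
    CliqueBudgetExceeded,
    betweenness_centrality,
    build_graph,
    central_intersection,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    mcc,
    median_core_screen,
    mnc,
    top_k,
)
from netpharm.reference import HUB_METRIC_FILES, load_hub_top10
from netpharm.target_assembly import TargetSet


def star(leaves=4):
    return graph_from_edges([("hub", f"L{i}") for i in range(leaves)])


def path3():
    return graph_from_edges([("A", "B"), ("B", "C")])


def complete(n):
    nodes = [f"K{i}" for i in range(n)]
    return graph_from_edges(list(combinations(nodes, 2)))


class TestBuildGraph:
    def test_required_nodes_become_isolated(self):
        g = build_graph([make_edge("A", "B")], TargetSet("req", frozenset("ABC")))
        assert g.nodes == {"A", "B", "C"}
        assert g.isolated_nodes() == {"C"}

    def test_all_isolated_when_no_edges(self):
        g = build_graph([], TargetSet("req", frozenset("ABCDE")))
        assert g.n_nodes == 5 and g.n_edges == 0

    def test_duplicate_edges_keep_max_score(self):
        g = build_graph([make_edge("A", "B", 0.5), make_edge("B", "A", 0.8)])
        assert g.edges() == [("A", "B", 0.8)]


class TestClosedForms:
    def test_degree(self):
        g = star(5)
        dc = degree_centrality(g)
        assert dc["hub"] == 5 and dc["L0"] == 1
        dc_path = degree_centrality(path3())
        assert dc_path == {"A": 1, "B": 2, "C": 1}

    def test_betweenness_path_star_cycle(self):
        assert betweenness_centrality(path3())["B"] == pytest.approx(1.0)
        assert betweenness_centrality(star(4))["hub"] == pytest.approx(6.0)  # C(4,2)
        cycle = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        bc = betweenness_centrality(cycle)
        assert all(v == pytest.approx(0.5) for v in bc.values())

    def test_closeness_variants(self):
        cc = closeness_centrality(path3())
        assert cc["B"] == pytest.approx(1.0)
        assert cc["A"] == pytest.approx(2 / 3)
        g = graph_from_edges([], extra_nodes=["lonely"])
        assert closeness_centrality(g)["lonely"] == 0.0
        assert all(v == pytest.approx(1.0) for v in closeness_centrality(complete(5)).values())

    def test_mcc_cliques_and_paths(self):
        assert set(mcc(complete(3)).values()) == {2}  # 2!
        assert set(mcc(complete(4)).values()) == {6}  # 3!
        scores = mcc(path3())
        assert scores["B"] == 2  # two maximal 2-cliques
        assert scores == degree_centrality(path3())  # no adjacent neighbors

    def test_mnc_neighborhood_components(self):
        assert mnc(star(4))["hub"] == 1  # leaves pairwise non-adjacent
        assert set(mnc(complete(4)).values()) == {3}
        # node X with two neighbor cliques of sizes 3 and 2
        edges = [("X", v) for v in "ABCDE"]
        edges += [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E")]
        assert mnc(graph_from_edges(edges))["X"] == 3

    def test_isolated_node_scores_zero_everywhere(self):
        g = graph_from_edges([("A", "B")], extra_nodes=["Z"])
        table = centrality_table(g).set_index("node")
        assert table.loc["Z"].tolist() == [0, 0, 0, 0, 0]


class TestOracleEquivalence:
    """Cross-checks against networkx and brute-force enumeration."""

    @pytest.mark.parametrize("trial", range(40))
    def test_random_graphs_match_oracles(self, trial):
        import networkx as nx

        from tests_oracles import brute_mcc, brute_mnc

        rng = random.Random(1000 + trial)
        g = random_graph(rng.randint(2, 12), rng.uniform(0.1, 0.9), rng)
        nxg = to_networkx(g)
        expected_bc = nx.betweenness_centrality(nxg, normalized=False)
        actual_bc = betweenness_centrality(g)
        for v in g.nodes:
            assert actual_bc[v] == pytest.approx(expected_bc[v], abs=1e-9)
        assert mcc(g) == brute_mcc(g)
        assert mnc(g) == brute_mnc(g)

    @pytest.mark.parametrize("trial", range(10))
    def test_handshake_and_relabel_invariance(self, trial):
        rng = random.Random(2000 + trial)
        g = random_graph(rng.randint(2, 15), rng.uniform(0.1, 0.6), rng)
        assert sum(degree_centrality(g).values()) == 2 * g.n_edges
        # permute labels: every metric must permute accordingly
        nodes = sorted(g.nodes)
        mapping = dict(zip(nodes, rng.sample(nodes, len(nodes))))
        h = graph_from_edges(
            [(mapping[a], mapping[b]) for a, b, _ in g.edges()],
            extra_nodes=[mapping[v] for v in g.isolated_nodes()],
        )
        for metric in (degree_centrality, mnc, mcc):
            orig, perm = metric(g), metric(h)
            assert all(perm[mapping[v]] == orig[v] for v in g.nodes)

    def test_clique_budget_raises(self):
        with pytest.raises(CliqueBudgetExceeded):
            mcc(complete(6), clique_budget=0)


class TestMedianCoreScreen:
    def test_worked_example_core_and_medians(self, core_screen_fixture):
        result = median_core_screen(core_screen_fixture)
        assert result.core == {"A"}
        assert result.medians["dc"] == 2
        assert result.medians["bc"] == 0
        assert result.medians["cc"] == pytest.approx(4 / 7)

    def test_vertex_transitive_graph_has_empty_core(self):
        assert median_core_screen(complete(6)).core == frozenset()

    def test_empty_graph_is_error(self):
        from netpharm.ppi_centrality import PPIGraph

        with pytest.raises(ValueError):
            median_core_screen(PPIGraph())

    def test_core_contains_planted_hubs(self):
        from netpharm.synthetic_data import SynthConfig, gen_ppi_with_hubs

        for seed in range(5):
            cfg = SynthConfig(seed=seed, n_genes=120, n_hubs=4, n_unmapped=0)
            edges, hubs, _ = gen_ppi_with_hubs(cfg)
            g = build_graph([e for e in edges if e.score >= 0.4])
            assert set(hubs) <= median_core_screen(g).core


class TestTopKAndIntersection:
    def test_boundary_tie_flag(self):
        import pandas as pd

        table = pd.DataFrame({"node": list("ABCD"), "dc": [3, 2, 2, 1],
                              "bc": 0.0, "cc": 0.0, "mcc": 0, "mnc": 0})
        result = top_k(table, "dc", 2)
        assert result.members == ("A", "B") and result.boundary_tie

    def test_full_ranking_and_unknown_metric(self, core_screen_fixture):
        table = centrality_table(core_screen_fixture)
        assert len(top_k(table, "dc", 5).members) == 5
        with pytest.raises(ValueError):
            top_k(table, "pagerank", 2)
        with pytest.raises(ValueError):
            top_k(table, "dc", 6)

    def test_published_hub_lists_intersect_to_six_central_targets(self):
        lists = {m: sorted(load_hub_top10(m).genes) for m in HUB_METRIC_FILES}
        assert central_intersection(lists) == {"IL6", "AKT1", "JUN", "CASP3", "TNF", "TP53"}

    def test_identical_and_disjoint_lists(self):
        assert central_intersection({"a": ["X", "Y"], "b": ["X", "Y"]}) == {"X", "Y"}
        assert central_intersection({"a": ["X"], "b": ["Y"]}) == frozenset()
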