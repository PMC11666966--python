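"""Shared fixtures and graph helpers for the test suite."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from netpharm.formats_io import EdgeRecord
from netpharm.ppi_centrality import PPIGraph

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def graph_from_edges(edges, extra_nodes=()) -> PPIGraph:
    """Build a PPIGraph from (a, b) pairs plus optional isolated nodes."""
    g = PPIGraph()
    for a, b in edges:
        g.add_edge(a, b)
    for v in extra_nodes:
        g.add_node(v)
    return g


def random_graph(n: int, p: float, rng: random.Random) -> PPIGraph:
    """Erdos-Renyi graph over string node labels n01..; may have isolated nodes."""
    g = PPIGraph()
    nodes = [f"n{i:02d}" for i in range(n)]
    for v in nodes:
        g.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g


def to_networkx(g: PPIGraph):
    import networkx as nx

    nxg = nx.Graph()
    nxg.add_nodes_from(g.nodes)
    nxg.add_edges_from((a, b) for a, b, _ in g.edges())
    return nxg


@pytest.fixture
def core_screen_fixture() -> PPIGraph:
    """Triangle A-B-C with pendant D on A and pendant E on D.

    Hand-computed metrics: dc = {A:3, B:2, C:2, D:2, E:1};
    bc = {A:4, D:3, others 0}; cc = {A:4/5, D:2/3, B=C:4/7, E:4/9}.
    """
    return graph_from_edges([("A", "B"), ("A", "C"), ("B", "C"), ("A", "D"), ("D", "E")])


def make_edge(a: str, b: str, score: float = 0.9) -> EdgeRecord:
    return EdgeRecord(a, b, score)
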