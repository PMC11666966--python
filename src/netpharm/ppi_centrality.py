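"""Native PPI hub metrics and the two-stage target screen.

The protein-protein interaction graph is an undirected simple graph over
gene symbols.  Five node metrics are computed:

* DC — degree (neighbor count);
* BC — betweenness, counted over unordered node pairs excluding the
  endpoints, unnormalized (the CytoNCA convention; conventions differ by a
  factor of two, so this is stated explicitly);
* CC — closeness in the reachable-set variant, r(v) / sum of distances to
  reachable nodes, which equals (n-1)/sum(d) on a connected graph and
  scores isolated nodes 0;
* MCC — maximal clique centrality: the sum of (|C| - 1)! over the maximal
  cliques C of size >= 2 containing the node;
* MNC — maximum neighborhood component: the size of the largest connected
  component of the subgraph induced by the node's neighbors.

Two screening stages are built on these: a "core" screen keeping nodes
strictly above the graph-wide median of DC, BC and CC simultaneously, and a
"central" screen intersecting the top-k lists of several metrics.

All metrics are computed on the unweighted graph; confidence scores are
used only when the edge list is filtered upstream.
"""

from __future__ import annotations

import statistics
from collections import deque
from dataclasses import dataclass, field
from math import factorial
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .target_assembly import TargetSet

__all__ = [
    "PPIGraph",
    "CliqueBudgetExceeded",
    "CoreScreenResult",
    "TopList",
    "build_graph",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "mcc",
    "mnc",
    "centrality_table",
    "median_core_screen",
    "top_k",
    "central_intersection",
]

METRICS = ("dc", "bc", "cc", "mcc", "mnc")


class CliqueBudgetExceeded(RuntimeError):
    """Raised when maximal-clique enumeration exceeds its safety budget."""


class PPIGraph:
    """Undirected simple graph over gene symbols, optionally score-annotated."""

    def __init__(self) -> None:
        self._adj: dict[str, set[str]] = {}
        self._scores: dict[frozenset[str], float] = {}

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self._adj.setdefault(node, set())

    def add_edge(self, a: str, b: str, score: float = 1.0) -> None:
        if a == b:
            return  # self-loops are never represented
        self.add_node(a)
        self.add_node(b)
        self._adj[a].add(b)
        self._adj[b].add(a)
        key = frozenset((a, b))
        self._scores[key] = max(score, self._scores.get(key, 0.0))

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def neighbors(self, node: str) -> set[str]:
        return self._adj[node]

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, ())

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for key, score in self._scores.items():
            a, b = sorted(key)
            out.append((a, b, score))
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return len(self._scores)

    def isolated_nodes(self) -> set[str]:
        return {v for v, nbrs in self._adj.items() if not nbrs}


def build_graph(edges: Iterable, required_nodes: Optional[TargetSet] = None) -> PPIGraph:
    """Assemble the PPI graph from (already score-filtered) edge records.

    ``required_nodes`` (e.g. the candidate target list) are added even when
    no retained interaction touches them, so the gap between the target-set
    size and the connected-node count stays visible.
    """
    g = PPIGraph()
    for e in edges:
        g.add_edge(e.node_a, e.node_b, e.score)
    if required_nodes is not None:
        for node in required_nodes.genes:
            g.add_node(node)
    return g


def degree_centrality(g: PPIGraph) -> dict[str, int]:
    return {v: g.degree(v) for v in g.nodes}


def betweenness_centrality(g: PPIGraph) -> dict[str, float]:
    """Brandes' algorithm, unweighted, unnormalized, unordered pairs.

    BC(v) = sum over pairs {s, t} with s != v != t of sigma_st(v)/sigma_st,
    where sigma counts shortest paths.
    """
    bc = dict.fromkeys(g.nodes, 0.0)
    for s in g.nodes:
        stack: list[str] = []
        preds: dict[str, list[str]] = {}
        sigma: dict[str, int] = {s: 1}
        dist: dict[str, int] = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            dv = dist[v]
            for w in g.neighbors(v):
                if w not in dist:
                    dist[w] = dv + 1
                    sigma[w] = 0
                    preds[w] = []
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(stack, 0.0)
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds.get(w, ()):
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: b / 2.0 for v, b in bc.items()}


def _bfs_distances(g: PPIGraph, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in g.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def closeness_centrality(g: PPIGraph) -> dict[str, float]:
    """Reachable-set closeness: r(v) / sum of distances to reachable nodes."""
    cc: dict[str, float] = {}
    for v in g.nodes:
        dist = _bfs_distances(g, v)
        total = sum(dist.values())
        reachable = len(dist) - 1
        cc[v] = reachable / total if total > 0 else 0.0
    return cc


def _maximal_cliques(g: PPIGraph, budget: int) -> list[frozenset[str]]:
    """Bron-Kerbosch with pivoting; returns maximal cliques of size >= 2."""
    adj = {v: g.neighbors(v) for v in g.nodes}
    cliques: list[frozenset[str]] = []

    def expand(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            if len(r) >= 2:
                if len(cliques) >= budget:
                    raise CliqueBudgetExceeded(
                        f"more than {budget} maximal cliques; raise the budget "
                        "explicitly if the graph is genuinely this dense"
                    )
                cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda u: len(adj[u] & p))
        for v in list(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(g.nodes), set())
    return cliques


def mcc(g: PPIGraph, clique_budget: int = 2_000_000) -> dict[str, int]:
    """Maximal clique centrality: sum of (|C|-1)! over maximal cliques with v.

    Singleton "cliques" are excluded, so an isolated node scores 0, and a
    node whose neighbors are pairwise non-adjacent scores its degree (each
    incident edge is a maximal 2-clique contributing 1! = 1).
    """
    scores = dict.fromkeys(g.nodes, 0)
    for clique in _maximal_cliques(g, clique_budget):
        contrib = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def mnc(g: PPIGraph) -> dict[str, int]:
    """Size of the largest connected component of each node's neighborhood."""
    out: dict[str, int] = {}
    for v in g.nodes:
        nbrs = g.neighbors(v)
        if not nbrs:
            out[v] = 0
            continue
        unvisited = set(nbrs)
        best = 0
        while unvisited:
            seed = unvisited.pop()
            size = 1
            queue = deque([seed])
            while queue:
                u = queue.popleft()
                for w in g.neighbors(u) & unvisited:
                    unvisited.remove(w)
                    size += 1
                    queue.append(w)
            best = max(best, size)
        out[v] = best
    return out


def centrality_table(g: PPIGraph, clique_budget: int = 2_000_000) -> pd.DataFrame:
    """All five metrics for every node, as a DataFrame sorted by symbol.

    Columns: node, dc, bc, cc, mcc, mnc.
    """
    dc = degree_centrality(g)
    bc = betweenness_centrality(g)
    cc = closeness_centrality(g)
    mcc_ = mcc(g, clique_budget)
    mnc_ = mnc(g)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "node": nodes,
            "dc": [dc[v] for v in nodes],
            "bc": [bc[v] for v in nodes],
            "cc": [cc[v] for v in nodes],
            "mcc": [mcc_[v] for v in nodes],
            "mnc": [mnc_[v] for v in nodes],
        }
    )


@dataclass(frozen=True)
class CoreScreenResult:
    core: frozenset[str]
    medians: dict[str, float] = field(default_factory=dict)


def median_core_screen(g: PPIGraph, table: Optional[pd.DataFrame] = None) -> CoreScreenResult:
    """Keep nodes strictly above the median of DC, BC and CC simultaneously.

    Medians are taken over every node of the graph, isolated nodes
    included.  The inequality is strict, so a graph where a metric is
    constant (e.g. any vertex-transitive graph) yields an empty core.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot screen an empty graph")
    if table is None:
        table = centrality_table(g)
    missing = g.nodes - set(table["node"])
    if missing:
        raise ValueError(f"centrality table does not cover nodes: {sorted(missing)[:5]}")
    medians = {m: float(statistics.median(table[m])) for m in ("dc", "bc", "cc")}
    mask = (
        (table["dc"] > medians["dc"])
        & (table["bc"] > medians["bc"])
        & (table["cc"] > medians["cc"])
    )
    core = frozenset(table.loc[mask, "node"])
    return CoreScreenResult(core, medians)


@dataclass(frozen=True)
class TopList:
    """Top-k ranking under one metric, with a flag for a tie at the boundary."""

    metric: str
    members: tuple[str, ...]
    boundary_tie: bool


def top_k(table: pd.DataFrame, metric: str, k: int = 10) -> TopList:
    """Top-k nodes by a metric, descending, ties broken by symbol.

    ``boundary_tie`` is set when rank k and rank k+1 share a value — the
    point where an arbitrary tie-break could change hub membership.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the node count {len(table)}")
    ranked = table.sort_values([metric, "node"], ascending=[False, True])
    values = ranked[metric].tolist()
    members = tuple(ranked["node"].iloc[:k])
    boundary_tie = k < len(table) and values[k - 1] == values[k] if k > 0 else False
    return TopList(metric, members, boundary_tie)


def central_intersection(top_lists: Mapping[str, Sequence[str]]) -> frozenset[str]:
    """Intersection of the members of several top-k hub lists."""
    if len(top_lists) < 2:
        raise ValueError("central_intersection needs at least two lists")
    iterator = iter(top_lists.values())
    result = set(next(iterator))
    for lst in iterator:
        result &= set(lst)
    return frozenset(result)
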