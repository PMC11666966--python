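"""Independent brute-force oracles for the hub metrics.

Deliberately naive: MCC by enumerating every vertex subset and checking
clique-ness and maximality directly; MNC via networkx component labeling
of each neighborhood.  Only usable on small graphs.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

from conftest import to_networkx


def brute_mcc(g):
    nodes = sorted(g.nodes)
    scores = dict.fromkeys(nodes, 0)
    for r in range(2, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if not all(g.has_edge(a, b) for a, b in combinations(subset, 2)):
                continue
            inside = set(subset)
            if any(
                all(g.has_edge(v, u) for u in subset) for v in set(nodes) - inside
            ):
                continue  # extendable, not maximal
            contrib = factorial(r - 1)
            for v in subset:
                scores[v] += contrib
    return scores


def brute_mnc(g):
    import networkx as nx

    nxg = to_networkx(g)
    out = {}
    for v in g.nodes:
        sub = nxg.subgraph(nxg.neighbors(v))
        out[v] = max((len(c) for c in nx.connected_components(sub)), default=0)
    return out
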