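"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive shortest-path enumeration,
explicit triangle scans and exact rational arithmetic.  These routines share
no code path with the package.
"""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def brute_betweenness(g: nx.Graph) -> dict:
    """Unnormalised betweenness by enumerating every shortest path."""
    bc = {v: 0.0 for v in g}
    nodes = list(g)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for v in g:
                if v in (s, t):
                    continue
                on = sum(1 for p in paths if v in p)
                # each unordered pair counted once (undirected convention)
                bc[v] += on / len(paths)
    return bc


def brute_closeness(g: nx.Graph) -> dict:
    """Wasserman–Faust component-scaled closeness from explicit distances."""
    n_total = g.number_of_nodes()
    cc = {}
    for v in g:
        comp = nx.node_connected_component(g, v)
        dists = nx.single_source_shortest_path_length(g, v)
        total = sum(d for u, d in dists.items() if u in comp)
        n_c = len(comp)
        if total > 0 and n_total > 1:
            cc[v] = ((n_c - 1) / total) * ((n_c - 1) / (n_total - 1))
        else:
            cc[v] = 0.0
    return cc


def brute_ecc(g: nx.Graph, u, v) -> float:
    """Edge clustering coefficient by scanning every possible third vertex."""
    triangles = sum(1 for w in g if w not in (u, v) and g.has_edge(u, w) and g.has_edge(v, w))
    denom = min(g.degree(u) - 1, g.degree(v) - 1)
    return triangles / denom if denom > 0 else 0.0


def brute_nc(g: nx.Graph) -> dict:
    return {v: sum(brute_ecc(g, v, u) for u in g[v]) for v in g}


def brute_lac(g: nx.Graph) -> dict:
    """Mean degree of each node's neighbours in the neighbour-induced subgraph."""
    lac = {}
    for v in g:
        nbrs = set(g[v])
        if not nbrs:
            lac[v] = 0.0
            continue
        total = sum(
            sum(1 for w in nbrs if w != u and g.has_edge(u, w)) for u in nbrs
        )
        lac[v] = total / len(nbrs)
    return lac


def exact_hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational via combinatorial enumeration."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))


def random_graph(rng: np.random.Generator, max_nodes: int = 8) -> nx.Graph:
    """Small random graph (possibly disconnected) for oracle comparisons."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.9))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
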