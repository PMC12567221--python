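"""PPI edge filtering, six-metric centralities and iterative median hub screening.

A protein–protein interaction network (undirected, simple, edge confidence in
[0, 1]) is first thresholded on confidence (STRING convention, default 0.700),
then repeatedly reduced: each round computes six topological centralities on
the current subnetwork —

* DC  — degree centrality, ``|N(v)|``
* BC  — betweenness (unnormalised pair counts), ``sum sigma_st(v)/sigma_st``
* CC  — closeness within v's connected component, ``(n_c - 1)/sum d(v, u)``
* EC  — eigenvector centrality: nonnegative principal eigenvector of the
  adjacency matrix, unit 2-norm
* NC  — sum over incident edges of the edge clustering coefficient
  ``ECC(u, v) = triangles(u, v) / min(deg u - 1, deg v - 1)`` (0 when the
  denominator is 0)
* LAC — local average connectivity: mean degree of v's neighbours inside the
  subgraph induced by those neighbours

— and keeps the nodes whose six values are all at or above the per-metric
median.  Survivors induce the next round's subnetwork.  Nodes surviving every
round are the hub targets.  Edge scores play no role after the confidence
filter: the centralities are purely topological.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .targets import CompoundRecord, TargetSet

__all__ = [
    "filter_edges",
    "centralities",
    "median_screen",
    "ScreeningRound",
    "ScreeningTrace",
    "build_compound_target_network",
    "read_string_edges",
    "read_sif",
    "write_sif",
    "read_graphml",
    "write_graphml",
]

CENTRALITY_COLUMNS = ["dc", "bc", "cc", "ec", "nc", "lac"]


def _check_simple(network: nx.Graph) -> None:
    if network.is_directed() or network.is_multigraph():
        raise ValueError("network must be an undirected simple graph")
    if any(u == v for u, v in network.edges()):
        raise ValueError("network must not contain self-loops")


def filter_edges(network: nx.Graph, min_score: float = 0.700) -> nx.Graph:
    """Keep edges with confidence score >= min_score; drop isolated leftovers.

    Edges without a ``score`` attribute are treated as score 1 (e.g. SIF input
    carries no confidence).
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be in [0, 1]")
    _check_simple(network)
    out = nx.Graph()
    for u, v, data in network.edges(data=True):
        score = float(data.get("score", 1.0))
        if score >= min_score:
            out.add_edge(u, v, score=score)
    return out


def _eigenvector_centrality(network: nx.Graph, nodes: list) -> np.ndarray:
    """Nonnegative principal eigenvector of the adjacency matrix, unit 2-norm.

    On a disconnected graph the Perron vector lives on the component with the
    largest adjacency spectral radius; if several components tie we take the
    one containing the smallest node label, keeping the result deterministic.
    """
    index = {v: i for i, v in enumerate(nodes)}
    best = None  # (lambda, tie_break_key, component, eigvec)
    for comp in nx.connected_components(network):
        comp_nodes = sorted(comp, key=str)
        a = nx.to_numpy_array(network, nodelist=comp_nodes, weight=None)
        vals, vecs = np.linalg.eigh(a)
        lam = float(vals[-1])
        vec = np.abs(vecs[:, -1])  # Perron vector of a connected graph, up to sign
        key = (round(lam, 12), str(comp_nodes[0]))
        if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
            best = (key[0], key[1], comp_nodes, vec)
    ec = np.zeros(len(nodes))
    if best is not None:
        _, _, comp_nodes, vec = best
        for v, x in zip(comp_nodes, vec):
            ec[index[v]] = x
        n = np.linalg.norm(ec)
        if n > 0:
            ec /= n
    return ec


def edge_clustering_coefficient(network: nx.Graph, u, v) -> float:
    """Triangles on edge (u, v) divided by min(deg u - 1, deg v - 1); 0 if degenerate."""
    denom = min(network.degree(u) - 1, network.degree(v) - 1)
    if denom <= 0:
        return 0.0
    triangles = len(set(network[u]) & set(network[v]))
    return triangles / denom


def centralities(network: nx.Graph) -> pd.DataFrame:
    """Six-metric centrality table, one row per node (sorted), columns dc..lac."""
    _check_simple(network)
    if network.number_of_nodes() == 0:
        raise ValueError("centralities of an empty network are undefined")
    nodes = sorted(network.nodes(), key=str)

    dc = np.array([network.degree(v) for v in nodes], dtype=float)
    bc_map = nx.betweenness_centrality(network, normalized=False)
    bc = np.array([bc_map[v] for v in nodes])
    # Wasserman–Faust component-scaled closeness: within-component closeness
    # (n_c - 1)/sum d(v, u) times the component-size fraction (n_c - 1)/(N - 1).
    # Identical to plain within-component closeness on connected graphs; on
    # fragmented graphs it stops 2-node components from posting CC = 1 and
    # crowding real hub modules out of the median screen.
    cc_map = nx.closeness_centrality(network, wf_improved=True)
    cc = np.array([cc_map[v] for v in nodes])
    ec = _eigenvector_centrality(network, nodes)

    nc = np.zeros(len(nodes))
    lac = np.zeros(len(nodes))
    index = {v: i for i, v in enumerate(nodes)}
    for v in nodes:
        nbrs = list(network[v])
        nc[index[v]] = sum(edge_clustering_coefficient(network, v, u) for u in nbrs)
        if nbrs:
            sub = network.subgraph(nbrs)
            lac[index[v]] = 2.0 * sub.number_of_edges() / len(nbrs)

    return pd.DataFrame(
        {"dc": dc, "bc": bc, "cc": cc, "ec": ec, "nc": nc, "lac": lac},
        index=pd.Index(nodes, name="node"),
    )


@dataclass
class ScreeningRound:
    thresholds: dict[str, float]
    nodes_before: int
    nodes_after: int
    edges_before: int
    edges_after: int
    surviving_nodes: list[str]


@dataclass
class ScreeningTrace:
    rounds: list[ScreeningRound] = field(default_factory=list)
    warning: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def median_screen(network: nx.Graph, rounds: int = 2) -> tuple[nx.Graph, ScreeningTrace]:
    """Iterative hub screening: keep nodes with all six centralities >= median.

    Each round recomputes the six centralities on the current induced
    subnetwork, takes the median of each metric over current nodes (even
    count: mean of the two central values) and keeps nodes at or above all
    six medians.  A round that eliminates every node is recorded in the trace
    with a warning and the empty network is returned rather than raising.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if network.number_of_nodes() == 0:
        raise ValueError("median_screen requires a nonempty network")
    current = nx.Graph(network)
    trace = ScreeningTrace()
    for _ in range(rounds):
        table = centralities(current)
        medians = table.median(axis=0)
        # inclusive >= with a tolerance so that analytically tied values
        # (e.g. eigenvector entries of symmetric nodes) are not split by
        # floating-point noise
        tol = 1e-9 * (1.0 + medians.abs())
        keep_mask = (table >= medians - tol).all(axis=1)
        survivors = sorted(table.index[keep_mask], key=str)
        sub = current.subgraph(survivors).copy()
        trace.rounds.append(
            ScreeningRound(
                thresholds={k: float(medians[k]) for k in CENTRALITY_COLUMNS},
                nodes_before=current.number_of_nodes(),
                nodes_after=sub.number_of_nodes(),
                edges_before=current.number_of_edges(),
                edges_after=sub.number_of_edges(),
                surviving_nodes=[str(v) for v in survivors],
            )
        )
        current = sub
        if current.number_of_nodes() == 0:
            trace.warning = "screening eliminated all nodes"
            break
    return current, trace


def build_compound_target_network(
    active_compounds: Sequence[CompoundRecord],
    hub_targets: TargetSet,
    mapping: Mapping[str, Sequence[str]] | Sequence[tuple[str, str]],
) -> tuple[nx.Graph, list[tuple[str, int]]]:
    """Bipartite compound–target network restricted to active compounds x hub targets.

    ``mapping`` is either compound_id -> iterable of target symbols or an edge
    list of (compound_id, symbol) pairs.  Compounds retaining no edge are
    dropped.  Returns the graph (node attribute ``kind`` in {compound,
    target}) and compounds ranked by decreasing degree, ties broken
    lexicographically by compound id.
    """
    if isinstance(mapping, Mapping):
        edges = [(c, t) for c, ts in mapping.items() for t in ts]
    else:
        edges = list(mapping)
    active_ids = {c.compound_id for c in active_compounds}
    hubs = hub_targets.symbols
    g = nx.Graph()
    for cid, sym in edges:
        if cid in active_ids and sym in hubs:
            g.add_node(cid, kind="compound")
            g.add_node(sym, kind="target")
            g.add_edge(cid, sym)
    ranking = sorted(
        ((cid, g.degree(cid)) for cid in g.nodes if g.nodes[cid]["kind"] == "compound"),
        key=lambda item: (-item[1], item[0]),
    )
    return g, ranking


# ---------------------------------------------------------------------------
# Network file formats
# ---------------------------------------------------------------------------

def read_string_edges(path: str | Path) -> nx.Graph:
    """Read a STRING-style TSV edge export (node1, node2, combined_score).

    The score scale is auto-detected: values above 1 are taken to be on the
    STRING 0–1000 integer scale and divided by 1000.
    """
    df = pd.read_csv(path, sep=r"\s+|\t", engine="python")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError("edge table needs at least three columns")
    u_col, v_col = cols[0], cols[1]
    s_col = "combined_score" if "combined_score" in cols else cols[2]
    scores = df[s_col].astype(float)
    if (scores > 1.0).any():
        scores = scores / 1000.0
    g = nx.Graph()
    for u, v, s in zip(df[u_col], df[v_col], scores):
        if u != v:
            g.add_edge(str(u), str(v), score=float(s))
    return g


def write_sif(network: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    lines = [f"{u}\t{relation}\t{v}" for u, v in sorted(network.edges(), key=str)]
    isolated = sorted((str(v) for v in nx.isolates(network)))
    Path(path).write_text("\n".join(lines + isolated) + ("\n" if lines or isolated else ""))


def read_sif(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t") if "\t" in line else line.split()
        if not parts or not parts[0]:
            continue
        if len(parts) == 1:
            g.add_node(parts[0])
        else:
            for target in parts[2:]:
                if target != parts[0]:
                    g.add_edge(parts[0], target, score=1.0)
    return g


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.Graph(nx.read_graphml(path))
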