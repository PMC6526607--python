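"""Graph construction, topology, module detection, and node roles.

The co-occurrence graph is undirected and simple; edge sign is carried as
an attribute and ignored by every topological computation except the
positive/negative edge counts.  Modules come from a seeded Louvain
modularity partition; MCODE complexes (overlapping, clique-like) are
reported alongside.  Node roles follow the Zi-Pi scheme: within-module
degree z-score Z and participation coefficient P, thresholded into
module hubs, connectors, network hubs, and peripherals.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BACKGROUND",
    "RoleThresholds",
    "DEFAULT_THRESHOLDS",
    "CLASSIC_THRESHOLDS",
    "TopologySummary",
    "graph_from_edges",
    "topology_summary",
    "detect_modules",
    "mcode",
    "zi_pi",
    "classify_roles",
    "sip_overlap",
]

BACKGROUND = -1


@dataclass(frozen=True)
class RoleThresholds:
    """Cutoffs of the Zi-Pi role plane."""

    z_cut: float = 0.25
    p_cut: float = 0.62


#: Thresholds as printed in the study this pipeline reproduces.
DEFAULT_THRESHOLDS = RoleThresholds(0.25, 0.62)
#: The classical literature's module-hub cutoff (Z > 2.5); shipped as an
#: alternative preset because published keystone Z values all exceed it.
CLASSIC_THRESHOLDS = RoleThresholds(2.5, 0.62)


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    neg_pos_ratio: float
    avg_path_length: float
    graph_density: float
    diameter: int
    avg_clustering: float
    avg_connectivity: float
    modularity_q: float

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def graph_from_edges(edges) -> nx.Graph:
    """Build an undirected simple graph from an edge-list DataFrame
    (columns taxon_a, taxon_b and optionally sign/ensemble_score) or pass
    an existing graph through."""
    if isinstance(edges, nx.Graph):
        return edges
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        attrs = {}
        if hasattr(row, "sign"):
            attrs["sign"] = int(row.sign)
        if hasattr(row, "ensemble_score"):
            attrs["weight"] = float(row.ensemble_score)
        g.add_edge(row.taxon_a, row.taxon_b, **attrs)
    return g


def topology_summary(edges, partition: dict | None = None, seed: int = 0) -> TopologySummary:
    """Whole-network topological characterization.

    Path metrics (average path length, diameter) are taken on the largest
    connected component; modularity Q is evaluated at the
    :func:`detect_modules` partition unless one is supplied.
    """
    g = graph_from_edges(edges)
    if g.number_of_edges() == 0:
        raise ValueError("topology summary requires at least one edge")
    n_pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    n_neg = g.number_of_edges() - n_pos
    if partition is None:
        partition = detect_modules(g, seed=seed, min_module_size=1)
    comms: dict[int, set] = {}
    for node, mod in partition.items():
        comms.setdefault(mod, set()).add(node)
    q = nx.community.modularity(g, comms.values())
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    degrees = [d for _, d in g.degree()]
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_positive=n_pos,
        n_negative=n_neg,
        neg_pos_ratio=n_neg / n_pos if n_pos else float("inf"),
        avg_path_length=nx.average_shortest_path_length(giant) if len(giant) > 1 else 0.0,
        graph_density=nx.density(g),
        diameter=nx.diameter(giant) if len(giant) > 1 else 0,
        avg_clustering=nx.average_clustering(g),
        avg_connectivity=float(np.mean(degrees)),
        modularity_q=q,
    )


def detect_modules(edges, seed: int = 0, min_module_size: int = 3) -> dict:
    """Louvain modularity partition, deterministic given ``seed``.

    Modules are indexed by descending size (ties broken by smallest
    member); modules below ``min_module_size`` are relabeled
    :data:`BACKGROUND` (-1).
    """
    g = graph_from_edges(edges)
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes()))  # fixed node order for tie-breaks
    h.add_edges_from((u, v) for u, v in g.edges())
    comms = nx.community.louvain_communities(h, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    partition: dict = {}
    nxt = 0
    for c in comms:
        if len(c) >= min_module_size:
            label, nxt = nxt, nxt + 1
        else:
            label = BACKGROUND
        for node in c:
            partition[node] = label
    return partition


def _vertex_weight(g: nx.Graph, v) -> float:
    """MCODE vertex weight: density of the highest k-core of the closed
    neighborhood, times that core's k."""
    nbrs = set(g[v]) | {v}
    h = g.subgraph(nbrs)
    if h.number_of_edges() == 0:
        return 0.0
    core = nx.core_number(h)
    kmax = max(core.values())
    kcore = h.subgraph([u for u, c in core.items() if c >= kmax])
    return kmax * nx.density(kcore)


def mcode(
    edges,
    node_score_cutoff: float = 0.2,
    k_core_min: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.2,
) -> list[dict]:
    """Molecular Complex Detection: mine dense, clique-like subgraphs.

    Stage 1 weights every vertex by (core-clustering coefficient) x
    (highest core number of its closed neighborhood).  Stage 2 grows a
    complex from each highest-weight unvisited seed, admitting unvisited
    neighbors whose weight is >= ``w_seed * (1 - node_score_cutoff)``.
    Stage 3 drops complexes without a 2-core, optionally trims singly
    connected nodes (haircut) or adds dense-neighborhood boundary nodes
    (fluff).  Complexes are ranked by density x size.
    """
    g = graph_from_edges(edges)
    weights = {v: _vertex_weight(g, v) for v in g.nodes()}
    order = sorted(g.nodes(), key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    complexes: list[set] = []
    for seed_node in order:
        if seed_node in visited or weights[seed_node] <= 0:
            continue
        threshold = weights[seed_node] * (1.0 - node_score_cutoff)
        members = {seed_node}
        visited.add(seed_node)
        frontier = [seed_node]
        while frontier:
            nxt = []
            for u in frontier:
                for w in g[u]:
                    if w not in visited and weights[w] >= threshold:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        complexes.append(members)

    results = []
    for members in complexes:
        sub = g.subgraph(members)
        core = nx.k_core(sub, k_core_min)
        if core.number_of_nodes() == 0:
            continue
        final = set(core.nodes()) if haircut else set(members)
        if fluff:
            for u in list(final):
                for w in g[u]:
                    if w in final:
                        continue
                    nbh = g.subgraph(set(g[w]) | {w})
                    if nx.density(nbh) > fluff_density:
                        final.add(w)
        fsub = g.subgraph(final)
        results.append(
            {"nodes": frozenset(final), "score": nx.density(fsub) * len(final)}
        )
    return sorted(results, key=lambda r: (-r["score"], sorted(map(str, r["nodes"]))))


def zi_pi(edges, partition: dict) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient.

    Z_i standardizes the node's within-module degree kappa_i against its
    module's (kappa) distribution (Z = 0 when the module's kappa variance
    is zero); P_i = 1 - sum_s (k_is / k_i)^2 over all modules s, and 0
    for isolated nodes (flagged).
    """
    g = graph_from_edges(edges)
    missing = [v for v in g.nodes() if v not in partition]
    if missing:
        raise ValueError(f"partition does not cover node(s): {missing[:5]}")
    nodes = list(g.nodes())
    rows = []
    kappa = {}
    for v in nodes:
        kappa[v] = sum(1 for u in g[v] if partition[u] == partition[v])
    by_module: dict[int, list] = {}
    for v in nodes:
        by_module.setdefault(partition[v], []).append(v)
    stats = {}
    for mod, members in by_module.items():
        ks = np.array([kappa[v] for v in members], dtype=float)
        stats[mod] = (ks.mean(), ks.std())  # population sd
    for v in nodes:
        k = g.degree(v)
        mu, sd = stats[partition[v]]
        z = (kappa[v] - mu) / sd if sd > 0 else 0.0
        if k == 0:
            p = 0.0
        else:
            per_mod: dict[int, int] = {}
            for u in g[v]:
                per_mod[partition[u]] = per_mod.get(partition[u], 0) + 1
            p = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
        rows.append((v, partition[v], k, kappa[v], z, p, k == 0))
    return pd.DataFrame(
        rows,
        columns=["taxon", "module", "degree", "within_module_degree", "Z", "P", "isolated"],
    ).set_index("taxon")


def classify_roles(
    zp: pd.DataFrame, thresholds: RoleThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Assign Zi-Pi roles: module_hub (Z > z_cut, P <= p_cut), connector
    (Z <= z_cut, P > p_cut), network_hub (both exceeded), else peripheral."""
    out = zp.copy()
    z, p = out["Z"], out["P"]
    hub = z > thresholds.z_cut
    conn = p > thresholds.p_cut
    role = np.select(
        [hub & ~conn, ~hub & conn, hub & conn],
        ["module_hub", "connector", "network_hub"],
        default="peripheral",
    )
    out["role"] = role
    return out


def sip_overlap(nodes, labeled, keystone_ids=()) -> tuple[float, dict]:
    """Fraction of network nodes found in the substrate-labeled taxon set,
    plus a per-keystone labeled flag."""
    nodes = set(nodes)
    labeled = set(labeled)
    frac = len(nodes & labeled) / len(nodes) if nodes else 0.0
    return frac, {k: k in labeled for k in keystone_ids}
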