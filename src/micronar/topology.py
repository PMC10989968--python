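"""Network complexity metrics and Zi-Pi node-role (keystone) classification.

Complexity is summarized by node count n, link count L, average degree
2L/n, and connectance L/n^2 (links over network size squared).  Modularity
is Newman's Q of a Louvain partition; relative modularity standardizes Q
against degree-preserving (Maslov-Sneppen) rewired null networks.  Node
roles follow the within-module degree z-score (Zi) and among-module
participation coefficient (Pi), with the conventional keystone quadrants:
network hubs (Zi >= 2.5, Pi >= 0.62), module hubs (Zi >= 2.5, Pi < 0.62),
connectors (Zi < 2.5, Pi >= 0.62), peripherals otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
KEYSTONE_ROLES = ("network_hub", "module_hub", "connector")


@dataclass
class NodeRole:
    otu_id: str
    module_id: int
    zi: float
    pi: float
    role: str


@dataclass
class NetworkProperties:
    """Complexity summary of one (sub)network."""

    n: int
    L: int
    avg_k: float
    connectance: float
    modularity: float
    relative_modularity: float
    n_keystone: int
    n_network_hub: int
    n_module_hub: int
    n_connector: int


def basic_properties(graph: nx.Graph) -> tuple[int, int, float, float]:
    """(n, L, average degree 2L/n, connectance L/n^2); all 0 for n = 0."""
    if any(True for _ in nx.selfloop_edges(graph)):
        raise ValueError("graph must have no self-loops")
    n = graph.number_of_nodes()
    L = graph.number_of_edges()
    if n == 0:
        return 0, 0, 0.0, 0.0
    return n, L, 2.0 * L / n, L / n ** 2


def detect_modules(graph: nx.Graph, seed: int = 0) -> dict:
    """Louvain modularity maximization; returns node -> module id.

    Unweighted (correlation magnitudes are association strengths, not
    affinities to optimize over); deterministic given ``seed``; components
    are handled naturally by the algorithm.  Fewer than 2 nodes yield a
    single trivial module.
    """
    if graph.number_of_nodes() < 2 or graph.number_of_edges() == 0:
        return {node: 0 for node in graph.nodes}
    comms = nx.community.louvain_communities(graph, weight=None, seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    return {node: m for m, comm in enumerate(comms) for node in comm}


def newman_modularity(graph: nx.Graph, partition: dict) -> float:
    """Newman's Q of a hard partition (unweighted)."""
    if graph.number_of_edges() == 0:
        return 0.0
    groups: dict = {}
    for node, m in partition.items():
        groups.setdefault(m, set()).add(node)
    return nx.community.modularity(graph, groups.values(), weight=None)


def rewire_degree_preserving(graph: nx.Graph, n_swaps: int | None = None,
                             rng: np.random.Generator | None = None,
                             max_tries_factor: int = 50) -> nx.Graph:
    """Maslov-Sneppen rewiring: repeated double-edge swaps preserving the
    degree sequence; defaults to 10 successful swaps per edge."""
    if rng is None:
        rng = np.random.default_rng()
    L = graph.number_of_edges()
    if n_swaps is None:
        n_swaps = 10 * L
    if L < 2:
        return graph.copy()
    edges = [tuple(e) for e in graph.edges()]
    edge_set = {frozenset(e) for e in edges}
    successes = 0
    tries = 0
    max_tries = max_tries_factor * n_swaps
    # pre-drawn randomness in blocks keeps the python loop tolerable
    block = 4096
    buf_idx = rng.integers(0, L, size=(block, 2))
    buf_flip = rng.random(block) < 0.5
    ptr = 0
    while successes < n_swaps and tries < max_tries:
        if ptr >= block:
            buf_idx = rng.integers(0, L, size=(block, 2))
            buf_flip = rng.random(block) < 0.5
            ptr = 0
        i, j = buf_idx[ptr]
        flip = buf_flip[ptr]
        ptr += 1
        tries += 1
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        successes += 1
    if successes < n_swaps:
        logger.warning(
            "rewire: only %d/%d swaps succeeded within try budget", successes, n_swaps
        )
    null = nx.Graph()
    null.add_nodes_from(graph.nodes)
    null.add_edges_from(edges)
    return null


def relative_modularity(graph: nx.Graph, m_obs: float | None = None,
                        n_null: int = 100, seed: int = 0,
                        swaps_per_edge: int = 10) -> float:
    """RM = (M_obs - mean(M_null)) / mean(M_null) over degree-preserving nulls.

    Each null is rewired with ``swaps_per_edge * L`` successful swaps and
    re-run through module detection with a derived seed.  NaN (with a
    warning) when the null mean is 0.
    """
    if n_null < 10:
        raise ValueError("n_null must be >= 10")
    if graph.number_of_edges() < 1:
        raise ValueError("graph must have at least one edge")
    if m_obs is None:
        m_obs = newman_modularity(graph, detect_modules(graph, seed=seed))
    m_null = np.empty(n_null)
    for k in range(n_null):
        rng = np.random.default_rng([seed, k])
        null = rewire_degree_preserving(
            graph, n_swaps=swaps_per_edge * graph.number_of_edges(), rng=rng
        )
        part = detect_modules(null, seed=seed + k + 1)
        m_null[k] = newman_modularity(null, part)
    mean_null = m_null.mean()
    if mean_null == 0:
        logger.warning("relative_modularity: null mean modularity is 0; RM undefined")
        return float("nan")
    return (m_obs - mean_null) / mean_null


def node_roles(graph: nx.Graph, partition: dict) -> list[NodeRole]:
    """Zi (within-module degree z-score) and Pi (participation coefficient).

    zi = (k_i,own - mean_m) / sd_m over the module's members' within-module
    degrees (population sd; sd = 0 gives zi = 0);
    pi = 1 - sum_s (k_is / k_i)^2 over modules s.
    Isolated nodes are an error: they are excluded upstream by edge calling.
    """
    members: dict = {}
    for node in graph.nodes:
        if node not in partition:
            raise ValueError(f"partition does not cover node {node!r}")
        members.setdefault(partition[node], []).append(node)

    within = {}
    links_by_module = {}
    for node in graph.nodes:
        k = graph.degree(node)
        if k == 0:
            raise ValueError(f"isolated node {node!r}; remove before role analysis")
        counts: dict = {}
        for nb in graph.neighbors(node):
            counts[partition[nb]] = counts.get(partition[nb], 0) + 1
        links_by_module[node] = counts
        within[node] = counts.get(partition[node], 0)

    stats = {}
    for m, nodes in members.items():
        vals = np.array([within[v] for v in nodes], dtype=float)
        stats[m] = (vals.mean(), vals.std())  # population sd

    roles = []
    for node in graph.nodes:
        m = partition[node]
        mean_m, sd_m = stats[m]
        zi = 0.0 if sd_m == 0 else (within[node] - mean_m) / sd_m
        k = graph.degree(node)
        pi = 1.0 - sum((c / k) ** 2 for c in links_by_module[node].values())
        roles.append(NodeRole(str(node), int(m), float(zi), float(pi),
                              _classify(zi, pi)))
    return roles


def _classify(zi: float, pi: float) -> str:
    if zi >= ZI_THRESHOLD:
        return "network_hub" if pi >= PI_THRESHOLD else "module_hub"
    return "connector" if pi >= PI_THRESHOLD else "peripheral"


def classify_keystones(roles: list[NodeRole]) -> dict:
    """Counts per role quadrant; keystones are the non-peripherals."""
    counts = {"network_hub": 0, "module_hub": 0, "connector": 0, "peripheral": 0}
    for r in roles:
        counts[r.role] += 1
    counts["keystone"] = sum(counts[r] for r in KEYSTONE_ROLES)
    return counts


def network_properties(graph: nx.Graph, seed: int = 0, n_null: int = 100,
                       swaps_per_edge: int = 10,
                       partition: dict | None = None) -> tuple[NetworkProperties, list[NodeRole]]:
    """Full complexity summary of one network: basic properties, modularity,
    RM against the rewired null ensemble, and keystone counts."""
    n, L, avg_k, conn = basic_properties(graph)
    if n == 0:
        props = NetworkProperties(0, 0, 0.0, 0.0, 0.0, float("nan"), 0, 0, 0, 0)
        return props, []
    if partition is None:
        partition = detect_modules(graph, seed=seed)
    m_obs = newman_modularity(graph, partition)
    if L >= 1 and n_null:
        rm = relative_modularity(graph, m_obs=m_obs, n_null=n_null, seed=seed,
                                 swaps_per_edge=swaps_per_edge)
    else:
        rm = float("nan")
    roles = node_roles(graph, partition)
    counts = classify_keystones(roles)
    props = NetworkProperties(
        n=n, L=L, avg_k=avg_k, connectance=conn, modularity=m_obs,
        relative_modularity=rm, n_keystone=counts["keystone"],
        n_network_hub=counts["network_hub"], n_module_hub=counts["module_hub"],
        n_connector=counts["connector"],
    )
    return props, roles
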