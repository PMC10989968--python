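"""Network stability: random-removal robustness, efficiency, vulnerability,
and the keystone-removal contrast.

Robustness is the proportion of taxa remaining after randomly removing a
fixed fraction of nodes, counting residual isolated nodes as secondary
extinctions.  Vulnerability is the maximum over nodes of the relative loss
of global efficiency caused by deleting that node; global efficiency is the
mean inverse shortest-path length over pairs (hop counts, unweighted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.5
DEFAULT_REPS = 999


@dataclass
class RobustnessResult:
    mean: float
    sd: float
    replicates: np.ndarray = field(repr=False)
    fraction: float = DEFAULT_FRACTION

    @property
    def reps(self) -> int:
        return len(self.replicates)


def _adjacency(graph: nx.Graph) -> tuple[sparse.csr_matrix, list]:
    nodes = list(graph.nodes)
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None, format="csr")
    return a, nodes


def robustness(graph: nx.Graph, fraction: float = DEFAULT_FRACTION,
               reps: int = DEFAULT_REPS, seed: int = 0) -> RobustnessResult:
    """Monte-Carlo robustness under uniform random node removal.

    Per replicate, floor(fraction * n) nodes are removed uniformly at
    random; any remaining node left with degree 0 is a secondary
    extinction; robustness is (survivors with degree >= 1) / n, with n the
    node count of the graph as passed in.  Deterministic given ``seed``.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("robustness needs at least 2 nodes")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_remove = int(np.floor(fraction * n))
    a, _ = _adjacency(graph)
    rng = np.random.default_rng(seed)
    # batched removal sets: rank a uniform matrix per replicate
    u = rng.random((reps, n))
    order = np.argpartition(u, n_remove, axis=1)
    keep = np.ones((reps, n), dtype=bool)
    rows = np.repeat(np.arange(reps), n_remove)
    keep[rows, order[:, :n_remove].ravel()] = False
    kept_neighbor_deg = a @ keep.T.astype(np.int64)   # n x reps
    survivors = (keep.T & (kept_neighbor_deg > 0)).sum(axis=0)
    reps_vec = survivors / n
    sd = float(reps_vec.std(ddof=1)) if reps > 1 else float("nan")
    if reps == 1:
        logger.warning("robustness: single replicate; sd undefined")
    return RobustnessResult(float(reps_vec.mean()), sd, reps_vec, fraction)


def robustness_exact(graph: nx.Graph, fraction: float = DEFAULT_FRACTION) -> float:
    """Exact expected robustness by enumerating all removal sets.

    Only feasible for small graphs (C(n, floor(fraction*n)) sets); used as
    an oracle for the Monte-Carlo estimator.
    """
    from itertools import combinations

    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    n_remove = int(np.floor(fraction * n))
    a, _ = _adjacency(graph)
    dense = a.toarray().astype(bool)
    total = 0.0
    count = 0
    for removed in combinations(range(n), n_remove):
        keep = np.ones(n, dtype=bool)
        keep[list(removed)] = False
        surv = (dense[keep][:, keep].any(axis=1)).sum()
        total += surv / n
        count += 1
    return total / count


def _efficiency_from_adjacency(a: sparse.csr_matrix) -> float:
    n = a.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(n, k=1)
    dv = d[iu]
    finite = np.isfinite(dv)
    inv = np.zeros_like(dv)
    inv[finite] = 1.0 / dv[finite]
    return float(inv.sum() * 2.0 / (n * (n - 1)))


def global_efficiency(graph: nx.Graph) -> float:
    """E = (2 / n(n-1)) * sum_{i<j} 1/d_ij with 1/d = 0 for disconnected
    pairs; unweighted hop-count shortest paths."""
    a, _ = _adjacency(graph)
    return _efficiency_from_adjacency(a)


def vulnerability(graph: nx.Graph, normalization: str = "reduced"
                  ) -> tuple[float, dict]:
    """Max node vulnerability V = max_i (E - E_-i) / E, plus per-node values.

    ``normalization="reduced"`` (default) computes E_-i as the global
    efficiency of the node-deleted graph over its own (n-1)(n-2)/2 pairs;
    ``"fixed"`` keeps the original pair count n(n-1)/2 in the denominator.
    Undefined (NaN, with a warning) when E = 0.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("vulnerability needs at least 3 nodes")
    if normalization not in ("reduced", "fixed"):
        raise ValueError(f"unknown normalization {normalization!r}")
    a, nodes = _adjacency(graph)
    e_full = _efficiency_from_adjacency(a)
    if e_full == 0:
        logger.warning("vulnerability: global efficiency is 0; V undefined")
        return float("nan"), {}
    per_node = {}
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        sub = a[keep][:, keep]
        e_i = _efficiency_from_adjacency(sub)
        if normalization == "fixed":
            e_i *= ((n - 1) * (n - 2)) / (n * (n - 1))
        per_node[nodes[i]] = (e_full - e_i) / e_full
    v = max(per_node.values())
    return float(v), per_node


@dataclass
class KeystoneRemovalResult:
    robustness_original: RobustnessResult
    robustness_removed: RobustnessResult
    t: float
    p: float
    n_keystones: int
    degenerate: bool = False   # True when zero keystones: ns by construction


def keystone_removal_test(graph: nx.Graph, roles, fraction: float = DEFAULT_FRACTION,
                          reps: int = DEFAULT_REPS, seed: int = 0
                          ) -> KeystoneRemovalResult:
    """Does deleting the keystone nodes reduce robustness?

    Keystones (network hubs, module hubs, connectors) are removed, isolated
    nodes dropped, and the robustness simulation run on both graphs with
    independent replicate streams; replicate vectors are compared with a
    two-sided Welch t-test.
    """
    keystones = {r.otu_id for r in roles if r.role != "peripheral"}
    non_keystone = [v for v in graph.nodes if v not in keystones]
    if not non_keystone:
        raise ValueError("graph has no non-keystone node")
    removed = graph.subgraph(non_keystone).copy()
    removed.remove_nodes_from([v for v, d in list(removed.degree()) if d == 0])

    rob_orig = robustness(graph, fraction=fraction, reps=reps, seed=2 * seed)
    degenerate = len(keystones) == 0
    if degenerate:
        logger.warning("keystone_removal_test: zero keystones; ns by construction")
        rob_rem = robustness(graph, fraction=fraction, reps=reps, seed=2 * seed + 1)
    else:
        if removed.number_of_nodes() < 2:
            raise ValueError("keystone-deleted graph has fewer than 2 nodes")
        rob_rem = robustness(removed, fraction=fraction, reps=reps, seed=2 * seed + 1)
    t, p = stats.ttest_ind(rob_orig.replicates, rob_rem.replicates, equal_var=False)
    return KeystoneRemovalResult(rob_orig, rob_rem, float(t), float(p),
                                 len(keystones), degenerate)
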