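import networkx as nx
import numpy as np
import pytest

from micronar.synthgen import generate_fixture


@pytest.fixture(scope="session")
def stability_graphs():
    return generate_fixture("star-stability")


@pytest.fixture(scope="session")
def modular_bundle():
    return generate_fixture("modular")


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_fixture("tiny")


@pytest.fixture(scope="session")
def random_graphs():
    """100 small random graphs (n <= 50), isolated nodes removed."""
    graphs = []
    rng = np.random.default_rng(42)
    while len(graphs) < 100:
        n = int(rng.integers(5, 51))
        p = float(rng.uniform(0.08, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        g.remove_nodes_from([v for v, d in list(g.degree()) if d == 0])
        if g.number_of_nodes() >= 4 and g.number_of_edges() >= 3:
            graphs.append(g)
    return graphs


# ---------------------------------------------------------------------------
# naive oracles, deliberately independent of the implementations they check
# ---------------------------------------------------------------------------

def naive_modularity(graph, partition):
    a = nx.to_numpy_array(graph, weight=None)
    nodes = list(graph.nodes)
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    k = a.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if partition[u] == partition[v]:
                q += a[i, j] - k[i] * k[j] / (2 * m)
    return q / (2 * m)


def naive_zi_pi(graph, partition):
    within = {}
    for v in graph.nodes:
        within[v] = sum(1 for u in graph.neighbors(v)
                        if partition[u] == partition[v])
    out = {}
    for v in graph.nodes:
        members = [u for u in graph.nodes if partition[u] == partition[v]]
        vals = np.array([within[u] for u in members], dtype=float)
        sd = vals.std()
        zi = 0.0 if sd == 0 else (within[v] - vals.mean()) / sd
        k = graph.degree(v)
        mods = {}
        for u in graph.neighbors(v):
            mods[partition[u]] = mods.get(partition[u], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in mods.values())
        out[v] = (zi, pi)
    return out


def naive_efficiency(graph):
    n = graph.number_of_nodes()
    total = 0.0
    nodes = list(graph.nodes)
    for i, u in enumerate(nodes):
        lengths = nx.single_source_shortest_path_length(graph, u)
        for v in nodes[i + 1:]:
            if v in lengths and lengths[v] > 0:
                total += 1.0 / lengths[v]
    return 2.0 * total / (n * (n - 1))


def naive_welch(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = len(x), len(y)
    return (x.mean() - y.mean()) / np.sqrt(v1 / n1 + v2 / n2)


def exhaustive_robustness(graph, fraction=0.5):
    """Exact expected robustness by enumerating all removal sets."""
    from itertools import combinations

    nodes = list(graph.nodes)
    n = len(nodes)
    n_remove = int(np.floor(fraction * n))
    a = nx.to_numpy_array(graph, weight=None).astype(bool)
    total = 0.0
    count = 0
    for removed in combinations(range(n), n_remove):
        keep = np.ones(n, dtype=bool)
        keep[list(removed)] = False
        total += a[keep][:, keep].any(axis=1).sum() / n
        count += 1
    return total / count
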