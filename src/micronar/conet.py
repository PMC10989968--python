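"""Spearman co-occurrence network inference and per-island subnetworks.

One meta-network is inferred across all samples from pairwise Spearman
correlations of (log-transformed) OTU abundances; edges are pairs whose
correlation magnitude and BH-adjusted p-value pass the calling thresholds.
Per-island networks are node-induced subgraphs of the meta-network on the
OTUs detected on that island, with isolated nodes removed.

Edges are statistical associations, not demonstrated biotic interactions;
negative correlations are kept as ordinary edges with their sign stored as
an attribute.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .tables_io import OtuTable, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_RHO_MIN = 0.6
DEFAULT_ALPHA = 0.05


@dataclass
class CorrelationResult:
    """All-pairs Spearman correlations with raw and BH-adjusted p-values.

    ``rho``, ``pval`` and ``qval`` are symmetric (n_otus x n_otus) matrices;
    entries involving a zero-variance OTU are NaN and never become edges.
    """

    otu_ids: list[str]
    rho: np.ndarray = field(repr=False)
    pval: np.ndarray = field(repr=False)
    qval: np.ndarray = field(repr=False)
    n_samples: int = 0


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone-enforced and capped at 1; NaNs (undefined tests) propagate and
    do not count toward the number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    flat = p.ravel()
    defined = ~np.isnan(flat)
    vals = flat[defined]
    if vals.size and ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(flat.shape, np.nan)
    m = vals.size
    if m:
        order = np.argsort(vals, kind="mergesort")
        scaled = vals[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(scaled[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(q, 1.0)
        out[defined] = adj
    return out.reshape(p.shape)


def _spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation t = rho * sqrt((n-2)/(1-rho^2))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return p


def _exact_spearman_pvalue(rho_obs: float, xr: np.ndarray, yr: np.ndarray) -> float:
    """Exact permutation two-sided p for one pair (enumeration; tiny n only)."""
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = (xc * yc[list(perm)]).sum() / denom
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def spearman_all_pairs(matrix: np.ndarray, otu_ids: list[str] | None = None,
                       pvalue_method: str = "t") -> CorrelationResult:
    """All-pairs average-rank Spearman correlation with BH-adjusted p-values.

    Parameters
    ----------
    matrix : ndarray (n_samples x n_otus)
        Abundances (raw or log-transformed; Spearman is rank-invariant).
    pvalue_method : {"t", "exact"}
        "t" uses the usual t-distribution approximation; "exact" enumerates
        all rank permutations per pair (only sensible for n_samples <= 8).

    Zero-variance OTUs (constant across samples) have undefined correlation:
    their rows/columns are NaN, they are counted and logged, and they can
    never become edges.  BH adjustment runs over the strict upper triangle
    of defined pairs only.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if n < 4:
        raise ValueError("need at least 4 samples for correlation inference")
    if p < 2:
        raise ValueError("need at least 2 OTUs")
    if otu_ids is None:
        otu_ids = [f"OTU{j}" for j in range(p)]

    ranks = stats.rankdata(matrix, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    n_const = int(constant.sum())
    if n_const:
        logger.warning("spearman_all_pairs: %d zero-variance OTU(s) excluded", n_const)

    z = ranks - ranks.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = z / np.sqrt((z ** 2).sum(axis=0))
    z[:, constant] = np.nan
    rho = z.T @ z
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan

    if pvalue_method == "t":
        pval = _spearman_pvalues(rho, n)
    elif pvalue_method == "exact":
        if n > 8:
            raise ValueError("exact permutation p-values only supported for n <= 8")
        pval = np.full_like(rho, np.nan)
        for i in range(p):
            if constant[i]:
                continue
            for j in range(i + 1, p):
                if constant[j]:
                    continue
                pval[i, j] = pval[j, i] = _exact_spearman_pvalue(
                    rho[i, j], ranks[:, i], ranks[:, j]
                )
        np.fill_diagonal(pval, 0.0)
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    pval[np.isnan(rho)] = np.nan
    np.fill_diagonal(pval, 0.0)

    iu = np.triu_indices(p, k=1)
    qflat = bh_adjust(pval[iu])
    qval = np.full_like(pval, np.nan)
    qval[iu] = qflat
    qval = np.where(np.isnan(qval) & ~np.isnan(qval.T), qval.T, qval)
    qval[iu[1], iu[0]] = qval[iu]
    np.fill_diagonal(qval, 0.0)
    qval[np.isnan(pval)] = np.nan
    return CorrelationResult(list(otu_ids), rho, pval, qval, n_samples=n)


def call_edges(corr: CorrelationResult, rho_min: float = DEFAULT_RHO_MIN,
               alpha: float = DEFAULT_ALPHA) -> nx.Graph:
    """Build the meta-network: edge iff |rho| >= rho_min and qval < alpha.

    OTUs left without any edge are excluded from the node set, so the
    returned graph has no isolated nodes.  Edge attributes: ``rho`` (signed)
    and ``qval``.
    """
    if not (0 <= rho_min):
        raise ValueError("rho_min must be >= 0")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    p = len(corr.otu_ids)
    iu = np.triu_indices(p, k=1)
    r = corr.rho[iu]
    q = corr.qval[iu]
    with np.errstate(invalid="ignore"):
        hit = (~np.isnan(r)) & (~np.isnan(q)) & (np.abs(r) >= rho_min) & (q < alpha)
    g = nx.Graph(rho_min=rho_min, alpha=alpha, n_samples=corr.n_samples)
    ids = corr.otu_ids
    for i, j, rr, qq in zip(iu[0][hit], iu[1][hit], r[hit], q[hit]):
        g.add_edge(ids[i], ids[j], rho=float(rr), qval=float(qq))
    return g


def load_edge_list(path) -> nx.Graph:
    """Import hook for an externally filtered edge list (e.g. after indirect-
    association removal): 3 columns otu_i, otu_j, rho, tab-separated."""
    g = nx.Graph()
    frame = pd.read_csv(path, sep="\t", comment="#",
                        names=["otu_i", "otu_j", "rho"], header=None, dtype={0: str, 1: str})
    # tolerate a header row
    if frame.iloc[0]["otu_i"] == "otu_i":
        frame = frame.iloc[1:]
    for _, row in frame.iterrows():
        g.add_edge(str(row["otu_i"]), str(row["otu_j"]), rho=float(row["rho"]))
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    """Export a network as GraphML (edge attributes rho/qval preserved)."""
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_i\totu_j\trho\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('rho', float('nan'))!r}\n")


@dataclass
class IslandSubnetwork:
    """Node-induced subgraph of the meta-network on one island's OTUs.

    Nodes are OTUs detected (count > 0) in at least one of the island's
    samples; nodes isolated in the induced graph are dropped.  An island
    where nothing survives carries an empty graph and is flagged.
    """

    island_id: str
    area_m2: float
    graph: nx.Graph = field(repr=False)

    @property
    def empty(self) -> bool:
        return self.graph.number_of_nodes() == 0


def extract_island_subnetworks(meta: nx.Graph, table: OtuTable,
                               metadata: SampleMetadata) -> list[IslandSubnetwork]:
    """Induced subnetwork per island, smallest area first.

    Island presence means non-zero abundance in >= 1 of the island's samples
    (in the table as given, i.e. post-rarefaction / post-filter).  Edge
    attributes are inherited unchanged from the meta-network.
    """
    missing = set(meta.nodes) - set(table.otu_ids)
    if missing:
        raise ValueError(
            f"meta-network contains OTUs absent from the table: "
            f"{sorted(missing)[:5]}"
        )
    island_of = metadata.island_of()
    pres = table.presence()
    col_of = {o: j for j, o in enumerate(table.otu_ids)}
    sample_island = np.array([island_of.get(s) for s in table.sample_ids], dtype=object)
    node_cols = np.array([col_of[o] for o in meta.nodes], dtype=int)
    nodes = list(meta.nodes)

    out = []
    for _, row in metadata.islands().iterrows():
        isl, area = row["island_id"], float(row["area_m2"])
        rows = pres[sample_island == isl]
        if rows.size == 0:
            present = []
        else:
            here = rows.any(axis=0)[node_cols]
            present = [n for n, h in zip(nodes, here) if h]
        sub = meta.subgraph(present).copy()
        sub.remove_nodes_from([n for n, d in list(sub.degree()) if d == 0])
        if sub.number_of_nodes() == 0:
            logger.warning("island %s: no nodes survive subnetwork extraction", isl)
        out.append(IslandSubnetwork(isl, area, sub))
    return out
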