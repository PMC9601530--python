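"""Global network attributes and per-gene centralities.

Covers the summary statistics used to track network evolution along
pseudo-time: density/diameter/edge counts, the density trajectory and its
U-shape test, degree/betweenness/clustering/PageRank/h-index centralities,
a discrete power-law fit of the degree distribution, and a small-world
comparison against uniform random graphs with matched size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .simulate import make_random_graph

__all__ = [
    "GlobalProperties",
    "global_properties",
    "centralities",
    "h_index",
    "powerlaw_fit",
    "smallworld_check",
    "density_trajectory",
]


@dataclass
class GlobalProperties:
    n_nodes: int
    n_edges: int
    density: float
    diameter: int
    mean_shortest_path: float
    mean_clustering: float
    connected: bool


def global_properties(net: nx.Graph) -> GlobalProperties:
    """Edge count, density 2E/(V(V-1)), diameter, and mean path length.

    On a disconnected graph the diameter is taken over the largest connected
    component and the mean shortest path over connected node pairs only; the
    ``connected`` flag records which case applied.
    """
    V = net.number_of_nodes()
    if V < 2:
        raise ValueError("density is undefined for graphs with fewer than 2 nodes")
    E = net.number_of_edges()
    density = 2.0 * E / (V * (V - 1))
    connected = nx.is_connected(net) if V else False
    components = list(nx.connected_components(net))
    largest = max(components, key=len) if components else set()
    total, pairs, diam = 0.0, 0, 0
    for comp in components:
        sub = net.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        in_largest = comp == largest
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for dd in dists.values():
                if dd > 0:
                    total += dd
                    pairs += 1
                    if in_largest and dd > diam:
                        diam = dd
    mean_sp = total / pairs if pairs else float("nan")
    return GlobalProperties(V, E, density, diam, mean_sp, nx.average_clustering(net), connected)


def h_index(net: nx.Graph, node) -> int:
    """Largest x such that ``node`` has >= x neighbors each of degree >= x."""
    if node not in net:
        raise ValueError(f"node {node!r} not in network")
    nbr_degs = sorted((net.degree(v) for v in net.neighbors(node)), reverse=True)
    h = 0
    for i, dgr in enumerate(nbr_degs, start=1):
        if dgr >= i:
            h = i
        else:
            break
    return h


def centralities(net: nx.Graph, damping: float = 0.85) -> pd.DataFrame:
    """Per-gene degree, betweenness, clustering coefficient, PageRank, h-index.

    Betweenness is unnormalized (raw counts of shortest-path pairs passing
    through the gene); PageRank uses power iteration to 1e-10.
    """
    nodes = list(net.nodes())
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)
    clust = nx.clustering(net)
    if net.number_of_edges() > 0:
        pr = nx.pagerank(net, alpha=damping, tol=1e-10, max_iter=500)
    else:
        pr = {v: 1.0 / len(nodes) for v in nodes} if nodes else {}
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "clustering_coefficient": [clust[v] for v in nodes],
            "pagerank": [pr[v] for v in nodes],
            "h_index": [h_index(net, v) for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def powerlaw_fit(degrees) -> tuple[float, float]:
    """Discrete power-law MLE with x_min = 1, plus a KS distance.

    Maximizes the zeta-distribution likelihood P(k) = k^(-alpha)/zeta(alpha)
    over the positive degrees and reports the Kolmogorov-Smirnov distance
    between the fitted and empirical CDFs.
    """
    k = np.asarray([d for d in degrees if d > 0], dtype=float)
    if k.size < 10:
        raise ValueError("need at least 10 nonzero degrees")
    if np.all(k == k[0]):
        raise ValueError("degenerate degree distribution (all degrees equal)")
    mean_log = np.mean(np.log(k))

    def nll(alpha):
        return alpha * mean_log + np.log(zeta(alpha, 1.0))

    res = minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded")
    alpha = float(res.x)
    kmax = int(k.max())
    ks_support = np.arange(1, kmax + 1)
    pmf = ks_support ** (-alpha) / zeta(alpha, 1.0)
    fitted_cdf = np.cumsum(pmf)
    emp_cdf = np.array([(k <= x).mean() for x in ks_support])
    ks = float(np.max(np.abs(emp_cdf - fitted_cdf)))
    return alpha, ks


@dataclass
class SmallWorldReport:
    mean_path: float
    mean_clustering: float
    random_path_mean: float
    random_path_sd: float
    random_clustering_mean: float
    random_clustering_sd: float


def smallworld_check(net: nx.Graph, n_random: int = 100, seed: int = 0) -> SmallWorldReport:
    """Compare L and CC against same-node-same-edge uniform random graphs.

    A small world has L close to the random reference while CC is much
    larger. L is the mean shortest path over connected pairs.
    """
    comp = max(nx.connected_components(net), key=len)
    if len(comp) < 3:
        raise ValueError("largest component must have at least 3 nodes")
    gp = global_properties(net)
    n, m = net.number_of_nodes(), net.number_of_edges()
    Ls, CCs = [], []
    for r in range(n_random):
        g = make_random_graph(n, m, seed=seed + r)
        Ls.append(global_properties(g).mean_shortest_path)
        CCs.append(nx.average_clustering(g))
    return SmallWorldReport(
        gp.mean_shortest_path,
        gp.mean_clustering,
        float(np.mean(Ls)),
        float(np.std(Ls)),
        float(np.mean(CCs)),
        float(np.std(CCs)),
    )


def density_trajectory(series, margin: float = 0.2):
    """Per-time density (and edge-count) vector with a U-shape flag.

    The flag is true iff the global minimum falls strictly inside the first
    and last 20% of time points and both endpoint densities exceed the
    minimum by the relative ``margin``.
    """
    graphs = series.to_graphs() if hasattr(series, "to_graphs") else list(series)
    if len(graphs) < 5:
        raise ValueError("need a series of at least 5 networks")
    dens = np.array([global_properties(g).density for g in graphs])
    counts = np.array([g.number_of_edges() for g in graphs])
    T = len(dens)
    amin = int(np.argmin(dens))
    inner = (amin > 0.2 * (T - 1)) and (amin < 0.8 * (T - 1))
    dmin = dens[amin]
    deep = dens[0] > dmin * (1 + margin) and dens[-1] > dmin * (1 + margin)
    if dmin == 0:
        deep = dens[0] > 0 and dens[-1] > 0
    return {
        "density": dens,
        "edge_count": counts,
        "argmin": amin,
        "u_shape": bool(inner and deep),
    }
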