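"""Shannon entropy of centrality distributions and graph energies.

Graph energies are sums of absolute eigenvalues of a matrix representation:
the adjacency matrix (graph energy), the degree-normalized Randic matrix
(Randic energy), and the Laplacian shifted by the mean degree 2m/n (Laplacian
energy). Each statistic is normalized against uniform random graphs with the
same node and edge counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .simulate import make_random_graph

__all__ = [
    "shannon_entropy",
    "graph_energy",
    "randic_energy",
    "laplacian_energy",
    "EnergyReport",
    "normalized_report",
]


def shannon_entropy(values) -> float:
    """Entropy -sum q_k log q_k of the normalized nonnegative measure vector.

    Zero entries contribute 0 (0 log 0 := 0); natural log. A network whose
    degree (or betweenness) mass is concentrated on few genes has low entropy.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0 or np.any(v < 0):
        raise ValueError("values must be nonnegative and non-empty")
    total = v.sum()
    if total <= 0:
        raise ValueError("at least one value must be positive")
    q = v[v > 0] / total
    return float(-(q * np.log(q)).sum())


def _adjacency(net: nx.Graph) -> np.ndarray:
    nodes = list(net.nodes())
    return nx.to_numpy_array(net, nodelist=nodes)


def graph_energy(net: nx.Graph) -> float:
    """Sum of absolute adjacency eigenvalues; 2(n-1) for K_n."""
    if net.number_of_nodes() == 0:
        return 0.0
    return float(np.abs(np.linalg.eigvalsh(_adjacency(net))).sum())


def randic_energy(net: nx.Graph) -> float:
    """Sum of absolute eigenvalues of the Randic matrix 1/sqrt(d_i d_j).

    Isolated nodes contribute zero rows; equals 2 for any complete graph.
    """
    if net.number_of_nodes() == 0:
        return 0.0
    A = _adjacency(net)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    R = A * np.outer(inv_sqrt, inv_sqrt)
    return float(np.abs(np.linalg.eigvalsh(R)).sum())


def laplacian_energy(net: nx.Graph) -> float:
    """Sum of |lambda_i - 2m/n| over Laplacian (D - A) eigenvalues."""
    n = net.number_of_nodes()
    if n == 0:
        return 0.0
    A = _adjacency(net)
    L = np.diag(A.sum(axis=1)) - A
    m = net.number_of_edges()
    lam = np.linalg.eigvalsh(L)
    return float(np.abs(lam - 2.0 * m / n).sum())


@dataclass
class EnergyReport:
    entropy_degree: float
    entropy_betweenness: float
    energy_adjacency: float
    energy_randic: float
    energy_laplacian: float
    random_mean: dict
    random_sd: dict
    normalized: dict


_METRICS = (
    "entropy_degree",
    "entropy_betweenness",
    "energy_adjacency",
    "energy_randic",
    "energy_laplacian",
)


def _metrics_of(net: nx.Graph) -> dict:
    degs = [d for _, d in net.degree()]
    btw = list(nx.betweenness_centrality(net, normalized=False).values())
    ent_deg = shannon_entropy(degs) if any(d > 0 for d in degs) else np.nan
    ent_btw = shannon_entropy(btw) if any(b > 0 for b in btw) else np.nan
    return {
        "entropy_degree": ent_deg,
        "entropy_betweenness": ent_btw,
        "energy_adjacency": graph_energy(net),
        "energy_randic": randic_energy(net),
        "energy_laplacian": laplacian_energy(net),
    }


def normalized_report(
    net: nx.Graph, n_random: int = 100, seed: int = 0, mode: str = "ratio"
) -> EnergyReport:
    """Entropies/energies of ``net`` normalized against matched random graphs.

    ``mode='ratio'`` divides each metric by its null mean; ``mode='zscore'``
    reports (value - null mean) / null sd instead.
    """
    if n_random < 10:
        raise ValueError("n_random must be at least 10")
    obs = _metrics_of(net)
    n, m = net.number_of_nodes(), net.number_of_edges()
    null = {k: [] for k in _METRICS}
    for r in range(n_random):
        g = make_random_graph(n, m, seed=seed + r)
        for k, v in _metrics_of(g).items():
            null[k].append(v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN degenerate nulls
        mean = {k: float(np.nanmean(null[k])) for k in _METRICS}
        sd = {k: float(np.nanstd(null[k])) for k in _METRICS}

    def ratio(o, m):
        if np.isnan(o) and np.isnan(m):
            return 1.0  # degenerate in both (e.g. all-zero betweenness on K_n)
        if m == 0.0:
            return 1.0 if o == 0.0 else np.nan
        return o / m

    def zscore(o, m, s):
        if np.isnan(o) and np.isnan(m):
            return 0.0
        if s > 0:
            return (o - m) / s
        return 0.0 if o == m else np.nan

    if mode == "ratio":
        norm = {k: ratio(obs[k], mean[k]) for k in _METRICS}
    elif mode == "zscore":
        norm = {k: zscore(obs[k], mean[k], sd[k]) for k in _METRICS}
    else:
        raise ValueError("mode must be 'ratio' or 'zscore'")
    return EnergyReport(
        obs["entropy_degree"],
        obs["entropy_betweenness"],
        obs["energy_adjacency"],
        obs["energy_randic"],
        obs["energy_laplacian"],
        mean,
        sd,
        norm,
    )
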