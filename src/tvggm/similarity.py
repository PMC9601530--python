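"""Network similarity (CNSI) and hierarchical staging of the time series.

CNSI scores two networks gene by gene as the Jaccard overlap of first-neighbor
sets; the network-level similarity is the sum over genes. Hierarchically
clustering the T x T similarity matrix groups the time points into
differentiation stages (stable / transition / stable on a three-phase course).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import average
from scipy.sparse import diags
from scipy.spatial.distance import squareform
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

__all__ = ["SimilarityMatrix", "cnsi", "similarity_matrix", "cluster_stages"]


@dataclass
class SimilarityMatrix:
    scores: np.ndarray  # (T, T), symmetric
    times: np.ndarray
    stage_labels: np.ndarray | None = None
    n_stages: int | None = None
    linkage_tree: np.ndarray | None = None


def cnsi(
    net_a: nx.Graph, net_b: nx.Graph, empty_union: str = "one"
) -> tuple[dict, float]:
    """Per-gene first-neighbor Jaccard overlap between two networks.

    The raw formula is 0/0 for a gene isolated in both networks. The default
    convention scores such genes 1 — their (empty) neighbor sets are
    identical, so two sparse networks that agree on which genes are
    disconnected count as similar, and self-similarity always attains the
    maximum (the gene count). ``empty_union='zero'`` scores them 0 instead,
    and ``'drop'`` excludes them from the sum. Returns (per-gene scores, sum).
    """
    if set(net_a.nodes()) != set(net_b.nodes()):
        raise ValueError("networks must share the same gene universe")
    if empty_union not in ("one", "zero", "drop"):
        raise ValueError("empty_union must be 'one', 'zero' or 'drop'")
    scores = {}
    total = 0.0
    for g in net_a.nodes():
        na, nb = set(net_a.neighbors(g)), set(net_b.neighbors(g))
        union = na | nb
        if not union:
            if empty_union == "one":
                scores[g] = 1.0
                total += 1.0
            elif empty_union == "zero":
                scores[g] = 0.0
            continue
        s = len(na & nb) / len(union)
        scores[g] = s
        total += s
    return scores, total


def similarity_matrix(series, empty_union: str = "one") -> SimilarityMatrix:
    """All pairwise CNSI sums over a network series (symmetric by construction)."""
    graphs = series.to_graphs() if hasattr(series, "to_graphs") else list(series)
    if len(graphs) < 2:
        raise ValueError("need at least two networks")
    T = len(graphs)
    times = (
        series.times if hasattr(series, "times") else np.arange(T, dtype=float)
    )
    scores = np.zeros((T, T))
    for i in range(T):
        for j in range(i, T):
            _, s = cnsi(graphs[i], graphs[j], empty_union=empty_union)
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(scores=scores, times=np.asarray(times, float))


def cluster_stages(
    sim: SimilarityMatrix, k: int | str = "auto", min_stage_frac: float = 0.2
) -> np.ndarray:
    """Agglomerative (average-linkage) staging of time points.

    Dissimilarity is (max score - score). Stages are contiguous pseudo-time
    intervals by definition, so merging is restricted to time-adjacent
    clusters. With ``k='auto'`` the stage count maximizes the mean silhouette
    over k in 2..6 among cuts whose smallest stage holds at least
    ``min_stage_frac`` of the time points (a differentiation stage is a
    macroscopic interval, not a couple of boundary networks); if no cut
    qualifies, the size floor is dropped. Labels are renumbered in time
    order. The unconstrained average-linkage merge history is recorded in
    ``sim.linkage_tree``.
    """
    S = sim.scores
    T = S.shape[0]
    dis = S.max() - S
    np.fill_diagonal(dis, 0.0)
    dis = 0.5 * (dis + dis.T)
    if np.allclose(dis, 0.0):
        warnings.warn("all networks equally similar; returning a single stage")
        sim.stage_labels = np.zeros(T, dtype=int)
        sim.n_stages = 1
        return sim.stage_labels
    sim.linkage_tree = average(squareform(dis, checks=False))
    conn = diags([np.ones(T - 1), np.ones(T - 1)], [-1, 1]).tocsr()

    def cut(kk: int) -> np.ndarray:
        ac = AgglomerativeClustering(
            n_clusters=kk, metric="precomputed", linkage="average", connectivity=conn
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # connectivity fragmentation notice
            return ac.fit_predict(dis)

    if k == "auto":
        min_size = int(np.ceil(min_stage_frac * T))
        candidates = []
        for kk in range(2, min(6, T - 1) + 1):
            labels = cut(kk)
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(dis, labels, metric="precomputed")
            ok_size = np.bincount(labels).min() >= min_size
            candidates.append((ok_size, sil, kk, labels))
        sized = [c for c in candidates if c[0]]
        pool = sized if sized else candidates
        if not pool:
            labels = np.zeros(T, dtype=int)
        else:
            labels = max(pool, key=lambda c: c[1])[3]
    else:
        labels = cut(int(k))
    remap, out = {}, np.empty(T, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    sim.stage_labels = out
    sim.n_stages = len(remap)
    return out
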