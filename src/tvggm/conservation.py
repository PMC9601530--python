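"""Cross-species comparison of aggregated time-varying networks.

Each species' network series is collapsed by union into an aggregated network
whose edges carry time-occurrence counts. Species are compared at the
centrality level (Pearson correlation of time-averaged centralities over
ortholog pairs) and at the edge level (Fisher's exact test over the common
gene-pair universe). The aggregated networks are transformed into a dual
hypergraph (edges become nodes, linked when they share a gene; occurrence
counts become node attributes) in which a greedy heuristic extracts a
connected high-occurrence conserved module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, pearsonr, spearmanr

from .properties import centralities

__all__ = [
    "AggregatedNetwork",
    "DualHypergraph",
    "ConservedModule",
    "aggregate_network",
    "centrality_correlation",
    "edge_overlap_test",
    "dual_hypergraph",
    "find_conserved_module",
    "compare_orderings",
]

Edge = tuple[str, str]


def _norm_edge(a, b) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class AggregatedNetwork:
    """Union of a network series with per-edge time-occurrence counts."""

    occurrence: dict[Edge, int]
    genes: list[str]
    n_times: int

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(self.occurrence)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for (a, b), occ in self.occurrence.items():
            g.add_edge(a, b, occurrence=occ)
        return g


def aggregate_network(series) -> AggregatedNetwork:
    """Collapse a series by edge union, counting time points per edge."""
    graphs = series.to_graphs() if hasattr(series, "to_graphs") else list(series)
    if not graphs:
        raise ValueError("series is empty")
    genes = (
        list(series.gene_names)
        if hasattr(series, "gene_names")
        else list(graphs[0].nodes())
    )
    occ: dict[Edge, int] = {}
    for g in graphs:
        for a, b in g.edges():
            e = _norm_edge(a, b)
            occ[e] = occ.get(e, 0) + 1
    return AggregatedNetwork(occ, genes, len(graphs))


def centrality_correlation(
    series_a, series_b, ortholog_map: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of time-averaged centralities across orthologs.

    Centralities (degree, betweenness, PageRank, h-index) are computed per
    time-point network and averaged over time for each species, then
    correlated over the ortholog-mapped genes. Returns one row per measure
    with r and the p value.
    """
    mapped = _map_pairs(ortholog_map)
    if len(mapped) < 3:
        raise ValueError("need at least 3 mapped gene pairs")
    mean_a = _mean_centralities(series_a)
    mean_b = _mean_centralities(series_b)
    rows = []
    ga = [a for a, b in mapped if a in mean_a.index and b in mean_b.index]
    gb = [b for a, b in mapped if a in mean_a.index and b in mean_b.index]
    if len(ga) < 3:
        raise ValueError("need at least 3 mapped genes present in both series")
    for measure in ("degree", "betweenness", "pagerank", "h_index"):
        xa = mean_a.loc[ga, measure].to_numpy()
        xb = mean_b.loc[gb, measure].to_numpy()
        if np.std(xa) == 0 or np.std(xb) == 0:
            rows.append({"measure": measure, "r": np.nan, "p": np.nan})
            continue
        r, p = pearsonr(xa, xb)
        rows.append({"measure": measure, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("measure")


def _mean_centralities(series) -> pd.DataFrame:
    graphs = series.to_graphs() if hasattr(series, "to_graphs") else list(series)
    tables = [centralities(g) for g in graphs]
    return sum(tables) / len(tables)


def _map_pairs(ortholog_map: pd.DataFrame) -> list[tuple[str, str]]:
    cols = list(ortholog_map.columns[:2])
    return list(zip(ortholog_map[cols[0]], ortholog_map[cols[1]]))


def edge_overlap_test(
    agg_a: AggregatedNetwork,
    agg_b: AggregatedNetwork,
    ortholog_map: pd.DataFrame,
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Edge-level overlap between species over the common gene-pair universe.

    Species B edges are mapped into species A's namespace; the universe is all
    g(g-1)/2 pairs of the mapped common genes. Reports the 2x2 table, Fisher's
    exact (hypergeometric) p, the sample odds ratio (with a Haldane-Anscombe
    0.5-corrected companion when a cell is zero), and the overlap fold
    observed/expected under independence; optionally a permutation fold
    distribution over random edge relabelings.
    """
    b_to_a = {b: a for a, b in _map_pairs(ortholog_map)}
    genes = [g for g in agg_a.genes if g in set(b_to_a.values())]
    gset = set(genes)
    edges_a = {e for e in agg_a.edges if e[0] in gset and e[1] in gset}
    edges_b = set()
    for x, y in agg_b.edges:
        if x in b_to_a and y in b_to_a:
            e = _norm_edge(b_to_a[x], b_to_a[y])
            if e[0] in gset and e[1] in gset:
                edges_b.add(e)
    if not edges_a or not edges_b:
        raise ValueError("both species must contribute at least one mapped edge")
    g = len(genes)
    universe = g * (g - 1) // 2
    both = len(edges_a & edges_b)
    only_a = len(edges_a) - both
    only_b = len(edges_b) - both
    neither = universe - both - only_a - only_b
    table = np.array([[both, only_a], [only_b, neither]])
    odds, p = fisher_exact(table, alternative="greater")
    if only_a == 0 or only_b == 0 or neither == 0 or both == 0:
        tc = table + 0.5
        odds_corrected = float(tc[0, 0] * tc[1, 1] / (tc[0, 1] * tc[1, 0]))
    else:
        odds_corrected = float(odds)
    expected = len(edges_a) * len(edges_b) / universe
    fold = both / expected
    out = {
        "table": table,
        "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
        "odds_ratio_corrected": odds_corrected,
        "fisher_p": float(p),
        "overlap_fold": float(fold),
        "n_overlap": both,
        "universe": universe,
    }
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(g, k=1)
        folds = np.empty(n_permutations)
        for t in range(n_permutations):
            pick = rng.choice(universe, size=len(edges_b), replace=False)
            eb = {(genes[iu[i]], genes[ju[i]]) for i in pick}
            folds[t] = len(edges_a & eb) / expected
        out["permutation_fold_mean"] = float(folds.mean())
        out["permutation_p"] = float((folds >= fold).mean())
    return out


@dataclass
class DualHypergraph:
    """Edges of the aggregated network become nodes; shared genes become links."""

    graph: nx.Graph  # nodes are Edge tuples with attribute 'occurrence'

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    def to_gene_network(self, nodes=None) -> nx.Graph:
        g = nx.Graph()
        for e in nodes if nodes is not None else self.graph.nodes():
            g.add_edge(e[0], e[1], occurrence=self.graph.nodes[e]["occurrence"])
        return g


def dual_hypergraph(
    agg_a: AggregatedNetwork,
    agg_b: AggregatedNetwork | None = None,
    ortholog_map: pd.DataFrame | None = None,
) -> DualHypergraph:
    """Transform aggregated network(s) into the dual hypergraph.

    One node per aggregated edge, attributed with its occurrence count; two
    nodes are linked iff the underlying edges share a gene. With two species,
    nodes are the ortholog-mapped edges present in both, attributed with the
    summed occurrence counts (unmatched edges are dropped).
    """
    if agg_b is None:
        attrs = dict(agg_a.occurrence)
    else:
        if ortholog_map is None:
            raise ValueError("ortholog_map required to combine two species")
        b_to_a = {b: a for a, b in _map_pairs(ortholog_map)}
        occ_b: dict[Edge, int] = {}
        for (x, y), occ in agg_b.occurrence.items():
            if x in b_to_a and y in b_to_a:
                occ_b[_norm_edge(b_to_a[x], b_to_a[y])] = occ
        attrs = {
            e: occ + occ_b[e] for e, occ in agg_a.occurrence.items() if e in occ_b
        }
    g = nx.Graph()
    for e, occ in attrs.items():
        g.add_node(e, occurrence=occ)
    nodes = list(attrs)
    by_gene: dict[str, list[Edge]] = {}
    for e in nodes:
        by_gene.setdefault(e[0], []).append(e)
        by_gene.setdefault(e[1], []).append(e)
    for members in by_gene.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j])
    return DualHypergraph(g)


@dataclass
class ConservedModule:
    genes: list[str]
    hyper_nodes: list[Edge]
    node_scores: dict[Edge, float]
    total_score: float

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.hyper_nodes)
        return g


def module_score(hg: DualHypergraph, nodes, tau: float) -> float:
    return sum(hg.graph.nodes[e]["occurrence"] - tau for e in nodes)


def find_conserved_module(
    hg: DualHypergraph, background_tau: float | None = None
) -> ConservedModule:
    """Greedy connected sub-hypergraph of maximal summed (occurrence - tau).

    Node score is occurrence minus the background ``tau`` (default: mean
    occurrence). From each positive-score seed, the search repeatedly applies
    the best score-improving move — adding a neighbor, adding a
    neighbor-plus-one-of-its-neighbors (so isolated positives reachable
    through one negative node are not missed), or removing a non-articulation
    node — until no move improves; the best run over all seeds is returned.
    Deterministic given the input.
    """
    g = hg.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty hypergraph")
    occ = {e: g.nodes[e]["occurrence"] for e in g.nodes()}
    tau = float(np.mean(list(occ.values()))) if background_tau is None else background_tau
    score = {e: occ[e] - tau for e in g.nodes()}
    seeds = sorted((e for e in g.nodes() if score[e] > 0), key=lambda e: (-score[e], e))
    if not seeds:
        warnings.warn("all node scores nonpositive; returning an empty module")
        return ConservedModule([], [], score, 0.0)

    def grow(seed):
        current = {seed}
        total = score[seed]
        while True:
            best_gain, best_move = 0.0, None
            boundary = sorted(
                {v for u in current for v in g.neighbors(u)} - current, key=str
            )
            for v in boundary:
                gain = score[v]
                if gain > best_gain + 1e-12:
                    best_gain, best_move = gain, ("add", (v,))
                # two-step lookahead through v
                nxt = sorted(set(g.neighbors(v)) - current - {v}, key=str)
                for w in nxt:
                    gain2 = score[v] + score[w]
                    if gain2 > best_gain + 1e-12:
                        best_gain, best_move = gain2, ("add", (v, w))
            if len(current) > 1:
                sub = g.subgraph(current)
                arts = set(nx.articulation_points(sub))
                for v in sorted(current - arts, key=str):
                    gain = -score[v]
                    if gain > best_gain + 1e-12:
                        best_gain, best_move = gain, ("remove", (v,))
            if best_move is None:
                return current, total
            kind, nodes_ = best_move
            if kind == "add":
                current |= set(nodes_)
                total += sum(score[v] for v in nodes_)
            else:
                current -= set(nodes_)
                total -= sum(score[v] for v in nodes_)

    best_set, best_total = set(), -np.inf
    for seed in seeds:
        cand, tot = grow(seed)
        if tot > best_total + 1e-12:
            best_set, best_total = cand, tot
    nodes = sorted(best_set)
    genes = sorted({g_ for e in nodes for g_ in e})
    return ConservedModule(genes, nodes, score, float(best_total))


def compare_orderings(pt_a: pd.Series, pt_b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation between two pseudo-time orderings."""
    pt_a, pt_b = pd.Series(pt_a), pd.Series(pt_b)
    if set(pt_a.index) != set(pt_b.index):
        raise ValueError("the two orderings must cover the same cells")
    pt_b = pt_b.reindex(pt_a.index)
    r, p = spearmanr(pt_a.to_numpy(), pt_b.to_numpy())
    return float(r), float(p)
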