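"""Aggregation, cross-species comparison, dual hypergraph, module search."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from tvggm.conservation import (
    AggregatedNetwork,
    aggregate_network,
    centrality_correlation,
    compare_orderings,
    dual_hypergraph,
    edge_overlap_test,
    find_conserved_module,
    module_score,
)


def graph_on(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


GENES = [f"G{i}" for i in range(6)]


class TestAggregate:
    def test_identical_networks_counted_fully(self):
        g = graph_on(GENES, [("G0", "G1"), ("G2", "G3")])
        agg = aggregate_network([g] * 25)
        assert agg.edges == {("G0", "G1"), ("G2", "G3")}
        assert all(v == 25 for v in agg.occurrence.values())

    def test_alternating_disjoint_edges(self):
        a = graph_on(GENES, [("G0", "G1")])
        b = graph_on(GENES, [("G2", "G3")])
        agg = aggregate_network([a, b] * 5)
        assert agg.occurrence[("G0", "G1")] == 5
        assert agg.occurrence[("G2", "G3")] == 5

    def test_counts_match_bruteforce_tally(self, rng):
        graphs = [nx.gnm_random_graph(6, 5, seed=s) for s in range(8)]
        agg = aggregate_network(graphs)
        for e, occ in agg.occurrence.items():
            tally = sum(g.has_edge(*e) for g in graphs)
            assert occ == tally

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            aggregate_network([])


class TestCentralityCorrelation:
    def test_relabeled_copy_gives_unit_correlation(self):
        graphs = [nx.gnm_random_graph(8, 10, seed=s) for s in range(4)]
        mapping = {i: f"m{i}" for i in range(8)}
        graphs_b = [nx.relabel_nodes(g, mapping) for g in graphs]
        omap = pd.DataFrame(
            {"species_a": list(range(8)), "species_b": [f"m{i}" for i in range(8)]}
        )
        out = centrality_correlation(graphs, graphs_b, omap)
        for m in out.index:
            assert out.loc[m, "r"] == pytest.approx(1.0)

    def test_too_few_mapped_genes_rejected(self):
        omap = pd.DataFrame({"a": ["G0"], "b": ["g0"]})
        with pytest.raises(ValueError):
            centrality_correlation([], [], omap)


class TestEdgeOverlap:
    def make_agg(self, edges, genes=("G0", "G1", "G2", "G3")):
        return AggregatedNetwork({e: 1 for e in edges}, list(genes), 1)

    def test_worked_four_gene_fixture(self):
        # A = {01, 02}, B = {02, 03} over 6 possible pairs
        agg_a = self.make_agg([("G0", "G1"), ("G0", "G2")])
        agg_b = self.make_agg([("G0", "G2"), ("G0", "G3")])
        omap = pd.DataFrame(
            {"a": ["G0", "G1", "G2", "G3"], "b": ["G0", "G1", "G2", "G3"]}
        )
        out = edge_overlap_test(agg_a, agg_b, omap)
        np.testing.assert_array_equal(out["table"], [[1, 1], [1, 3]])
        assert out["odds_ratio"] == pytest.approx(3.0)
        # one-sided hypergeometric enumeration: P(X >= 1), X ~ HG(6, 2, 2)
        expected_p = 1.0 - hypergeom.pmf(0, 6, 2, 2)
        assert out["fisher_p"] == pytest.approx(expected_p)
        assert out["overlap_fold"] == pytest.approx(1 / (2 * 2 / 6))

    def test_fisher_matches_hypergeometric_on_random_sets(self, rng):
        genes = [f"G{i}" for i in range(10)]  # universe of 45 pairs
        pairs = list(itertools.combinations(genes, 2))
        omap = pd.DataFrame({"a": genes, "b": genes})
        for s in range(5):
            rs = np.random.default_rng(s)
            ea = [pairs[i] for i in rs.choice(45, size=8, replace=False)]
            eb = [pairs[i] for i in rs.choice(45, size=12, replace=False)]
            out = edge_overlap_test(self.make_agg(ea, genes), self.make_agg(eb, genes), omap)
            k = out["n_overlap"]
            p_exact = hypergeom.sf(k - 1, 45, 8, 12)
            assert out["fisher_p"] == pytest.approx(p_exact, rel=1e-9)

    def test_identical_edge_sets_flagged_infinite(self):
        agg = self.make_agg([("G0", "G1"), ("G2", "G3")])
        omap = pd.DataFrame(
            {"a": ["G0", "G1", "G2", "G3"], "b": ["G0", "G1", "G2", "G3"]}
        )
        out = edge_overlap_test(agg, agg, omap)
        assert out["odds_ratio"] == np.inf
        assert np.isfinite(out["odds_ratio_corrected"])
        assert out["overlap_fold"] == pytest.approx(6 / 2)

    def test_independent_sets_fold_near_one(self):
        genes = [f"G{i}" for i in range(12)]
        pairs = list(itertools.combinations(genes, 2))
        omap = pd.DataFrame({"a": genes, "b": genes})
        folds = []
        for s in range(40):
            rs = np.random.default_rng(100 + s)
            ea = [pairs[i] for i in rs.choice(len(pairs), size=15, replace=False)]
            eb = [pairs[i] for i in rs.choice(len(pairs), size=15, replace=False)]
            out = edge_overlap_test(
                self.make_agg(ea, genes), self.make_agg(eb, genes), omap
            )
            folds.append(out["overlap_fold"])
        assert abs(np.mean(folds) - 1.0) < 0.25

    def test_empty_edges_rejected(self):
        omap = pd.DataFrame({"a": ["G0", "G1"], "b": ["G0", "G1"]})
        with pytest.raises(ValueError):
            edge_overlap_test(
                self.make_agg([]), self.make_agg([("G0", "G1")]), omap
            )


class TestDualHypergraph:
    def test_two_edge_worked_example(self):
        agg = AggregatedNetwork(
            {("G1", "G3"): 3, ("G1", "G2"): 2}, ["G1", "G2", "G3"], 25
        )
        hg = dual_hypergraph(agg)
        assert hg.node_count == 2
        assert hg.graph.number_of_edges() == 1
        assert hg.graph.nodes[("G1", "G3")]["occurrence"] == 3
        assert hg.graph.nodes[("G1", "G2")]["occurrence"] == 2

    def test_triangle_gives_three_nodes_three_links(self):
        agg = AggregatedNetwork(
            {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1}, ["A", "B", "C"], 1
        )
        hg = dual_hypergraph(agg)
        assert hg.node_count == 3
        assert hg.graph.number_of_edges() == 3

    def test_links_match_shared_endpoint_oracle(self, rng):
        g = nx.gnm_random_graph(8, 10, seed=12)
        agg = aggregate_network([g])
        hg = dual_hypergraph(agg)
        edges = list(agg.edges)
        for e1, e2 in itertools.combinations(edges, 2):
            shares = bool(set(e1) & set(e2))
            assert hg.graph.has_edge(e1, e2) == shares

    def test_round_trip_identity(self, rng):
        g = nx.gnm_random_graph(9, 14, seed=3)
        agg = aggregate_network([g])
        hg = dual_hypergraph(agg)
        back = hg.to_gene_network()
        assert {tuple(sorted(e)) for e in back.edges()} == set(agg.edges)

    def test_two_species_attributes_summed_and_unmatched_dropped(self):
        agg_a = AggregatedNetwork({("G0", "G1"): 3, ("G1", "G2"): 2}, ["G0", "G1", "G2"], 25)
        agg_b = AggregatedNetwork({("g0", "g1"): 4, ("g0", "g2"): 1}, ["g0", "g1", "g2"], 25)
        omap = pd.DataFrame({"a": ["G0", "G1", "G2"], "b": ["g0", "g1", "g2"]})
        hg = dual_hypergraph(agg_a, agg_b, omap)
        assert set(hg.graph.nodes()) == {("G0", "G1")}
        assert hg.graph.nodes[("G0", "G1")]["occurrence"] == 7


def chain_hypergraph(scores):
    """Dual hypergraph of a gene path; node i is edge (G_i, G_{i+1}).

    Consecutive path edges share a gene, so the dual nodes form a chain.
    Occurrences are set to the desired scores (tau = 0 in the tests).
    """
    occ = {(f"G{i}", f"G{i + 1}"): s for i, s in enumerate(scores)}
    genes = [f"G{i}" for i in range(len(scores) + 1)]
    return dual_hypergraph(AggregatedNetwork(occ, genes, 1))


def exhaustive_best(hg, tau):
    nodes = list(hg.graph.nodes())
    best = -np.inf
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not nx.is_connected(hg.graph.subgraph(sub)):
                continue
            best = max(best, module_score(hg, sub, tau))
    return best


class TestConservedModule:
    def test_single_positive_node(self):
        hg = chain_hypergraph([5.0])
        mod = find_conserved_module(hg, background_tau=0.0)
        assert mod.hyper_nodes == [("G0", "G1")]
        assert mod.total_score == pytest.approx(5.0)

    def test_chain_with_negative_bridges_reaches_optimum(self):
        hg = chain_hypergraph([2, -1, 2, -1, 2])
        mod = find_conserved_module(hg, background_tau=0.0)
        opt = exhaustive_best(hg, 0.0)
        assert opt == pytest.approx(4.0)
        assert mod.total_score >= 0.9 * opt

    def test_greedy_within_90pct_of_exhaustive_on_small_instances(self):
        for s in range(8):
            rs = np.random.default_rng(s)
            g = nx.gnm_random_graph(10, 16, seed=s)
            hg_graph = nx.Graph()
            mapping = {i: (f"X{i}", f"Y{i}") for i in g.nodes()}
            for i in g.nodes():
                hg_graph.add_node(mapping[i], occurrence=float(rs.normal(0.5, 2.0)))
            for u, v in g.edges():
                hg_graph.add_edge(mapping[u], mapping[v])
            from tvggm.conservation import DualHypergraph

            hg = DualHypergraph(hg_graph)
            if all(hg_graph.nodes[n]["occurrence"] <= 0 for n in hg_graph.nodes()):
                continue
            mod = find_conserved_module(hg, background_tau=0.0)
            opt = exhaustive_best(hg, 0.0)
            assert mod.total_score >= 0.9 * opt - 1e-9

    def test_deterministic(self):
        hg = chain_hypergraph([1, 2, -1, 3, -2, 1])
        m1 = find_conserved_module(hg, background_tau=0.0)
        m2 = find_conserved_module(hg, background_tau=0.0)
        assert m1.hyper_nodes == m2.hyper_nodes

    def test_module_connected_in_both_representations(self):
        hg = chain_hypergraph([2, 1, 2])
        mod = find_conserved_module(hg, background_tau=0.0)
        assert nx.is_connected(hg.graph.subgraph(mod.hyper_nodes))
        assert nx.is_connected(mod.to_graph())

    def test_all_negative_scores_warns_empty(self):
        hg = chain_hypergraph([-1, -2])
        with pytest.warns(UserWarning):
            mod = find_conserved_module(hg, background_tau=0.0)
        assert mod.genes == []


class TestCompareOrderings:
    def test_identical_orderings(self):
        pt = pd.Series([0.1, 0.5, 0.9], index=["c1", "c2", "c3"])
        r, p = compare_orderings(pt, pt)
        assert r == pytest.approx(1.0)

    def test_reversed_orderings(self):
        pt = pd.Series([0.1, 0.5, 0.9], index=["c1", "c2", "c3"])
        r, _ = compare_orderings(pt, 1.0 - pt)
        assert r == pytest.approx(-1.0)

    def test_monotone_transform_matches_rank_oracle(self, rng):
        n = 50
        x = rng.random(n)
        y = np.exp(3 * x) + rng.normal(0, 0.1, n)
        idx = [f"c{i}" for i in range(n)]
        r, _ = compare_orderings(pd.Series(x, index=idx), pd.Series(y, index=idx))
        rx = pd.Series(x).rank()
        ry = pd.Series(y).rank()
        expected = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_mismatched_cells_rejected(self):
        a = pd.Series([0.1], index=["c1"])
        b = pd.Series([0.1], index=["c2"])
        with pytest.raises(ValueError):
            compare_orderings(a, b)


class TestPairedSpeciesAnalyses:
    def test_conserved_core_drives_degree_correlation(self):
        from tvggm.simulate import TVGGMSpec, make_paired_species

        spec = TVGGMSpec(
            n_genes=30,
            n_cells=100,
            edge_density_per_phase=(0.06, 0.02, 0.06),
            partial_corr_strength=0.3,
            conserved_core_fraction=0.8,
            seed=21,
        )
        pair = make_paired_species(spec)

        def true_series(truth):
            graphs = []
            for es in truth.true_edge_sets:
                g = graph_on(truth.gene_names, list(es))
                graphs.append(g)
            return graphs

        out = centrality_correlation(
            true_series(pair.truth_a), true_series(pair.truth_b), pair.ortholog_map
        )
        assert out.loc["degree", "r"] > 0
        assert out.loc["degree", "p"] < 0.05

    def test_module_recovers_implanted_high_occurrence_core(self):
        # a persistent core path shared by both species plus shared transient
        # noise edges; the module search should return the core genes
        rng = np.random.default_rng(13)
        genes_a = [f"G{i}" for i in range(20)]
        genes_b = [f"m{i}" for i in range(20)]
        omap = pd.DataFrame({"a": genes_a, "b": genes_b})
        core = [(f"G{i}", f"G{i+1}") for i in range(8)]
        noise_pool = [
            ("G10", "G11"), ("G12", "G13"), ("G14", "G15"), ("G16", "G17"),
            ("G18", "G19"), ("G10", "G12"), ("G14", "G16"), ("G11", "G18"),
        ]
        T = 25
        occ_a = {e: T for e in core}
        occ_b = {(f"m{x[1:]}", f"m{y[1:]}"): T for x, y in core}
        for e in noise_pool:
            occ_a[e] = 2
            occ_b[(f"m{e[0][1:]}", f"m{e[1][1:]}")] = 2
        agg_a = AggregatedNetwork(occ_a, genes_a, T)
        agg_b = AggregatedNetwork(occ_b, genes_b, T)
        hg = dual_hypergraph(agg_a, agg_b, omap)
        mod = find_conserved_module(hg)
        core_genes = {g for e in core for g in e}
        recovered = len(core_genes & set(mod.genes)) / len(core_genes)
        assert recovered >= 0.8
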