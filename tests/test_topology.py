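"""Node topology battery vs independent brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

import ncbroker as nb
from ncbroker.errors import ConfigurationError


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def oracle_clustering(graph, node):
    nbrs = list(graph.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for a, b in itertools.combinations(nbrs, 2) if graph.has_edge(a, b))
    return links / (k * (k - 1) / 2)


def oracle_effective_size(graph, node):
    """Full Burt redundancy formula with indicator weights."""
    nbrs = list(graph.neighbors(node))
    k = len(nbrs)
    if k == 0:
        return 0.0
    total = 0.0
    for j in nbrs:
        redundancy = 0.0
        for q in nbrs:
            if q == j:
                continue
            p_iq = 1.0 / k
            m_jq = 1.0 if graph.has_edge(j, q) else 0.0
            redundancy += p_iq * m_jq
        total += 1.0 - redundancy
    return total


def oracle_local_efficiency(graph, node):
    """Floyd–Warshall over the neighbor-induced subgraph (node excluded)."""
    nbrs = list(graph.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    idx = {v: i for i, v in enumerate(nbrs)}
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(k)] for i in range(k)]
    for a, b in itertools.combinations(nbrs, 2):
        if graph.has_edge(a, b):
            dist[idx[a]][idx[b]] = dist[idx[b]][idx[a]] = 1
    for m in range(k):
        for i in range(k):
            for j in range(k):
                if dist[i][m] + dist[m][j] < dist[i][j]:
                    dist[i][j] = dist[i][m] + dist[m][j]
    total = sum(
        1.0 / dist[i][j]
        for i in range(k)
        for j in range(i + 1, k)
        if dist[i][j] < inf
    )
    return total / (k * (k - 1) / 2)


def oracle_articulation_points(graph):
    out = set()
    base = nx.number_connected_components(graph)
    for v in graph.nodes:
        h = graph.copy()
        h.remove_node(v)
        if h.number_of_nodes() and nx.number_connected_components(h) > base:
            out.add(v)
    return out


def oracle_bridges(graph):
    out = set()
    base = nx.number_connected_components(graph)
    for e in graph.edges:
        h = graph.copy()
        h.remove_edge(*e)
        if nx.number_connected_components(h) > base:
            out.add(frozenset(e))
    return out


# ---------------------------------------------------------------------------
# hand-checkable cases
# ---------------------------------------------------------------------------

class TestSmallCases:
    def test_triangle(self):
        g = nx.cycle_graph(3)
        assert nb.clustering_coefficient(g, 0) == 1.0
        assert nb.effective_size(g, 0) == pytest.approx(1.0)
        assert nb.local_efficiency(g, 0) == 1.0
        assert nb.brokerage(g, 0) == pytest.approx(1.0)

    def test_star_center(self):
        g = nx.star_graph(4)
        assert nb.clustering_coefficient(g, 0) == 0.0
        assert nb.effective_size(g, 0) == pytest.approx(4.0)
        assert nb.local_efficiency(g, 0) == 0.0
        assert nb.brokerage(g, 0) == pytest.approx(4.0)

    def test_path_interior_node(self):
        g = nx.path_graph(3)
        assert nb.local_efficiency(g, 1) == 0.0
        assert nb.brokerage(g, 1) == pytest.approx(2.0)
        points, bridges = nb.articulation_and_bridges(g)
        assert points == {1}
        assert bridges == {frozenset((0, 1)), frozenset((1, 2))}

    def test_neighbor_subgraph_excludes_the_node(self):
        """G_i is a 3-path: distances 1, 1, 2 -> E = (1+1+0.5)/3."""
        g = nx.Graph([("c", "a"), ("c", "b"), ("c", "d"), ("a", "b"), ("b", "d")])
        assert nb.local_efficiency(g, "c") == pytest.approx((1 + 1 + 0.5) / 3)

    def test_cycle_has_no_cut_elements(self):
        g = nx.cycle_graph(6)
        points, bridges = nb.articulation_and_bridges(g)
        assert points == set() and bridges == set()

    def test_isolated_and_pendant_conventions(self):
        g = nx.Graph()
        g.add_node("a")
        g.add_edge("b", "c")
        assert nb.brokerage(g, "a") == 0.0
        assert nb.effective_size(g, "a") == 0.0
        assert nb.brokerage(g, "b") == 1.0

    def test_normalized_brokerage_degenerate_and_barbell(self):
        k4 = nx.complete_graph(4)
        assert set(nb.normalized_brokerage(k4).values()) == {1.0}
        g, bridges = nb.generate_broker_graph(2, 5, 1, seed=1)
        norm = nb.normalized_brokerage(g)
        assert norm[bridges[0]] == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in norm.values())


class TestOracleAgreement:
    def test_random_graphs_match_oracles(self, rng):
        for rep in range(25):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            points, bridges = nb.articulation_and_bridges(g)
            assert points == oracle_articulation_points(g)
            assert bridges == oracle_bridges(g)
            for v in g.nodes:
                assert nb.clustering_coefficient(g, v) == pytest.approx(
                    oracle_clustering(g, v)
                )
                assert nb.effective_size(g, v) == pytest.approx(
                    oracle_effective_size(g, v)
                )
                assert nb.local_efficiency(g, v) == pytest.approx(
                    oracle_local_efficiency(g, v)
                )

    def test_removing_articulation_point_increases_components(self, rng):
        found = 0
        for rep in range(300):
            g = nx.gnp_random_graph(10, 0.2, seed=int(rng.integers(2**31)))
            points, _ = nb.articulation_and_bridges(g)
            for v in points:
                before = nx.number_connected_components(g)
                h = g.copy()
                h.remove_node(v)
                assert nx.number_connected_components(h) > before
                found += 1
            if found >= 100:
                break
        assert found >= 100


class TestDisruption:
    def test_complete_graph_single_removal(self):
        g = nx.complete_graph(6)
        prof = nb.disruption_profile(g, [0], n_random=10, seed=1)
        assert prof.n_components_after == [1]
        assert prof.giant_fraction_after[0] == pytest.approx(5 / 6)

    def test_barbell_bridge_removal_splits(self):
        g, bridges = nb.generate_broker_graph(2, 5, 1, seed=1)
        prof = nb.disruption_profile(g, bridges, n_random=20, seed=2)
        assert prof.n_components_after[0] == 2

    def test_broker_removal_beats_random_baseline(self):
        g, bridges = nb.generate_broker_graph(3, 6, 2, seed=7)
        norm = nb.normalized_brokerage(g)
        top2 = sorted(norm, key=lambda v: -norm[v])[:2]
        prof = nb.disruption_profile(g, top2, n_random=200, seed=3)
        assert prof.giant_fraction_after[-1] < prof.baseline_p5[-1]

    def test_duplicate_targets_rejected(self):
        g = nx.complete_graph(4)
        with pytest.raises(ConfigurationError):
            nb.disruption_profile(g, [0, 0], n_random=5, seed=0)

    def test_bit_identical_given_seed(self):
        g, bridges = nb.generate_broker_graph(3, 5, 2, seed=4)
        a = nb.disruption_profile(g, bridges, n_random=30, seed=5)
        b = nb.disruption_profile(g, bridges, n_random=30, seed=5)
        assert a.to_frame().equals(b.to_frame())


class TestBrokerRanking:
    def make_network(self):
        g, bridges = nb.generate_broker_graph(2, 5, 1, seed=0)
        for v in g:
            g.nodes[v]["is_ncrna"] = v in bridges
            g.nodes[v]["biotype"] = "pseudogene" if v in bridges else "protein_coding"
        return g, bridges

    def test_single_ncrna_ranked_first(self):
        g, bridges = self.make_network()
        ranking = nb.rank_ncrna_brokers(g)
        assert ranking[0][0] == bridges[0]

    def test_interactors_are_non_ncrna_neighbors(self):
        g, bridges = self.make_network()
        _, _, interactors = nb.rank_ncrna_brokers(g)[0]
        expected = sorted(
            u for u in g.neighbors(bridges[0]) if not g.nodes[u]["is_ncrna"]
        )
        assert interactors == expected

    def test_planted_broker_outranks_module_ncrna(self, rng):
        """A bridging ncRNA ranks above a within-module ncRNA in nearly
        every seeded replicate."""
        wins = 0
        for rep in range(20):
            g, bridges = nb.generate_broker_graph(2, 6, 1, seed=rep)
            # add a within-clique ncRNA wired to 4 members of clique 0
            clique0 = [v for v in g if g.nodes[v].get("clique") == 0]
            g.add_node("NC_module")
            rg = np.random.default_rng(rep)
            for t in rg.choice(clique0, size=4, replace=False):
                g.add_edge("NC_module", t)
            for v in g:
                g.nodes[v]["is_ncrna"] = v in (bridges[0], "NC_module")
            ranking = [r[0] for r in nb.rank_ncrna_brokers(g)]
            wins += ranking.index(bridges[0]) < ranking.index("NC_module")
        assert wins >= 19

    def test_no_ncrnas_gives_empty_ranking(self):
        g = nx.complete_graph(4)
        assert nb.rank_ncrna_brokers(g) == []

    def test_topology_table_fields(self):
        g, _ = self.make_network()
        table = nb.node_topology_table(g)
        assert {"degree", "clustering", "effective_size", "local_efficiency",
                "brokerage", "normalized_brokerage", "is_articulation",
                "betweenness"} <= set(table.columns)
        assert len(table) == g.number_of_nodes()
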