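"""Centralities vs brute-force enumeration; hub intersection; permutation test."""

import math

import networkx as nx
import numpy as np
import pytest

from oracles import (
    brute_closeness,
    brute_mnc,
    brute_stress,
    exact_epc,
    random_graph,
)

from excessh2.network import (
    CentralityTable,
    closeness,
    epc,
    hub_genes,
    mnc,
    score_nodes,
    stress,
    subnetwork_enrichment_p,
)
from excessh2.synthetic import gen_network


def _graph(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestCloseness:
    def test_path_graph(self):
        g = _graph("abc", [("a", "b"), ("b", "c")])
        c = closeness(g)
        assert c == {"a": 1.5, "b": 2.0, "c": 1.5}

    def test_star_graph(self):
        g = _graph("cabde", [("c", x) for x in "abde"])
        c = closeness(g)
        assert c["c"] == 4.0
        assert all(c[x] == pytest.approx(1 + 3 * 0.5) for x in "abde")

    def test_isolated_nodes_zero(self):
        c = closeness(_graph("ab", []))
        assert c == {"a": 0.0, "b": 0.0}


class TestStress:
    def test_path_graph(self):
        g = _graph("abc", [("a", "b"), ("b", "c")])
        assert stress(g) == {"a": 0, "b": 1, "c": 0}

    def test_complete_graph_all_zero(self):
        g = _graph("abcd", [(x, y) for i, x in enumerate("abcd") for y in "abcd"[i + 1 :]])
        assert set(stress(g).values()) == {0}

    def test_four_cycle_each_node_on_one_geodesic(self):
        g = nx.cycle_graph(4)
        s = stress(g)
        oracle = brute_stress(list(g.nodes), list(g.edges))
        assert s == oracle
        assert set(s.values()) == {1}


class TestMnc:
    def test_star_center_has_mnc_one(self):
        g = _graph("cabde", [("c", x) for x in "abde"])
        assert mnc(g)["c"] == 1

    def test_triangle_node(self):
        g = _graph("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        assert mnc(g) == {"a": 2, "b": 2, "c": 2}

    def test_isolated_node_zero(self):
        assert mnc(_graph("a", []))["a"] == 0


class TestBruteForceSweep:
    """All four methods against explicit enumeration on random small graphs."""

    @pytest.mark.parametrize("batch", range(4))
    def test_topological_methods_match_enumeration(self, batch):
        rng = np.random.default_rng(100 + batch)
        for _ in range(50):  # 4 x 50 = 200 random graphs <= 7 nodes
            n = int(rng.integers(2, 8))
            p = float(rng.uniform(0.2, 0.8))
            nodes, edges = random_graph(n, p, rng)
            g = _graph(nodes, edges)
            assert closeness(g) == pytest.approx(brute_closeness(nodes, edges))
            assert stress(g) == brute_stress(nodes, edges)
            assert mnc(g) == brute_mnc(nodes, edges)

    def test_epc_within_monte_carlo_error_of_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            nodes, edges = random_graph(5, 0.5, rng)
            if len(edges) > 10 or not edges:
                continue
            retention = [float(rng.uniform(0.2, 0.9)) for _ in edges]
            exact = exact_epc(nodes, edges, retention)
            g = _graph(nodes, edges)
            ret = {e: r for e, r in zip(edges, retention)}
            n_real = 3000
            est = epc(g, n_realizations=n_real, retention=ret, seed=11)
            for v in nodes:
                se = math.sqrt(max(exact[v], 0.05) * (len(nodes) - 1)) / math.sqrt(n_real)
                assert abs(est[v] - exact[v]) <= max(3 * se, 0.15), v


class TestEpc:
    def test_single_edge_expectation(self):
        g = _graph("uv", [("u", "v")])
        est = epc(g, n_realizations=4000, retention=0.5, seed=1)
        # exact expectation is 0.5 (edge present half the time)
        se = 0.5 / math.sqrt(4000)
        assert abs(est["u"] - 0.5) <= 3 * se

    def test_retention_one_gives_component_size(self):
        g = _graph("abcde", [("a", "b"), ("b", "c"), ("d", "e")])
        est = epc(g, n_realizations=10, retention=1.0, seed=0)
        assert est == {"a": 2.0, "b": 2.0, "c": 2.0, "d": 1.0, "e": 1.0}

    def test_retention_zero_all_zero(self):
        g = _graph("abc", [("a", "b")])
        assert set(epc(g, 10, retention=0.0, seed=0).values()) == {0.0}

    def test_deterministic_per_seed_and_se_shrinks(self):
        g = gen_network(30, 3, p_background=0.1, p_hub=0.6, seed=5)
        a = epc(g, n_realizations=200, seed=9)
        b = epc(g, n_realizations=200, seed=9)
        assert a == b
        # Monte-Carlo spread shrinks roughly as 1/sqrt(n_realizations)
        node = sorted(g.nodes)[0]
        spread = {
            n_real: np.std([
                epc(g, n_realizations=n_real, seed=s)[node] for s in range(8)
            ])
            for n_real in (50, 800)
        }
        assert spread[800] < spread[50]

    def test_invalid_realizations(self):
        with pytest.raises(ValueError):
            epc(_graph("ab", [("a", "b")]), n_realizations=0)


class TestHubGenes:
    @staticmethod
    def _table(per_method_scores):
        return CentralityTable(scores=per_method_scores)

    def test_identical_rankings_intersect_to_top_quarter(self):
        nodes = [f"g{i}" for i in range(100)]
        sc = {v: float(100 - i) for i, v in enumerate(nodes)}
        table = self._table({m: dict(sc) for m in ("closeness", "stress", "epc", "mnc")})
        hubs = hub_genes(table, quantile=0.25)
        assert hubs.members == frozenset(nodes[:25])

    def test_disjoint_top_quartiles_empty(self):
        nodes = [f"g{i}" for i in range(8)]
        methods = ("closeness", "stress", "epc", "mnc")
        scores = {}
        for mi, m in enumerate(methods):
            # a different pair of nodes tops each method
            scores[m] = {
                v: (10.0 if i // 2 == mi else 0.0) for i, v in enumerate(nodes)
            }
        hubs = hub_genes(self._table(scores), quantile=0.25)
        assert hubs.members == frozenset()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        nodes = [f"g{i}" for i in range(40)]
        base = {m: {v: float(rng.random()) for v in nodes}
                for m in ("closeness", "stress", "epc", "mnc")}
        hubs = hub_genes(self._table(base))
        transformed = {
            m: {v: math.exp(3 * s) for v, s in sc.items()} for m, sc in base.items()
        }
        assert hub_genes(self._table(transformed)).members == hubs.members

    def test_ties_at_cutoff_included(self):
        nodes = ["a", "b", "c", "d"]
        sc = {"a": 2.0, "b": 1.0, "c": 1.0, "d": 0.0}
        table = self._table({m: dict(sc) for m in ("closeness", "stress", "epc", "mnc")})
        hubs = hub_genes(table, quantile=0.5)  # k=2, cutoff score 1.0
        assert hubs.members == frozenset({"a", "b", "c"})

    def test_planted_hub_recovery(self):
        recovered, planted_total = 0, 0
        for s in range(10):
            g = gen_network(100, 10, p_background=0.02, p_hub=0.6, seed=s)
            planted = set(g.graph["planted_hubs"])
            scores = score_nodes(g, epc_realizations=200, seed=s)
            hubs = hub_genes(scores, quantile=0.25)
            recovered += len(hubs.members & planted)
            planted_total += len(planted)
        assert recovered / planted_total >= 0.8


class TestSubnetworkEnrichment:
    def test_planted_clique_minimal_p(self):
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(100))
        clique = [f"n{i}" for i in range(6)]
        g.add_edges_from(
            (clique[i], clique[j]) for i in range(6) for j in range(i + 1, 6)
        )
        rng = np.random.default_rng(2)
        others = [f"n{i}" for i in range(6, 100)]
        for _ in range(60):
            u, v = rng.choice(others, size=2, replace=False)
            g.add_edge(u, v)
        p = subnetwork_enrichment_p(g, clique, n_perm=500, seed=3)
        assert p == pytest.approx(1 / 501)

    def test_zero_internal_edges_p_one(self):
        g = nx.path_graph(10)
        p = subnetwork_enrichment_p(g, [0, 5], n_perm=200, seed=1)
        assert p == 1.0

    def test_whole_node_set_p_one(self):
        g = nx.cycle_graph(8)
        p = subnetwork_enrichment_p(g, list(g.nodes), n_perm=100, seed=1)
        assert p == 1.0

    def test_small_subset_rejected(self):
        with pytest.raises(ValueError):
            subnetwork_enrichment_p(nx.path_graph(5), [0], n_perm=100, seed=0)
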