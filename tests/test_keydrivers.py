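"""MI estimation, ARACNE-style thresholding and DPI, hub/NHNN ranking."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from brainaging import keydrivers as kd
from brainaging import synthdata as sd
from brainaging.normalize import log_cpm

GAUSS_MI_RHO09 = 0.830  # -0.5 * ln(1 - 0.9^2)


class TestEstimateMI:
    def test_exact_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert kd.estimate_mi(x, y) == kd.estimate_mi(y, x)

    def test_independent_vectors_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals.append(kd.estimate_mi(rng.uniform(size=200), rng.uniform(size=200)))
        assert np.mean(vals) < 0.05

    def test_gaussian_closed_form(self):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=2000)
            y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=2000)
            errs.append(abs(kd.estimate_mi(x, y) - GAUSS_MI_RHO09) / GAUSS_MI_RHO09)
        assert np.mean(errs) < 0.25

    def test_self_mi_equals_discretized_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        b = max(2, int(np.floor(np.sqrt(400) / 2)))
        mi = kd.estimate_mi(x, x, bins=b, miller_madow=False)
        # equal-frequency bins: entropy of x's bin labels is log(b)
        assert mi == pytest.approx(np.log(b), rel=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            kd.estimate_mi(np.arange(5.0), np.arange(5.0))


@pytest.fixture(scope="module")
def values():
    rng = np.random.default_rng(2)
    return pd.DataFrame(rng.normal(size=(15, 60)))


class TestMiThreshold:

    def test_threshold_monotone_in_alpha(self, values):
        t_strict = kd.mi_threshold(values, n_perm=300, alpha=0.001, seed=0)
        t_loose = kd.mi_threshold(values, n_perm=300, alpha=0.5, seed=0)
        assert t_strict >= t_loose

    def test_seed_reproducibility(self, values):
        assert kd.mi_threshold(values, n_perm=200, seed=5) == kd.mi_threshold(
            values, n_perm=200, seed=5
        )

    def test_null_network_nearly_empty_after_threshold(self, values):
        net = kd.build_mi_network(values, tolerance=None, n_perm=300, seed=1)
        n_pairs = 15 * 14 // 2
        assert net.graph.number_of_edges() <= 0.05 * n_pairs

    def test_too_few_permutations_rejected(self, values):
        with pytest.raises(ValueError, match="n_perm"):
            kd.mi_threshold(values, n_perm=50)


def _dpi_oracle(graph: nx.Graph, tolerance: float) -> nx.Graph:
    """Fixpoint triangle scan: repeatedly drop the weakest violating edge."""
    g = graph.copy()
    while True:
        worst = None
        for a, b in g.edges:
            mi = g[a][b]["mi"]
            for k in set(g.neighbors(a)) & set(g.neighbors(b)):
                if mi < (1 - tolerance) * min(g[a][k]["mi"], g[b][k]["mi"]):
                    if worst is None or mi < worst[2]:
                        worst = (a, b, mi)
                    break
        if worst is None:
            return g
        g.remove_edge(worst[0], worst[1])


class TestDPI:
    def test_markov_chain_indirect_edge_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1500)
        y = 0.9 * x + 0.45 * rng.normal(size=1500)
        z = 0.9 * y + 0.45 * rng.normal(size=1500)
        g = nx.Graph()
        g.add_edge("x", "y", mi=kd.estimate_mi(x, y))
        g.add_edge("y", "z", mi=kd.estimate_mi(y, z))
        g.add_edge("x", "z", mi=kd.estimate_mi(x, z))
        pruned = kd.dpi_prune(kd.MINetwork(graph=g), tolerance=0.15)
        assert not pruned.graph.has_edge("x", "z")
        assert pruned.graph.has_edge("x", "y") and pruned.graph.has_edge("y", "z")

    def test_two_node_network_unchanged(self):
        g = nx.Graph()
        g.add_edge("a", "b", mi=1.0)
        pruned = kd.dpi_prune(kd.MINetwork(graph=g))
        assert pruned.graph.number_of_edges() == 1

    def test_high_tolerance_keeps_near_ties(self):
        g = nx.Graph()
        g.add_edge("a", "b", mi=1.00)
        g.add_edge("b", "c", mi=0.99)
        g.add_edge("a", "c", mi=0.98)
        pruned = kd.dpi_prune(kd.MINetwork(graph=g), tolerance=0.99)
        assert pruned.graph.number_of_edges() == 3

    def test_invalid_tolerance_rejected(self):
        g = nx.Graph()
        with pytest.raises(ValueError, match="tolerance"):
            kd.dpi_prune(kd.MINetwork(graph=g), tolerance=1.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(15, 0.4, seed=seed)
        for a, b in g.edges:
            g[a][b]["mi"] = float(rng.uniform(0.1, 1.0))
        pruned = kd.dpi_prune(kd.MINetwork(graph=g), tolerance=0.15)
        oracle = _dpi_oracle(g, 0.15)
        assert set(pruned.graph.edges) == set(oracle.edges)

    def test_never_adds_edges_and_no_violations_remain(self):
        rng = np.random.default_rng(42)
        g = nx.gnp_random_graph(20, 0.5, seed=3)
        for a, b in g.edges:
            g[a][b]["mi"] = float(rng.uniform(0.1, 1.0))
        pruned = kd.dpi_prune(kd.MINetwork(graph=g), tolerance=0.15).graph
        assert set(pruned.edges) <= set(g.edges)
        for a, b in pruned.edges:
            for k in set(pruned.neighbors(a)) & set(pruned.neighbors(b)):
                assert pruned[a][b]["mi"] >= (1 - 0.15) * min(
                    pruned[a][k]["mi"], pruned[b][k]["mi"]
                )


class TestHubs:
    def _net(self, edges):
        g = nx.Graph()
        g.add_edges_from((a, b, {"mi": 1.0}) for a, b in edges)
        return kd.MINetwork(graph=g)

    def test_star_center_is_unique_hub(self):
        net = self._net([("hub", f"n{i}") for i in range(20)])
        assert kd.identify_hubs(net, top_fraction=0.04) == {"hub"}

    def test_ring_ties_include_all(self):
        nodes = [f"n{i}" for i in range(10)]
        net = self._net([(nodes[i], nodes[(i + 1) % 10]) for i in range(10)])
        assert kd.identify_hubs(net, top_fraction=0.1) == set(nodes)

    def test_aged_specific_difference(self):
        young = self._net([("hub", f"n{i}") for i in range(10)])
        aged_edges = [("hub", f"n{i}") for i in range(10)] + [
            ("driver", f"n{i}") for i in range(9)
        ]
        aged = self._net(aged_edges)
        aged.graph.add_nodes_from(young.graph.nodes)
        young.graph.add_nodes_from(aged.graph.nodes)
        out = kd.aged_specific_hubs(young, aged, top_fraction=0.1)
        assert out == {"driver"}

    def test_identical_networks_no_aged_specific(self):
        net = self._net([("a", "b"), ("b", "c")])
        assert kd.aged_specific_hubs(net, net) == set()

    def test_disjoint_node_sets_rejected(self):
        with pytest.raises(ValueError, match="node universe"):
            kd.aged_specific_hubs(self._net([("a", "b")]), self._net([("c", "d")]))


class TestNHNN:
    def _net(self, edges):
        g = nx.Graph()
        g.add_edges_from((a, b, {"mi": 1.0}) for a, b in edges)
        return kd.MINetwork(graph=g)

    def test_star_one_hop(self):
        net = self._net([("c", f"n{i}") for i in range(7)])
        nhnn = kd.nhnn_rank(net, n_hops=1)
        assert nhnn["c"] == 7
        assert nhnn.index[0] == "c"

    def test_path_two_hops_hand_counts(self):
        net = self._net([("a", "b"), ("b", "c"), ("c", "d")])
        nhnn = kd.nhnn_rank(net, n_hops=2)
        assert nhnn["b"] == 3 and nhnn["a"] == 2 and nhnn["c"] == 3

    def test_monotone_in_hops_and_component_limit(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(25, 0.12, seed=1)
        for a, b in g.edges:
            g[a][b]["mi"] = 1.0
        net = kd.MINetwork(graph=g)
        prev = None
        for hops in (1, 2, 3, 10):
            cur = kd.nhnn_rank(net, n_hops=hops)
            if prev is not None:
                assert (cur.loc[prev.index] >= prev).all()
            prev = cur
        # at >= diameter hops, NHNN = component size - 1 (brute-force BFS check)
        full = kd.nhnn_rank(net, n_hops=30)
        for node in g.nodes:
            comp = nx.node_connected_component(g, node)
            assert full[node] == len(comp) - 1


class TestEndToEndDriverRecovery:
    def test_planted_aged_specific_driver_recovered(self, design8, group_cols):
        young_cols, aged_cols = group_cols
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            params = sd.TruthParams(
                n_genes=500,
                modules=(sd.ModuleSpec(size=30, r_young=0.45, r_aged=0.65,
                                       n_hubs=0, n_aged_specific_hubs=1),),
            )
            counts, truth = sd.simulate_counts(design8, params, seed=seed)
            lc = log_cpm(counts)
            genes = [g for g, m in truth.module_membership.items()]
            driver = truth.aged_specific_hubs["module_1"][0]
            ny = kd.build_mi_network(lc.loc[genes, young_cols], n_perm=200, seed=seed)
            na = kd.build_mi_network(lc.loc[genes, aged_cols], n_perm=200, seed=seed + 1000)
            in_hubs = driver in kd.aged_specific_hubs(ny, na)
            in_top5 = driver in list(kd.nhnn_rank(na).index[:5])
            hits += in_hubs and in_top5
        assert hits / n_rep >= 0.8

    def test_key_driver_report_consistency(self, design8, group_cols):
        young_cols, aged_cols = group_cols
        params = sd.TruthParams(
            n_genes=300,
            modules=(sd.ModuleSpec(size=30, r_young=0.45, r_aged=0.65,
                                   n_hubs=1, n_aged_specific_hubs=1),),
        )
        counts, truth = sd.simulate_counts(design8, params, seed=0)
        lc = log_cpm(counts)
        genes = [g for g, m in truth.module_membership.items()]
        ny = kd.build_mi_network(lc.loc[genes, young_cols], n_perm=200, seed=1)
        na = kd.build_mi_network(lc.loc[genes, aged_cols], n_perm=200, seed=2)
        report = kd.key_driver_report(ny, na, module="m")
        t = report.table
        # aged-specific implies aged hub and not young hub
        aspec = t[t["aged_specific_hub"]]
        assert aspec["hub_aged"].all()
        assert not aspec["hub_young"].any()
        assert set(t.index) == set(ny.nodes)
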