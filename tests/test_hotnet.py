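import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fi_netkit.hotnet import (
    HeatAssignment,
    auto_delta,
    heat_from_mutations,
    hot_subnetworks,
    influence_matrix,
    significance_test,
)
from fi_netkit.io import FINetwork, MutationTable

from helpers import make_fi


def _random_net(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return make_fi([(f"G{a}", f"G{b}") for a, b in g.edges], nodes=[f"G{a}" for a in g.nodes])


class TestInfluenceMatrix:
    def test_t_zero_is_identity(self):
        net = make_fi([("A", "B"), ("B", "C")])
        infl = influence_matrix(net, "diffusion", 0.0)
        assert np.allclose(infl.M, np.eye(3), atol=1e-14)

    def test_negative_parameter_errors(self):
        net = make_fi([("A", "B")])
        with pytest.raises(ValueError):
            influence_matrix(net, "diffusion", -0.1)
        with pytest.raises(ValueError):
            influence_matrix(net, "inverse", 0.0)

    def test_k2_large_t_reaches_uniform_equilibrium(self):
        net = make_fi([("A", "B")])
        infl = influence_matrix(net, "diffusion", 50.0)
        assert np.allclose(infl.M, 0.5, atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_truncated_series(self, seed):
        """exp(-tL) agrees with the 40-term Taylor series on <= 8-node graphs."""
        net = _random_net(8, 0.4, seed)
        infl = influence_matrix(net, "diffusion", 0.3)
        genes = infl.genes
        for comp_nodes in nx.connected_components(net.graph):
            comp = sorted(comp_nodes)
            a = nx.to_numpy_array(net.graph, nodelist=comp, weight=None)
            lap = np.diag(a.sum(axis=1)) - a
            series = np.zeros_like(lap)
            term = np.eye(len(comp))
            for k in range(41):
                series += term
                term = term @ (-0.3 * lap) / (k + 1)
            ids = [genes.index(c) for c in comp]
            assert np.allclose(infl.M[np.ix_(ids, ids)], series, atol=1e-8)

    def test_heat_conservation_column_sums(self):
        net = _random_net(20, 0.2, 5)
        # keep the largest component so the graph is connected
        comp = max(nx.connected_components(net.graph), key=len)
        infl = influence_matrix(net.subgraph(comp), "diffusion", 0.5)
        assert np.allclose(infl.M.sum(axis=0), 1.0, atol=1e-10)

    def test_cross_component_influence_zero(self):
        net = make_fi([("A", "B"), ("X", "Y")])
        infl = influence_matrix(net, "diffusion", 1.0)
        i, j = infl.index["A"], infl.index["X"]
        assert infl.M[i, j] == 0.0 and infl.M[j, i] == 0.0

    def test_inverse_kernel_is_regularised_inverse(self):
        net = make_fi([("A", "B"), ("B", "C")])
        gamma = 0.7
        infl = influence_matrix(net, "inverse", gamma)
        a = nx.to_numpy_array(net.graph, nodelist=infl.genes, weight=None)
        lap = np.diag(a.sum(axis=1)) - a
        assert np.allclose(infl.M @ (gamma * np.eye(3) + lap), gamma * np.eye(3), atol=1e-12)


class TestHotSubnetworks:
    def test_delta_above_max_score_gives_no_multigene_components(self):
        net = make_fi([("A", "B"), ("B", "C")])
        infl = influence_matrix(net, "diffusion", 0.1)
        heat = HeatAssignment({"A": 1.0, "B": 1.0, "C": 1.0})
        hot = hot_subnetworks(infl, heat, delta=10.0, min_singleton_heat=100.0)
        assert hot.components == []

    def test_tiny_delta_connects_all_hot_genes(self):
        net = make_fi([("A", "B"), ("B", "C"), ("C", "D")])
        infl = influence_matrix(net, "diffusion", 0.5)
        heat = HeatAssignment({g: 2.0 for g in "ABCD"})
        hot = hot_subnetworks(infl, heat, delta=1e-12)
        assert hot.components == [frozenset("ABCD")]

    def test_zero_heat_genes_excluded(self):
        net = make_fi([("A", "B"), ("B", "C")])
        infl = influence_matrix(net, "diffusion", 0.5)
        heat = HeatAssignment({"A": 5.0, "B": 0.0, "C": 5.0})
        hot = hot_subnetworks(infl, heat, delta=1e-12, min_singleton_heat=2.0)
        # B is cold and leaves every component, but influence still flows
        # through it, so A and C remain joined
        assert hot.components == [frozenset({"A", "C"})]

    def test_all_zero_heat_errors(self):
        net = make_fi([("A", "B")])
        infl = influence_matrix(net, "diffusion", 0.1)
        with pytest.raises(ValueError, match="zero"):
            hot_subnetworks(infl, HeatAssignment({"A": 0.0}), 0.1)

    def test_planted_hot_cliques_recovered(self):
        """Two hot 4-cliques in a cold sparse background come out as exactly
        the two planted components under a calibrated delta."""
        net = FINetwork()
        hotA = [f"A{i}" for i in range(4)]
        hotB = [f"B{i}" for i in range(4)]
        cold = [f"C{i}" for i in range(12)]
        for grp in (hotA, hotB):
            for a, b in itertools.combinations(grp, 2):
                net.add_edge(a, b)
        for i, c in enumerate(cold):
            net.add_edge(c, cold[(i + 1) % len(cold)])
        net.add_edge("A0", "C0")
        net.add_edge("B0", "C6")
        infl = influence_matrix(net, "diffusion", 0.1)
        heat = HeatAssignment({g: 10.0 for g in hotA + hotB} | {g: 0.5 for g in cold})
        sym = np.minimum(infl.M, infl.M.T)
        # brute-force evaluation of the edge rule to pick a delta separating
        # within-clique pairs from everything else
        heats = np.array([heat.heat[g] for g in infl.genes])
        scores = sym * np.minimum.outer(heats, heats)
        within = [
            scores[infl.index[a], infl.index[b]]
            for grp in (hotA, hotB)
            for a, b in itertools.combinations(grp, 2)
        ]
        cross = [
            scores[infl.index["A0"], infl.index["C0"]],
            scores[infl.index["B0"], infl.index["C6"]],
        ]
        delta = (min(within) + max(cross)) / 2
        assert max(cross) < delta < min(within)
        hot = hot_subnetworks(infl, heat, delta, min_singleton_heat=np.inf)
        assert hot.components == [frozenset(hotA), frozenset(hotB)]

    @pytest.mark.parametrize("d1,d2", [(1e-4, 1e-3), (1e-3, 1e-2)])
    def test_components_refine_as_delta_grows(self, d1, d2):
        net = _random_net(25, 0.15, 9)
        infl = influence_matrix(net, "diffusion", 0.2)
        rng = np.random.default_rng(4)
        heat = HeatAssignment({g: float(rng.exponential(1.0)) for g in infl.genes})
        coarse = hot_subnetworks(infl, heat, d1, min_singleton_heat=np.inf).components
        fine = hot_subnetworks(infl, heat, d2, min_singleton_heat=np.inf).components
        for comp in fine:
            assert any(comp <= parent for parent in coarse)


class TestSignificance:
    def _setup(self):
        net = _random_net(20, 0.2, 3)
        infl = influence_matrix(net, "diffusion", 0.1)
        rng = np.random.default_rng(0)
        heat = HeatAssignment({g: float(rng.exponential(1.0)) for g in infl.genes})
        return net, infl, heat

    def test_observed_zero_gives_p_one(self):
        net, infl, heat = self._setup()
        p = significance_test(net, infl, heat, delta=100.0, sizes=[3], n_perm=100, seed=0)
        assert p[3] == 1.0

    def test_identical_seed_identical_pmap(self):
        net, infl, heat = self._setup()
        kwargs = dict(delta=0.01, sizes=[2, 3], n_perm=150, seed=42)
        assert significance_test(net, infl, heat, **kwargs) == significance_test(
            net, infl, heat, **kwargs
        )

    def test_add_one_rule_never_zero(self):
        net, infl, heat = self._setup()
        p = significance_test(net, infl, heat, delta=0.01, sizes=[2, 3, 5], n_perm=100, seed=1)
        assert all(v >= 1 / 101 for v in p.values())

    def test_n_perm_below_100_errors(self):
        net, infl, heat = self._setup()
        with pytest.raises(ValueError, match="n_perm"):
            significance_test(net, infl, heat, 0.01, [3], n_perm=50)


class TestDefaults:
    def test_heat_from_mutations_is_distinct_sample_count(self):
        mut = MutationTable(
            pd.DataFrame(
                {
                    "gene": ["A", "A", "A", "B"],
                    "sample": ["S1", "S1", "S2", "S1"],
                    "variant_classification": ["M", "N", "M", "M"],
                }
            )
        )
        assert heat_from_mutations(mut).heat == {"A": 2.0, "B": 1.0}

    def test_auto_delta_controls_null_component_size(self):
        net = _random_net(30, 0.15, 7)
        infl = influence_matrix(net, "diffusion", 0.1)
        rng = np.random.default_rng(2)
        heat = HeatAssignment({g: float(rng.exponential(1.0)) for g in infl.genes})
        delta = auto_delta(infl, heat, s=4, n_perm=100, seed=5)
        sym = np.minimum(infl.M, infl.M.T)
        heats = np.array([heat.heat[g] for g in infl.genes])
        # re-check the guarantee on a fresh permutation stream
        from fi_netkit.hotnet import _component_sets, _hot_edge_matrix

        rng2 = np.random.default_rng(99)
        ok = 0
        for _ in range(100):
            perm = rng2.permutation(heats)
            comps = _component_sets(_hot_edge_matrix(sym, perm, delta), perm > 0)
            if not comps or max(len(c) for c in comps) < 4:
                ok += 1
        assert ok >= 85
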