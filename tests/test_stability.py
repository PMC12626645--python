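import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netstab.errors import InvalidInputError
from netstab.io import CountTable
from netstab.stability import (
    _connectedness_from_corr,
    cohesion,
    compare_stability,
    connectedness,
    global_efficiency,
    keystone_removal_test,
    robustness,
    vulnerability,
)


def _signed_graph(edges, nodes=None, abundance=1.0):
    g = nx.Graph()
    if nodes is not None:
        for v in nodes:
            g.add_node(v, abundance=abundance)
    for u, v, rho in edges:
        g.add_edge(u, v, rho=rho, weight=abs(rho), sign=1 if rho > 0 else -1)
        g.nodes[u].setdefault("abundance", abundance)
        g.nodes[v].setdefault("abundance", abundance)
    return g


class TestGlobalEfficiency:
    def test_complete_graphs(self):
        for n in (3, 5, 8):
            assert global_efficiency(nx.complete_graph(n)) == pytest.approx(1.0)

    def test_path_p3(self):
        assert global_efficiency(nx.path_graph(3)) == pytest.approx(5 / 6)

    def test_edgeless(self):
        assert global_efficiency(nx.empty_graph(4)) == 0.0

    def test_too_small(self):
        with pytest.raises(InvalidInputError):
            global_efficiency(nx.empty_graph(1))


class TestVulnerability:
    def test_clique_is_invulnerable(self):
        assert vulnerability(nx.complete_graph(4)) == pytest.approx(0.0)

    def test_star_center_is_everything(self):
        assert vulnerability(nx.star_graph(3)) == pytest.approx(1.0)

    def test_four_cycle(self):
        # removing any C4 node leaves P3 with equal efficiency
        assert vulnerability(nx.cycle_graph(4)) == pytest.approx(0.0, abs=1e-12)

    def test_relabeling_invariance(self):
        g = nx.gnp_random_graph(12, 0.3, seed=0)
        mapping = {v: f"node{(v * 7) % 12}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        assert vulnerability(g) == pytest.approx(vulnerability(h))


class TestRobustness:
    def test_all_positive_complete_network(self):
        g = _signed_graph([(i, j, 0.9) for i in range(10) for j in range(i + 1, 10)])
        res = robustness(g, removal_fraction=0.5, n_reps=20, seed=0)
        np.testing.assert_allclose(res.replicates, 0.5)

    def test_all_negative_network_collapses(self):
        g = _signed_graph([(i, j, -0.9) for i in range(8) for j in range(i + 1, 8)])
        res = robustness(g, removal_fraction=0.5, n_reps=10, seed=0)
        np.testing.assert_allclose(res.replicates, 0.0)

    def test_replicates_within_bounds(self):
        g = _signed_graph(
            [(i, (i + 1) % 12, 0.8 if i % 3 else -0.8) for i in range(12)]
        )
        res = robustness(g, removal_fraction=0.5, n_reps=50, seed=1)
        assert (res.replicates >= 0).all()
        assert (res.replicates <= 0.5 + 1e-12).all()

    def test_matching_graph_against_exhaustive_enumeration(self):
        # perfect matching on 8 nodes: a node survives the cascade iff its
        # partner also survived the random removal
        g = _signed_graph([(2 * i, 2 * i + 1, 0.9) for i in range(4)])
        exact = []
        for removed in itertools.combinations(range(8), 4):
            alive = set(range(8)) - set(removed)
            survivors = {v for v in alive if (v ^ 1) in alive}
            exact.append(len(survivors) / 8)
        exact_mean = np.mean(exact)
        res = robustness(g, removal_fraction=0.5, n_reps=4000, seed=2)
        assert res.mean == pytest.approx(exact_mean, abs=0.01)

    def test_adding_positive_edges_never_hurts(self):
        rng = np.random.default_rng(0)
        base_edges = [(i, (i + 1) % 10, 0.7) for i in range(10)]
        g1 = _signed_graph(base_edges, nodes=range(10))
        extra = base_edges + [(0, 5, 0.9), (2, 7, 0.9), (1, 6, 0.9)]
        g2 = _signed_graph(extra, nodes=range(10))
        r1 = robustness(g1, removal_fraction=0.5, n_reps=200, seed=3)
        r2 = robustness(g2, removal_fraction=0.5, n_reps=200, seed=3)
        assert r2.mean >= r1.mean - 0.02

    def test_missing_abundance_rejected(self):
        g = _signed_graph([(0, 1, 0.5)])
        g.add_node(2)  # no abundance attribute
        with pytest.raises(InvalidInputError, match="abundance"):
            robustness(g, n_reps=2, seed=0)


class TestConnectednessAndCohesion:
    def test_aggregation_from_exact_correlations(self):
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        pos, neg = _connectedness_from_corr(corr)
        np.testing.assert_allclose(pos, 0.5)
        np.testing.assert_allclose(neg, 0.0)

    def test_mixed_signs(self):
        corr = np.array([[1.0, 0.6, -0.4], [0.6, 1.0, 0.2], [-0.4, 0.2, 1.0]])
        pos, neg = _connectedness_from_corr(corr)
        assert pos[0] == pytest.approx(0.6)
        assert neg[0] == pytest.approx(-0.4)
        assert pos[1] == pytest.approx(0.4)  # mean of 0.6 and 0.2

    def test_taxa_shuffle_null_on_iid_noise(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(50, 150, size=(84, 30))
        tab = CountTable(counts, tuple(f"s{i}" for i in range(84)),
                         tuple(f"t{j}" for j in range(30)))
        conn = connectedness(tab, n_shuffle=200, seed=6)
        assert np.abs(conn["pos_connectedness"]).mean() <= 0.1
        assert np.abs(conn["neg_connectedness"]).mean() <= 0.1

    def test_cohesion_direct_formula(self):
        tab = CountTable(np.array([[4, 6], [6, 4]]), ("a", "b"), ("x", "y"))
        conn = pd.DataFrame(
            {"pos_connectedness": [0.5, 0.25], "neg_connectedness": [-0.2, 0.0]},
            index=["x", "y"],
        )
        coh = cohesion(tab, conn)
        assert coh.loc["a", "cohesion_pos"] == pytest.approx(0.4 * 0.5 + 0.6 * 0.25)
        assert coh.loc["a", "cohesion_neg"] == pytest.approx(0.4 * -0.2)
        assert (coh["cohesion_pos"] >= 0).all()
        assert (coh["cohesion_neg"] <= 0).all()

    def test_zero_connectedness_gives_missing_ratio(self):
        tab = CountTable(np.array([[4, 6], [6, 4]]), ("a", "b"), ("x", "y"))
        conn = pd.DataFrame(
            {"pos_connectedness": [0.0, 0.0], "neg_connectedness": [0.0, 0.0]},
            index=["x", "y"],
        )
        coh = cohesion(tab, conn)
        assert (coh["cohesion_pos"] == 0).all()
        assert coh["np_ratio"].isna().all()


class TestKeystoneRemoval:
    def test_empty_keystone_set(self):
        g = nx.cycle_graph(6)
        out = keystone_removal_test(g, set())
        assert out["delta_v"] == pytest.approx(0.0)

    def test_star_center_removal(self):
        g = nx.star_graph(3)
        out = keystone_removal_test(g, {0})
        assert out["v_before"] == pytest.approx(1.0)
        assert out["v_after"] == pytest.approx(0.0)
        assert out["delta_v"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_removing_isolated_node_preserves_remaining_paths(self, seed):
        g = nx.gnp_random_graph(15, 0.25, seed=seed)
        g.add_node("iso")
        before = dict(nx.all_pairs_shortest_path_length(g))
        h = g.subgraph([v for v in g.nodes if v != "iso"])
        after = dict(nx.all_pairs_shortest_path_length(h))
        for u in h.nodes:
            assert {k: v for k, v in before[u].items() if k != "iso"} == after[u]

    def test_too_few_remaining(self):
        g = nx.path_graph(4)
        with pytest.raises(InvalidInputError):
            keystone_removal_test(g, {0, 1})


class TestCompareStability:
    def test_identical_paired_vectors(self):
        a = np.array([0.4, 0.5, 0.6])
        out = compare_stability(a, a.copy(), test="paired")
        assert out["t"] == 0.0
        assert out["p"] == 1.0

    def test_large_offset_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, 30)
        out = compare_stability(a, a + 5.0, test="welch")
        assert out["p"] < 1e-3

    def test_order_swap_flips_sign(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 20)
        ab = compare_stability(a, b)
        ba = compare_stability(b, a)
        assert ab["t"] == pytest.approx(-ba["t"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_paired_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            compare_stability([1, 2], [1, 2, 3], test="paired")
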