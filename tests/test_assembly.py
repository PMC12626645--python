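import dendropy
import numpy as np
import pandas as pd
import pytest

from netstab.assembly import (
    bmntd,
    bnti,
    partition_processes,
    patristic_matrix,
    rc_bray,
)
from netstab.errors import InvalidInputError
from netstab.io import CountTable
from netstab.synth import simulate_tree


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def _table(counts, taxa):
    counts = np.asarray(counts)
    return CountTable(
        counts, tuple(f"s{i}" for i in range(counts.shape[0])), tuple(taxa)
    )


def brute_force_bmntd(counts, d, weighted=True):
    """Independent all-pairs scan implementation of betaMNTD."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    out = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            if k == l:
                continue
            total = 0.0
            for side, (src, dst) in enumerate(((k, l), (l, k))):
                present_src = np.nonzero(counts[src] > 0)[0]
                present_dst = np.nonzero(counts[dst] > 0)[0]
                if weighted:
                    f = counts[src] / counts[src].sum()
                else:
                    f = (counts[src] > 0) / (counts[src] > 0).sum()
                for i in present_src:
                    total += f[i] * min(d[i, j] for j in present_dst)
            out[k, l] = 0.5 * total
    return out


class TestBmntd:
    def test_identical_communities_are_zero(self):
        tree = _tree("((A:0.3,B:0.5):0.2,C:0.7);")
        tab = _table([[3, 1, 2], [3, 1, 2]], ["A", "B", "C"])
        mat = bmntd(tab, tree).to_numpy()
        np.testing.assert_allclose(mat, 0.0, atol=1e-12)

    def test_two_singleton_communities(self):
        # tips at patristic distance 0.3 + 0.5 = 0.8
        tree = _tree("((A:0.3,B:0.5):0.2,C:0.7);")
        tab = _table([[5, 0, 0], [0, 7, 0]], ["A", "B", "C"])
        mat = bmntd(tab, tree).to_numpy()
        assert mat[0, 1] == pytest.approx(0.8)

    @pytest.mark.parametrize("weighted", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fast_path_matches_brute_force(self, weighted, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(10, seed=seed)
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        counts = rng.integers(0, 20, size=(6, 10))
        counts[counts.sum(axis=1) == 0, 0] = 1
        tab = _table(counts, taxa)
        d = patristic_matrix(tree, taxa)
        fast = bmntd(tab, tree, weighted=weighted).to_numpy()
        brute = brute_force_bmntd(counts, d, weighted=weighted)
        np.testing.assert_allclose(fast, brute, atol=1e-10)

    def test_missing_taxon_reported(self):
        tree = _tree("(A:0.5,B:0.5);")
        tab = _table([[1, 1, 1], [2, 1, 0]], ["A", "B", "Z"])
        with pytest.raises(InvalidInputError, match="Z"):
            bmntd(tab, tree)


class TestBnti:
    def test_symmetric_and_deterministic(self):
        tree = simulate_tree(12, seed=4)
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        rng = np.random.default_rng(4)
        tab = _table(rng.integers(0, 30, size=(5, 12)) + 1, taxa)
        a = bnti(tab, tree, n_null=99, seed=7)
        b = bnti(tab, tree, n_null=99, seed=7)
        z = a.values.to_numpy()
        np.testing.assert_allclose(z, z.T, atol=1e-12)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_minimum_null_count_enforced(self):
        tree = simulate_tree(5, seed=0)
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        tab = _table(np.ones((3, 5), dtype=int), taxa)
        with pytest.raises(InvalidInputError):
            bnti(tab, tree, n_null=10, seed=0)


class TestRcBray:
    def test_identical_samples_near_minus_one(self):
        rng = np.random.default_rng(0)
        row = rng.integers(1, 40, size=12)
        counts = np.vstack([row, row, rng.integers(1, 40, size=12)])
        tab = _table(counts, [f"t{j}" for j in range(12)])
        rc = rc_bray(tab, n_null=199, seed=1).to_numpy()
        assert rc[0, 1] <= -0.9

    def test_disjoint_samples_near_plus_one(self):
        counts = np.zeros((2, 40), dtype=int)
        counts[0, :20] = 5
        counts[1, 20:] = 5
        tab = _table(counts, [f"t{j}" for j in range(40)])
        rc = rc_bray(tab, n_null=199, seed=2).to_numpy()
        assert rc[0, 1] >= 0.9

    def test_bounded(self):
        rng = np.random.default_rng(3)
        tab = _table(rng.integers(0, 15, size=(6, 20)) + 1, [f"t{j}" for j in range(20)])
        rc = rc_bray(tab, n_null=99, seed=3).to_numpy()
        assert (rc >= -1).all() and (rc <= 1).all()


class TestPartition:
    def _matrices(self, bnti_vals, rc_vals, ids):
        b = pd.DataFrame(bnti_vals, index=ids, columns=ids)
        r = pd.DataFrame(rc_vals, index=ids, columns=ids)
        return b, r

    def test_pure_heterogeneous_selection(self):
        ids = list("abc")
        b, r = self._matrices(np.full((3, 3), 3.0), np.zeros((3, 3)), ids)
        part = partition_processes(b, r)
        assert part.fractions["heterogeneous_selection"] == 1.0

    def test_pure_dispersal_limitation(self):
        ids = list("abc")
        b, r = self._matrices(np.zeros((3, 3)), np.full((3, 3), 0.99), ids)
        part = partition_processes(b, r)
        assert part.fractions["dispersal_limitation"] == 1.0

    def test_mixed_toy_matrix(self):
        # 5 samples -> 10 pairs classified by hand:
        # 3 HeS (bnti 3), 2 HoS (-3), 3 DL (0, rc .99), 1 HD (0, rc -.99),
        # 1 drift (0, 0)
        ids = list("abcde")
        b = np.zeros((5, 5))
        r = np.zeros((5, 5))
        pair_specs = {
            (0, 1): (3, 0), (0, 2): (3, 0), (0, 3): (3, 0),
            (0, 4): (-3, 0), (1, 2): (-3, 0),
            (1, 3): (0, 0.99), (1, 4): (0, 0.99), (2, 3): (0, 0.99),
            (2, 4): (0, -0.99),
            (3, 4): (0, 0.0),
        }
        for (i, j), (zb, zr) in pair_specs.items():
            b[i, j] = b[j, i] = zb
            r[i, j] = r[j, i] = zr
        part = partition_processes(*self._matrices(b, r, ids))
        expect = {
            "heterogeneous_selection": 0.3,
            "homogeneous_selection": 0.2,
            "dispersal_limitation": 0.3,
            "homogenizing_dispersal": 0.1,
            "drift": 0.1,
        }
        for key, val in expect.items():
            assert part.fractions[key] == pytest.approx(val)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        b = rng.normal(0, 3, size=(n, n))
        b = (b + b.T) / 2
        r = np.clip(rng.normal(0, 0.8, size=(n, n)), -1, 1)
        r = (r + r.T) / 2
        ids = [f"s{i}" for i in range(n)]
        part = partition_processes(
            pd.DataFrame(b, index=ids, columns=ids),
            pd.DataFrame(r, index=ids, columns=ids),
        )
        assert part.fractions.sum() == pytest.approx(1.0)
        assert len(part.pair_table) == n * (n - 1) // 2

    def test_mismatched_ids_rejected(self):
        b = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        r = pd.DataFrame(np.zeros((2, 2)), index=["a", "c"], columns=["a", "c"])
        with pytest.raises(InvalidInputError):
            partition_processes(b, r)
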