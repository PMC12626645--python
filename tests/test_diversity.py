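import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from netstab.diversity import (
    alpha_diversity,
    anosim,
    bray_curtis,
    compare_alpha,
    pcoa,
    permanova,
)
from netstab.errors import InvalidInputError
from netstab.io import CountTable


def _table(counts, prefix="s"):
    counts = np.asarray(counts)
    return CountTable(
        counts,
        tuple(f"{prefix}{i}" for i in range(counts.shape[0])),
        tuple(f"t{j}" for j in range(counts.shape[1])),
    )


class TestAlphaDiversity:
    def test_uniform_and_single_taxon(self):
        a = alpha_diversity(_table([[5, 5, 5, 5], [10, 0, 0, 0]]))
        assert a.loc["s0", "shannon"] == pytest.approx(np.log(4))
        assert a.loc["s0", "simpson"] == pytest.approx(0.75)
        assert a.loc["s0", "pielou"] == pytest.approx(1.0)
        assert a.loc["s1", "shannon"] == pytest.approx(0.0)
        assert a.loc["s1", "simpson"] == pytest.approx(0.0)
        assert np.isnan(a.loc["s1", "pielou"])  # single observed taxon

    def test_hand_computed_shannon_and_chao(self):
        # counts (1,1,2): H = 1.0397; bias-corrected Chao1 with F1=2, F2=1:
        # 3 + 2*1/(2*(1+1)) = 3.5
        a = alpha_diversity(_table([[1, 1, 2], [4, 4, 8]]))
        assert a.loc["s0", "shannon"] == pytest.approx(1.0397, abs=1e-4)
        assert a.loc["s0", "chao1"] == pytest.approx(3.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            alpha_diversity(_table([[1, 1], [0, 0]]))

    def test_group_comparison_smoke(self):
        rng = np.random.default_rng(0)
        tab = _table(rng.integers(1, 50, size=(10, 8)))
        alpha = alpha_diversity(tab)
        import pandas as pd

        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=alpha.index)
        out = compare_alpha(alpha, groups)
        assert set(out["metric"]) == {"shannon", "simpson", "pielou", "chao1"}
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


class TestBrayCurtis:
    def test_hand_cases(self):
        d = bray_curtis(_table([[1, 0], [0, 1], [1, 0]]))
        assert d[0, 1] == pytest.approx(1.0)  # disjoint
        assert d[0, 2] == pytest.approx(0.0)  # identical composition
        d2 = bray_curtis(_table([[2, 2], [1, 3]]))
        assert d2[0, 1] == pytest.approx(0.25)

    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    @settings(max_examples=50, deadline=None)
    def test_entries_bounded_unit_interval(self, rows):
        d = np.asarray(bray_curtis(_table(rows)).data)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(d, d.T, atol=1e-12)


class TestPcoa:
    def test_points_on_a_line(self):
        d = DistanceMatrix(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=["a", "b", "c"]
        )
        res = pcoa(d)
        x = res.coordinates.iloc[:, 0].to_numpy()
        spacing = np.diff(np.sort(x))
        np.testing.assert_allclose(spacing, [1, 1], atol=1e-8)
        assert np.all(np.abs(res.eigenvalues[1:]) < 1e-8)

    def test_all_zero_distances(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(d)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_input_reproduced_exactly(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((8, 3))
        d = DistanceMatrix.from_iterable(pts, lambda a, b: np.linalg.norm(a - b))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(recon, d.data, atol=1e-8)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 100, size=(10, 12))
        d = bray_curtis(_table(counts))
        ours = pcoa(d)
        ref = skbio_pcoa(d, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates.iloc[:, :3].to_numpy()),
            np.abs(ref.samples.to_numpy()),
            atol=1e-6,
        )


class TestGroupTests:
    def _null_distance(self, seed, n=12):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 100, size=(n, 10))
        return bray_curtis(_table(counts))

    def test_exchangeable_groups_are_null(self):
        # two groups that are exact copies of each other's samples
        counts = np.vstack([np.eye(4, 6, dtype=int) * 5 + 1] * 2)
        d = bray_curtis(_table(counts))
        groups = ["a"] * 4 + ["b"] * 4
        res = permanova(d, groups, n_perm=199, seed=0)
        assert res.r_squared == pytest.approx(0.0, abs=0.05)
        assert res.p_value > 0.5

    def test_disjoint_groups_saturate(self):
        # within-group compositions nearly identical, groups on disjoint taxa:
        # between-group distances ~1, within ~0, so the true labelling is the
        # essentially unique maximizer and p hits the permutation floor
        k = 10
        counts = np.zeros((2 * k, 8), dtype=int)
        for i in range(k):
            counts[i, :4] = [50, 1, 1, 1]
            counts[i, i % 4] += i
            counts[k + i, 4:] = [50, 1, 1, 1]
            counts[k + i, 4 + i % 4] += i
        d = bray_curtis(_table(counts))
        groups = ["a"] * k + ["b"] * k
        # a sampled permutation can tie the observed F only by reproducing
        # the exact split (or its complement), ~1% chance over 999 draws
        res = permanova(d, groups, n_perm=999, seed=1)
        assert res.r_squared > 0.9
        assert res.p_value == pytest.approx(1 / 1000)
        res2 = anosim(d, groups, n_perm=99, seed=0)
        assert res2.statistic == pytest.approx(1.0)

    def test_anosim_null_and_bounds(self):
        d = self._null_distance(3)
        groups = ["a"] * 6 + ["b"] * 6
        res = anosim(d, groups, n_perm=199, seed=1)
        assert -1 <= res.statistic <= 1
        assert abs(res.statistic) < 0.3

    def test_statistics_match_skbio(self):
        d = self._null_distance(4)
        groups = ["a"] * 6 + ["b"] * 6
        ours_f = permanova(d, groups, n_perm=99, seed=0).statistic
        ours_r = anosim(d, groups, n_perm=99, seed=0).statistic
        ref_f = skbio_permanova(d, grouping=list(groups), permutations=0)["test statistic"]
        ref_r = skbio_anosim(d, grouping=list(groups), permutations=0)["test statistic"]
        assert ours_f == pytest.approx(ref_f, rel=1e-10)
        assert ours_r == pytest.approx(ref_r, rel=1e-10)

    def test_small_group_rejected(self):
        d = self._null_distance(5, n=5)
        with pytest.raises(InvalidInputError):
            permanova(d, ["a", "a", "a", "a", "b"], n_perm=9, seed=0)
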