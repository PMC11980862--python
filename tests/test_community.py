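"""Distance, permutation-test, ordination and rank-test contracts.

The Monte-Carlo permutation machinery is checked against two independent
oracles: exhaustive enumeration of all label arrangements on tiny instances,
and scikit-bio's PERMANOVA implementation on a shared distance matrix.
"""

import numpy as np
import pandas as pd
import pytest

from diatomring import (
    AbundanceTable,
    bray_curtis,
    distance_matrix,
    kruskal_wallis,
    mrpp,
    nmds,
    permanova,
)
from diatomring.community import StatsError


def _rel_table(mat, groups):
    cols = [f"E3/{g}/R/{i + 1}" for i, g in enumerate(groups)]
    df = pd.DataFrame(np.asarray(mat, float).T, columns=cols)
    df.index = [f"t{i}" for i in range(df.shape[0])]
    df = df / df.sum(axis=0)
    return AbundanceTable(df, mode="relative")


def _random_dist(n, seed):
    rng = np.random.default_rng(seed)
    X = rng.dirichlet(np.ones(6), size=n)
    from scipy.spatial.distance import pdist, squareform

    return pd.DataFrame(squareform(pdist(X, "braycurtis")))


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_is_one(self):
        assert bray_curtis([0.5, 0.5, 0], [0, 0, 1.0]) == 1.0

    def test_closed_form(self):
        # 1 - 2 * (0.3 + 0.3 + 0) / 2 = 0.4
        assert bray_curtis([0.7, 0.3, 0], [0.3, 0.3, 0.4]) == pytest.approx(0.4)

    def test_symmetry(self):
        x, y = [0.1, 0.9, 0.0], [0.4, 0.2, 0.4]
        assert bray_curtis(x, y) == pytest.approx(bray_curtis(y, x))

    def test_double_empty_undefined(self):
        assert np.isnan(bray_curtis([0.0], [0.0]))

    def test_matrix_properties(self, small_counts):
        from diatomring import to_relative

        dm = distance_matrix(to_relative(small_counts))
        arr = dm.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.all(np.diag(arr) == 0)
        assert arr.min() >= 0 and arr.max() <= 1


class TestPermanova:
    def test_two_distinct_compositions_r2_one(self):
        tab = _rel_table(
            [[10, 0, 5], [10, 0, 5], [0, 10, 5], [0, 10, 5]], ["A", "A", "B", "B"]
        )
        res = permanova(distance_matrix(tab), ["A", "A", "B", "B"], seed=0)
        assert res.effect_size == pytest.approx(1.0)
        assert res.exhaustive  # 6 distinct arrangements

    def test_r2_partition_identity(self):
        dm = _random_dist(8, seed=1)
        groups = list("AABBCCDD")
        res = permanova(dm, groups, n_perm=99, seed=0)
        assert 0.0 <= res.effect_size <= 1.0

    def test_monte_carlo_vs_exhaustive_small_n(self):
        # n=7, groups (4,3): 35 distinct arrangements -> exact available
        dm = _random_dist(7, seed=2)
        groups = list("AAAABBB")
        exact = permanova(dm, groups, seed=0)
        assert exact.exhaustive
        # force Monte-Carlo through a tiny enumeration budget
        import diatomring.community as cs

        old = cs.EXHAUSTIVE_LIMIT
        cs.EXHAUSTIVE_LIMIT = 1
        try:
            mc = permanova(dm, groups, n_perm=2000, seed=3)
        finally:
            cs.EXHAUSTIVE_LIMIT = old
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / mc.n_perm)
        assert abs(mc.p_value - exact.p_value) <= 2 * se + 1e-3

    def test_against_skbio_oracle(self):
        skbio = pytest.importorskip("skbio")
        dm = _random_dist(10, seed=4)
        groups = list("AAABBBCCCC")
        mine = permanova(dm, groups, n_perm=999, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.to_numpy()), grouping=groups, permutations=999
        )
        assert mine.statistic == pytest.approx(float(sk["test statistic"]), rel=1e-9)
        assert abs(mine.p_value - float(sk["p-value"])) < 0.05

    def test_null_p_uniformity(self):
        # structureless data: p should not concentrate near 0
        ps = []
        for seed in range(20):
            dm = _random_dist(9, seed=100 + seed)
            ps.append(permanova(dm, list("AAABBBCCC"), n_perm=199, seed=seed).p_value)
        assert np.mean(np.array(ps) <= 0.05) <= 0.25
        assert min(ps) >= 1 / 200

    def test_p_value_lower_bound(self):
        tab = _rel_table([[10, 0], [10, 0], [0, 10], [0, 10]], ["A", "A", "B", "B"])
        res = permanova(distance_matrix(tab), ["A", "A", "B", "B"], n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            permanova(_random_dist(4, 0), ["A"] * 4)


class TestMRPP:
    def test_perfect_separation(self):
        tab = _rel_table(
            [[10, 0, 3], [10, 0, 3], [0, 10, 6], [0, 10, 6]], ["A", "A", "B", "B"]
        )
        res = mrpp(distance_matrix(tab), ["A", "A", "B", "B"], seed=0)
        assert res.statistic == pytest.approx(0.0)  # delta
        assert res.effect_size == pytest.approx(1.0)  # A

    def test_no_structure_a_near_zero(self):
        vals = []
        for seed in range(10):
            dm = _random_dist(8, seed=200 + seed)
            vals.append(mrpp(dm, list("AABBAABB"), n_perm=199, seed=seed).effect_size)
        assert abs(np.mean(vals)) < 0.05

    def test_monte_carlo_vs_exhaustive(self):
        dm = _random_dist(6, seed=5)
        groups = list("AAABBB")
        exact = mrpp(dm, groups, seed=0)
        assert exact.exhaustive
        import diatomring.community as cs

        old = cs.EXHAUSTIVE_LIMIT
        cs.EXHAUSTIVE_LIMIT = 1
        try:
            mc = mrpp(dm, groups, n_perm=2000, seed=1)
        finally:
            cs.EXHAUSTIVE_LIMIT = old
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / mc.n_perm)
        assert abs(mc.p_value - exact.p_value) <= 2 * se + 1e-3

    def test_singleton_group_excluded(self):
        dm = _random_dist(5, seed=6)
        res = mrpp(dm, ["A", "A", "B", "B", "C"], n_perm=99, seed=0)
        assert res.excluded_groups == ("C",)


class TestNMDS:
    def test_triangle_embeds_with_low_stress(self):
        # an exactly embeddable 2D configuration
        pts = np.array([[0, 0], [1, 0], [0.4, 0.9]])
        from scipy.spatial.distance import pdist, squareform

        dm = pd.DataFrame(squareform(pdist(pts)))
        coords, stress = nmds(dm, k=2, seed=0)
        assert stress < 0.01

    def test_seeded_determinism(self):
        dm = _random_dist(8, seed=7)
        c1, s1 = nmds(dm, seed=42)
        c2, s2 = nmds(dm, seed=42)
        pd.testing.assert_frame_equal(c1, c2)
        assert s1 == s2

    def test_coordinates_centred(self):
        dm = _random_dist(8, seed=8)
        coords, _ = nmds(dm, seed=0)
        assert np.abs(coords.mean(axis=0)).max() < 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(StatsError):
            nmds(_random_dist(2, 0), k=2)


class TestKruskalWallis:
    def test_identical_values(self):
        h, p = kruskal_wallis([5.0] * 6, list("AABBCC"))
        assert h == 0.0 and p == 1.0

    def test_separated_ranks_closed_form(self):
        # two groups n=(3,3), complete separation: ranks (1,2,3) vs (4,5,6)
        # H = 12/(N(N+1)) * sum(R_k^2/n_k) - 3(N+1) = 12/42 * (36/3+225/3) - 21
        h, p = kruskal_wallis([1, 2, 3, 10, 11, 12], list("AAABBB"))
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)

    def test_chi2_vs_permutation_oracle(self):
        # seeded permutation oracle for H >= H_obs; the chi-square
        # approximation is adequate from a dozen observations up
        from scipy.stats import rankdata

        rng = np.random.default_rng(12)
        values = rng.normal(size=12) + np.repeat([0.0, 1.0], 6)
        groups = np.repeat([0, 1], 6)

        def h_stat(vals):
            ranks = rankdata(vals)
            n = len(vals)
            out = sum(ranks[groups == g].sum() ** 2 / 6 for g in (0, 1))
            return 12 / (n * (n + 1)) * out - 3 * (n + 1)

        h_obs, p_chi2 = kruskal_wallis(values.tolist(), groups.tolist())
        perms = [h_stat(rng.permutation(values)) for _ in range(20_000)]
        p_perm = np.mean(np.array(perms) >= h_obs - 1e-12)
        # the chi-square approximation carries O(1/n) error at this size
        assert abs(p_chi2 - p_perm) < 0.1

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            kruskal_wallis([1, 2, 3], ["A", "A", "A"])
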