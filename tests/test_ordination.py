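"""Bray-Curtis, isotonic regression, NMDS, ANOSIM and UPGMA clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from trflp.ordination import (
    DistanceMatrix,
    _kruskal_stress,
    anosim_test,
    bray_curtis,
    monotone_regression,
    nmds_embed,
    upgma_cluster,
)
from trflp.profiles import CommunityMatrix, TRFBin


def _matrix(rows: dict[str, list[float]]) -> CommunityMatrix:
    table = pd.DataFrame(rows).T
    table = table.div(table.sum(axis=1), axis=0)
    bins = tuple(TRFBin(float(100 + 10 * j)) for j in range(table.shape[1]))
    table.columns = [b.label for b in bins]
    return CommunityMatrix("DdeI", bins, table)


def _dm(labels, square):
    return DistanceMatrix(tuple(labels), np.asarray(square, dtype=float))


class TestBrayCurtis:
    def test_disjoint_compositions_are_maximally_dissimilar(self):
        m = _matrix({"s1": [1, 0], "s2": [0, 1]})
        assert bray_curtis(m).d[0, 1] == pytest.approx(1.0)

    def test_identical_compositions_have_zero_distance(self):
        m = _matrix({"s1": [0.3, 0.7], "s2": [0.3, 0.7]})
        assert bray_curtis(m).d[0, 1] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        m = _matrix({"s1": [0.6, 0.4], "s2": [0.4, 0.6]})
        assert bray_curtis(m).d[0, 1] == pytest.approx(0.2)

    def test_percent_similarity_scale(self):
        m = _matrix({"s1": [0.6, 0.4], "s2": [0.4, 0.6]})
        sim = bray_curtis(m).similarity_percent()
        assert sim[0, 1] == pytest.approx(80.0)

    def test_two_empty_samples_rejected(self):
        table = pd.DataFrame({"100.0": [0.0, 0.0]}, index=["s1", "s2"])
        m = CommunityMatrix("DdeI", (TRFBin(100.0),), table)
        with pytest.raises(ValueError, match="undefined"):
            bray_curtis(m)


class TestMonotoneRegression:
    def test_pool_adjacent_violators_by_hand(self):
        fit = monotone_regression([1, 2, 3], [1, 3, 2])
        assert np.allclose(fit, [1, 2.5, 2.5])

    def test_already_monotone_unchanged(self):
        assert np.allclose(monotone_regression([1, 2, 3], [1, 2, 3]), [1, 2, 3])

    def test_constant_unchanged(self):
        assert np.allclose(monotone_regression([1, 2, 3], [2, 2, 2]), [2, 2, 2])

    def test_matches_sklearn_isotonic_on_random_data(self):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            d = rng.random(n)
            y = rng.random(n)
            ours = monotone_regression(d, y)
            ref = IsotonicRegression().fit_transform(d, y)
            assert np.allclose(np.sort(ours), np.sort(ref), atol=1e-12)

    def test_tied_d_block_is_free_to_reorder(self):
        # with both d tied, any order is monotone: fit equals the target
        fit = monotone_regression([1, 1], [3, 2])
        assert sorted(fit) == [2, 3]


class TestNMDS:
    def test_right_triangle_embeds_perfectly(self):
        d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        res = nmds_embed(_dm("ABC", d), n_starts=8, seed=0)
        assert res.stress < 1e-3

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 2))
        d = squareform(pdist(pts))
        res = nmds_embed(_dm("ABCDEF", d), n_starts=20, seed=1)
        assert res.stress < 0.01
        rho = spearmanr(pdist(res.coordinates), squareform(d, checks=False))[0]
        assert rho > 0.99

    def test_more_starts_never_worse(self):
        rng = np.random.default_rng(5)
        d = squareform(pdist(rng.random((7, 3))))  # 3-D data in 2-D: stress > 0
        dm = _dm("ABCDEFG", d)
        s1 = nmds_embed(dm, n_starts=1, seed=42).stress
        s5 = nmds_embed(dm, n_starts=5, seed=42).stress
        assert s5 <= s1 + 1e-12

    def test_stress_matches_formula_on_returned_solution(self):
        rng = np.random.default_rng(7)
        d = squareform(pdist(rng.random((6, 3))))
        res = nmds_embed(_dm("ABCDEF", d), n_starts=4, seed=9)
        cd = pdist(res.coordinates)
        assert res.stress == pytest.approx(_kruskal_stress(cd, res.disparities))

    def test_rigid_motion_leaves_stress_unchanged(self):
        rng = np.random.default_rng(11)
        delta = pdist(rng.random((8, 2)))
        x = rng.random((8, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        for y in (x, x @ rot + [3.0, -1.0], 2.5 * x):
            cd = pdist(y)
            disp = monotone_regression(delta, cd)
            stress = _kruskal_stress(cd, disp)
            if y is x:
                base = stress
            else:
                assert stress == pytest.approx(base, abs=1e-10)

    def test_too_few_samples_or_dims_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            nmds_embed(_dm("AB", d))
        d3 = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        with pytest.raises(ValueError):
            nmds_embed(_dm("ABC", d3), k=3)


def _separated_dm():
    # all between-distances (0.8-0.9) exceed all within-distances (0.1-0.2)
    d = np.array([
        [0.0, 0.1, 0.8, 0.9],
        [0.1, 0.0, 0.85, 0.82],
        [0.8, 0.85, 0.0, 0.2],
        [0.9, 0.82, 0.2, 0.0],
    ])
    return _dm(["a1", "a2", "b1", "b2"], d)


class TestANOSIM:
    LABELS = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_perfect_separation_exact_enumeration(self):
        res = anosim_test(_separated_dm(), self.LABELS, n_permutations=999)
        assert res.R == pytest.approx(1.0)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_inverted_separation_gives_minus_one(self):
        # groups straddle the clusters so the two largest distances are the
        # within-group ones: maximal inversion
        labels = {"a1": "A", "b2": "A", "a2": "B", "b1": "B"}
        res = anosim_test(_separated_dm(), labels, n_permutations=999)
        assert res.R == pytest.approx(-1.0)

    def test_rank_based_R_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        d = squareform(pdist(rng.random((8, 3))))
        labels = {f"s{i}": "A" if i < 4 else "B" for i in range(8)}
        dm1 = _dm(list(labels), d)
        dm2 = _dm(list(labels), d**2)  # monotone transform preserves ranks
        r1 = anosim_test(dm1, labels, n_permutations=99, seed=0).R
        r2 = anosim_test(dm2, labels, n_permutations=99, seed=0).R
        assert r1 == pytest.approx(r2)

    def test_statistic_matches_scikit_bio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(17)
        d = squareform(pdist(rng.random((9, 4))))
        labels = {f"s{i}": f"g{i % 3}" for i in range(9)}
        dm = _dm(list(labels), d)
        ours = anosim_test(dm, labels, n_permutations=99, seed=0)
        ref = skbio_anosim(
            SkbioDM(d, ids=list(labels)),
            grouping=[labels[s] for s in labels],
            permutations=0,
        )
        assert ours.R == pytest.approx(float(ref["test statistic"]))

    def test_sampled_p_close_to_exact_p(self):
        rng = np.random.default_rng(19)
        d = squareform(pdist(rng.random((7, 2))))
        labels = {f"s{i}": "A" if i < 3 else "B" for i in range(7)}
        dm = _dm(list(labels), d)
        exact = anosim_test(dm, labels, n_permutations=10_000)
        assert exact.method == "exact"  # 35 distinct labelings
        forced = _sampled_p(dm, labels, 9_999, seed=3)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 9_999)
        assert abs(forced - exact.p_value) <= 3 * se + 1e-4

    def test_null_R_is_centered_at_zero(self):
        rng = np.random.default_rng(23)
        rs = []
        labels = {f"s{i}": "A" if i < 4 else "B" for i in range(8)}
        for _ in range(100):
            d = squareform(pdist(rng.random((8, 2))))
            dm = _dm(list(labels), d)
            rs.append(anosim_test(dm, labels, n_permutations=19, seed=1).R)
        assert abs(np.mean(rs)) < 0.05

    def test_pairwise_results_cover_all_group_pairs(self):
        rng = np.random.default_rng(29)
        d = squareform(pdist(rng.random((9, 3))))
        labels = {f"s{i}": f"g{i % 3}" for i in range(9)}
        res = anosim_test(_dm(list(labels), d), labels, n_permutations=99, seed=0)
        assert set(res.pairwise) == {("g0", "g1"), ("g0", "g2"), ("g1", "g2")}
        for r, p in res.pairwise.values():
            assert -1 <= r <= 1 and 0 < p <= 1

    def test_singleton_group_rejected(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "C"}
        with pytest.raises(ValueError, match="size 1"):
            anosim_test(_separated_dm(), labels)


def _sampled_p(dm, labels, m, seed):
    """Monte-Carlo p ignoring the exact-enumeration shortcut (test helper)."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    order = list(dm.labels)
    g = np.array([labels[s] for s in order])
    codes = np.array([sorted(set(g)).index(x) for x in g])
    n = len(order)
    rank_c = rankdata(dm.condensed)
    iu, ju = np.triu_indices(n, k=1)

    def r_for(gv):
        within = gv[iu] == gv[ju]
        return (rank_c[~within].mean() - rank_c[within].mean()) / (n * (n - 1) / 4)

    r_obs = r_for(codes)
    count = sum(r_for(rng.permutation(codes)) >= r_obs - 1e-12 for _ in range(m))
    return (1 + count) / (1 + m)


class TestUPGMA:
    def test_hand_worked_merge_heights(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]])
        dendro = upgma_cluster(_dm("ABC", d))
        assert np.allclose(dendro.heights, [0.2, 0.7])
        assert np.allclose(dendro.similarity_levels(), [80.0, 30.0])

    def test_two_samples_single_merge(self):
        d = np.array([[0, 0.3], [0.3, 0]])
        dendro = upgma_cluster(_dm("AB", d))
        assert np.allclose(dendro.heights, [0.3])
        assert dendro.to_newick() == "(A:0.15,B:0.15);"

    def test_equidistant_samples_have_equal_heights(self):
        d = np.full((3, 3), 0.4)
        np.fill_diagonal(d, 0.0)
        dendro = upgma_cluster(_dm("ABC", d))
        assert np.allclose(dendro.heights, 0.4)

    def test_cophenetic_distances_are_ultrametric(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            x = rng.random((6, 4))
            d = squareform(pdist(x) / pdist(x).max())
            dendro = upgma_cluster(_dm("ABCDEF", d))
            c = squareform(dendro.cophenetic())
            n = c.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert c[i, j] <= max(c[i, k], c[k, j]) + 1e-12

    def test_newick_leaf_depths_equal_half_merge_height(self):
        from skbio import TreeNode
        import io

        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]])
        dendro = upgma_cluster(_dm("ABC", d))
        tree = TreeNode.read(io.StringIO(dendro.to_newick()))
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        root_height = dendro.heights.max() / 2
        for depth in depths.values():
            assert depth == pytest.approx(root_height)
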