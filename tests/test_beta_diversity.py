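import io

import dendropy
import numpy as np
import pandas as pd
import pytest
import skbio
from skbio.diversity import beta_diversity as skbio_beta
from skbio.stats.distance import permanova as skbio_permanova

from assemblage.beta_diversity import (
    DistanceMatrixResult,
    bh_fdr,
    branch_structure,
    generalized_unifrac,
    pairwise_permanova,
    pcoa,
    permanova_one_way,
    permanova_two_way,
    unifrac_matrix,
    unweighted_unifrac,
)
from assemblage.community_io import CommunityTable, normalize_proportions
from assemblage.synthetic_data import simulate_tree

FOUR_TIP = "((A:1,B:1):1,(C:1,D:1):1);"


def oracle_generalized_unifrac(newick, ids, pa, pb, alpha):
    """Independent per-branch tally via explicit leaf enumeration per edge."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pos = {a: i for i, a in enumerate(ids)}
    num = den = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        leaves = [l.taxon.label for l in edge.head_node.leaf_iter()]
        qa = sum(pa[pos[l]] for l in leaves if l in pos)
        qb = sum(pb[pos[l]] for l in leaves if l in pos)
        if qa + qb == 0:
            continue
        w = edge.length * (qa + qb) ** alpha
        num += w * abs(qa - qb) / (qa + qb)
        den += w
    return num / den


class TestUnifrac:
    def test_hand_worked_unweighted(self):
        L, M = branch_structure(FOUR_TIP, list("ABCD"))
        d = unweighted_unifrac([1, 1, 0, 0], [1, 0, 1, 0], L, M)
        assert d == pytest.approx(0.6, abs=1e-12)

    def test_identical_and_disjoint(self):
        L, M = branch_structure(FOUR_TIP, list("ABCD"))
        assert unweighted_unifrac([1, 1, 0, 0], [1, 1, 0, 0], L, M) == 0.0
        assert unweighted_unifrac([1, 1, 0, 0], [0, 0, 1, 1], L, M) == 1.0
        assert generalized_unifrac([0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5], L, M) == pytest.approx(1.0)
        assert generalized_unifrac([0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0], L, M) == pytest.approx(0.0)

    def test_unweighted_matches_skbio_on_random_data(self, rng):
        nwk = simulate_tree(12, 3)
        ids = [f"ASV{i + 1:04d}" for i in range(12)]
        counts = (rng.poisson(2, size=(5, 12)) * (rng.random((5, 12)) > 0.3)).astype(int)
        counts[counts.sum(axis=1) == 0, 0] = 1
        sk_tree = skbio.TreeNode.read(io.StringIO(nwk))
        expected = skbio_beta("unweighted_unifrac", counts, ids=[f"s{i}" for i in range(5)],
                              taxa=ids, tree=sk_tree)
        L, M = branch_structure(nwk, ids)
        for i in range(5):
            for j in range(i + 1, 5):
                got = unweighted_unifrac(counts[i] > 0, counts[j] > 0, L, M)
                assert got == pytest.approx(expected[i, j], abs=1e-9)

    def test_generalized_matches_independent_tally(self, rng):
        for seed in range(5):
            nwk = simulate_tree(10, seed)
            ids = [f"ASV{i + 1:04d}" for i in range(10)]
            pa = rng.random(10) * (rng.random(10) > 0.3)
            pb = rng.random(10) * (rng.random(10) > 0.3)
            if pa.sum() == 0 or pb.sum() == 0:
                continue
            pa, pb = pa / pa.sum(), pb / pb.sum()
            L, M = branch_structure(nwk, ids)
            got = generalized_unifrac(pa, pb, L, M, alpha=0.5)
            want = oracle_generalized_unifrac(nwk, ids, pa, pb, 0.5)
            assert got == pytest.approx(want, abs=1e-10)
            assert got == pytest.approx(generalized_unifrac(pb, pa, L, M, 0.5), abs=1e-12)

    def test_unweighted_invariant_to_abundance(self, rng):
        ids = [f"ASV{i + 1:04d}" for i in range(8)]
        nwk = simulate_tree(8, 1)
        counts = pd.DataFrame(rng.poisson(3, size=(8, 4)) + 1, index=ids,
                              columns=list("wxyz"))
        counts.iloc[0, 0] = 0
        meta = pd.DataFrame(index=counts.columns)
        rel1 = normalize_proportions(CommunityTable(counts, meta))
        rel2 = normalize_proportions(CommunityTable(counts * 7, meta))
        d1 = unifrac_matrix(rel1, nwk, metric="unweighted")
        d2 = unifrac_matrix(rel2, nwk, metric="unweighted")
        np.testing.assert_allclose(d1.dist, d2.dist, atol=1e-12)

    def test_matrix_bounds_and_symmetry(self, rng):
        ids = [f"ASV{i + 1:04d}" for i in range(8)]
        counts = pd.DataFrame(rng.poisson(3, size=(8, 5)) + 1, index=ids,
                              columns=[f"s{i}" for i in range(5)])
        rel = normalize_proportions(CommunityTable(counts, pd.DataFrame(index=counts.columns)))
        dm = unifrac_matrix(rel, simulate_tree(8, 2), metric="generalized")
        assert np.allclose(dm.dist, dm.dist.T)
        assert (dm.dist >= 0).all() and (dm.dist <= 1).all()


class TestPcoa:
    def test_collinear_points_single_axis(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        coords, pct = pcoa(D, 2)
        assert pct[0] == pytest.approx(100.0)

    def test_identical_samples_zero_coordinates(self):
        D = np.zeros((4, 4))
        coords, _ = pcoa(D, 2)
        np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-9)

    def test_euclidean_round_trip(self, rng):
        pts = rng.random((6, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, _ = pcoa(D, 5)
        got = np.sqrt(((coords.to_numpy()[:, None] - coords.to_numpy()[None]) ** 2).sum(-1))
        np.testing.assert_allclose(got, D, atol=1e-8)


class TestPermanova:
    def _random_dm(self, rng, n):
        pts = rng.random((n, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return D

    def test_one_way_statistic_matches_skbio(self, rng):
        for _ in range(5):
            D = self._random_dm(rng, 8)
            labels = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"s{i}" for i in range(8)])
            F, _ = permanova_one_way(D, labels, n_perm=9, seed=0)
            sk = skbio_permanova(skbio.DistanceMatrix(D, ids=list(labels.index)),
                                 labels.to_numpy(), permutations=9)
            assert F == pytest.approx(sk["test statistic"], abs=1e-9)

    def test_two_way_total_df_and_terms(self, rng):
        D = self._random_dm(rng, 12)
        ids = [f"s{i}" for i in range(12)]
        meta = pd.DataFrame({"A": ["a1", "a2"] * 6, "B": ["b1"] * 6 + ["b2"] * 6}, index=ids)
        res = permanova_two_way(DistanceMatrixResult("euclid", ids, D, {}), meta,
                                "A", "B", n_perm=99, seed=1)
        total = res[res.term == "Total"].iloc[0]
        assert total.df == 11
        assert set(res.term) == {"A", "B", "A x B", "Residual", "Total"}
        assert res[res.term != "Total"].df.sum() == 11
        assert res.loc[res.term == "A", "SS"].iloc[0] + res.loc[res.term == "B", "SS"].iloc[0] >= 0

    def test_separated_groups_reach_minimum_p(self):
        # within-group distance 0, between-group 1: permutation minimum p
        n = 6
        D = np.ones((n, n))
        D[:3, :3] = 0
        D[3:, 3:] = 0
        np.fill_diagonal(D, 0)
        labels = pd.Series(["g1"] * 3 + ["g2"] * 3, index=[f"s{i}" for i in range(n)])
        F, p = permanova_one_way(D, labels, n_perm=199, seed=0)
        # 10 of the 20 distinct splits reproduce the same extreme statistic
        assert p <= 0.15
        assert F > 1e6 or np.isinf(F)

    def test_two_way_raw_and_residual_agree_on_signal(self, rng):
        pts = np.concatenate([rng.normal(0, 0.05, (6, 2)), rng.normal(3, 0.05, (6, 2))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        meta = pd.DataFrame({"A": ["a1"] * 6 + ["a2"] * 6,
                             "B": ["b1", "b2"] * 6}, index=ids)
        for scheme in ("raw", "residual"):
            res = permanova_two_way(DistanceMatrixResult("e", ids, D, {}), meta,
                                    "A", "B", n_perm=199, seed=2, scheme=scheme)
            assert res.loc[res.term == "A", "p"].iloc[0] <= 0.01
            assert res.loc[res.term == "B", "p"].iloc[0] > 0.05

    def test_small_cells_raise(self, rng):
        D = self._random_dm(rng, 5)
        ids = [f"s{i}" for i in range(5)]
        meta = pd.DataFrame({"A": ["a1", "a1", "a2", "a2", "a2"],
                             "B": ["b1", "b1", "b1", "b2", "b2"]}, index=ids)
        with pytest.raises(ValueError, match="<2"):
            permanova_two_way(DistanceMatrixResult("e", ids, D, {}), meta, "A", "B", n_perm=9)


class TestPairwise:
    def test_single_pair_adjusted_equals_raw(self, rng):
        pts = rng.random((8, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(8)]
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        res = pairwise_permanova(DistanceMatrixResult("e", ids, D, {}), labels,
                                 n_perm=99, seed=0)
        assert len(res) == 1
        assert res.loc[0, "p_adj"] == res.loc[0, "p"]

    def test_separated_groups_all_significant(self):
        n = 9
        D = np.ones((n, n))
        for k in range(3):
            D[3 * k:3 * k + 3, 3 * k:3 * k + 3] = 0
        np.fill_diagonal(D, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=ids)
        res = pairwise_permanova(DistanceMatrixResult("e", ids, D, {}), labels,
                                 n_perm=999, seed=1)
        assert (res["t"] > 10).all() or (res["pseudo_F"] > 100).all()


class TestBhFdr:
    def test_hand_worked(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_and_ties(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr([0.05, 0.05, 0.05]), [0.05, 0.05, 0.05])

    def test_monotone_bounded_and_conservative(self, rng):
        p = rng.random(20)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
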