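import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from assemblage.community_io import CommunityTable, PhyloDistances, normalize_proportions
from assemblage.phylo_dispersion import (
    _independent_swap_array,
    mntd_weighted,
    null_independent_swap,
    null_taxa_labels,
    ses_mntd,
    t_test_vs_zero,
)

from .conftest import TOY_NEWICK, random_table


def brute_force_mntd(weights, dist):
    """Independent oracle: explicit nearest-neighbour enumeration."""
    present = [i for i, w in enumerate(weights) if w > 0]
    tot = sum(weights[i] for i in present)
    acc = 0.0
    for i in present:
        nn = min(dist[i][j] for j in present if j != i)
        acc += (weights[i] / tot) * nn
    return acc


class TestMntd:
    def test_two_taxon_community(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert mntd_weighted([0.5, 0.5], d) == pytest.approx(2.0)

    def test_hand_worked_three_taxon(self, toy_dist):
        # f = (A:0.5, B:0.25, C:0.25): 0.5*1 + 0.25*1 + 0.25*4 = 1.75
        assert mntd_weighted([0.5, 0.25, 0.25], toy_dist) == pytest.approx(1.75)

    def test_matches_brute_force_on_random_communities(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 10))
            m = rng.uniform(0.1, 5, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            w = rng.random(n) * (rng.random(n) > 0.3)
            if (w > 0).sum() < 2:
                continue
            w = w / w.sum()
            assert mntd_weighted(w, d) == pytest.approx(brute_force_mntd(w, d), abs=1e-12)

    def test_single_present_taxon_raises(self, toy_dist):
        with pytest.raises(ValueError):
            mntd_weighted([1.0, 0.0, 0.0], toy_dist)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_mntd_matches_picante_oracle(tmp_path, toy_dist):
    """Cross-check abundance-weighted MNTD against the reference R implementation."""
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(picante))\n'
        f'tree <- read.tree(text="{TOY_NEWICK}")\n'
        'dis <- cophenetic(tree)\n'
        'samp <- matrix(c(0.5,0.25,0.25, 0.2,0.3,0.5), nrow=2, byrow=TRUE)\n'
        'colnames(samp) <- c("A","B","C"); rownames(samp) <- c("s1","s2")\n'
        'cat(sprintf("%.10f\\n", mntd(samp, dis[colnames(samp), colnames(samp)], abundance.weighted=TRUE)))\n'
    )
    out = subprocess.run(["Rscript", "--vanilla", str(script)],
                         capture_output=True, text=True, timeout=240)
    assert out.returncode == 0, out.stderr
    vals = [float(x) for x in out.stdout.split()]
    assert mntd_weighted([0.5, 0.25, 0.25], toy_dist) == pytest.approx(vals[0], abs=1e-8)
    assert mntd_weighted([0.2, 0.3, 0.5], toy_dist) == pytest.approx(vals[1], abs=1e-8)


class TestTaxaLabelsNull:
    def test_offdiagonal_multiset_preserved(self, toy_dist, rng):
        null = null_taxa_labels(toy_dist, rng)
        assert sorted(null.dist[np.triu_indices(3, 1)]) == sorted(
            toy_dist.dist[np.triu_indices(3, 1)])

    def test_two_taxon_matrix_invariant(self, rng):
        d = PhyloDistances(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        for _ in range(5):
            np.testing.assert_array_equal(null_taxa_labels(d, rng).dist, d.dist)


class TestIndependentSwap:
    def test_single_checkerboard_swaps(self, rng):
        counts = np.array([[5, 0], [0, 7]])
        out = _independent_swap_array(counts, 1, rng)
        np.testing.assert_array_equal(out, np.array([[0, 5], [7, 0]]))

    def test_occurrence_margins_preserved_random(self, rng):
        for _ in range(200):
            M = rng.poisson(2, size=(8, 6)) * (rng.random((8, 6)) > 0.4)
            out = _independent_swap_array(M.astype(np.int64), 50, rng)
            np.testing.assert_array_equal((out > 0).sum(0), (M > 0).sum(0))
            np.testing.assert_array_equal((out > 0).sum(1), (M > 0).sum(1))
            # per-row abundance multisets carried with the presences
            for r in range(8):
                assert sorted(out[r][out[r] > 0]) == sorted(M[r][M[r] > 0])

    def test_full_matrix_unchanged(self, rng):
        M = np.ones((4, 4), dtype=np.int64)
        np.testing.assert_array_equal(_independent_swap_array(M, 10, rng), M)

    def test_table_wrapper(self, rng):
        tab = random_table(rng)
        out = null_independent_swap(tab, 20, rng)
        assert out.asv_ids == tab.asv_ids
        assert out.counts.to_numpy().sum() == tab.counts.to_numpy().sum()


class TestSesMntd:
    def test_neutral_random_assignment_centers_near_zero(self, rng):
        # data whose taxon placement is exchangeable with the null
        ses_all = []
        for rep in range(15):
            tab = random_table(np.random.default_rng(rep), n_taxa=15, n_samples=4)
            m = np.random.default_rng(100 + rep).uniform(0.5, 3, size=(15, 15))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            dist = PhyloDistances(tab.asv_ids, d)
            rel = normalize_proportions(tab)
            res = ses_mntd(rel, dist, n_perm=99, group_by=None, seed=rep)
            ses_all.extend(res["ses"].dropna())
        assert abs(np.mean(ses_all)) < 0.4

    def test_degenerate_null_flagged_nan(self):
        # equidistant taxa: every relabeling gives the same MNTD
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0)
        dist = PhyloDistances(["A", "B", "C"], d)
        counts = pd.DataFrame({"S1": [1, 1, 1], "S2": [2, 1, 1]}, index=["A", "B", "C"])
        meta = pd.DataFrame(index=["S1", "S2"])
        rel = normalize_proportions(CommunityTable(counts, meta))
        with pytest.warns(UserWarning, match="degenerate"):
            res = ses_mntd(rel, dist, n_perm=19, group_by=None, seed=0)
        assert res["ses"].isna().all()
        assert (res["null_sd"] == 0).all()

    def test_sparse_samples_skipped(self, toy_dist):
        counts = pd.DataFrame({"S1": [4, 0, 0], "S2": [1, 1, 1]}, index=["A", "B", "C"])
        rel = normalize_proportions(CommunityTable(counts, pd.DataFrame(index=["S1", "S2"])))
        with pytest.warns(UserWarning, match="<2 taxa"):
            res = ses_mntd(rel, toy_dist, n_perm=19, group_by=None, seed=0)
        assert list(res["sample_id"]) == ["S2"]

    def test_unknown_null_raises(self, small_rel, toy_dist):
        with pytest.raises(ValueError, match="null model"):
            ses_mntd(small_rel, toy_dist, null_model="bogus", group_by=None)


class TestTTest:
    def test_hand_worked_values(self):
        res = t_test_vs_zero([1.0, 2.0, 3.0], "g")
        assert res.mean == pytest.approx(2.0)
        assert res.df == 2
        assert res.t == pytest.approx(3.4641016, abs=1e-6)
        assert res.p == pytest.approx(0.0742, abs=2e-4)

    def test_symmetric_values_give_t_zero(self):
        res = t_test_vs_zero([-1.0, 0.0, 1.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("vals", [[1.0, 1.0, 1.0], [0.5, 0.5]])
    def test_degenerate_inputs_raise(self, vals):
        with pytest.raises(ValueError):
            t_test_vs_zero(vals)


def test_group_ttest_type_one_error_near_nominal():
    """SES scored against data generated under its own null keeps the
    group t-test's false-positive rate near the nominal level."""
    alpha = 0.05
    reject = 0
    n_reps = 300
    base = np.random.default_rng(2024)
    for rep in range(n_reps):
        rng = np.random.default_rng(base.integers(2**31 - 1))
        n_taxa, n_samples = 14, 8
        m = rng.uniform(0.5, 3, size=(n_taxa, n_taxa))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        counts = (rng.poisson(3, size=(n_taxa, n_samples))
                  * (rng.random((n_taxa, n_samples)) > 0.4)).astype(np.int64)
        for s in range(n_samples):
            while (counts[:, s] > 0).sum() < 2:
                counts[rng.integers(n_taxa), s] += 1
        ids = [f"T{i}" for i in range(n_taxa)]
        tab = CommunityTable(pd.DataFrame(counts, index=ids,
                                          columns=[f"S{j}" for j in range(n_samples)]),
                             pd.DataFrame(index=[f"S{j}" for j in range(n_samples)]))
        rel = normalize_proportions(tab)
        dist = PhyloDistances(ids, d)
        res = ses_mntd(rel, dist, n_perm=99, group_by=None,
                       seed=int(rng.integers(2**31 - 1)))
        vals = res["ses"].dropna()
        if len(vals) >= 3 and vals.std() > 0:
            if t_test_vs_zero(vals).p < alpha:
                reject += 1
    assert abs(reject / n_reps - alpha) < 0.035
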