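"""Within-sample phylogenetic dispersion: abundance-weighted MNTD and its
standardized effect size (ses.MNTD) under permutation null models.

MNTD (mean nearest taxon distance) averages, over the taxa present in one
sample, the cophenetic distance to each taxon's closest co-occurring
relative, weighted by relative abundance.  Comparing the observed value with
a null distribution gives ses.MNTD = (obs - null_mean) / null_sd; negative
mean SES across samples indicates phylogenetic clustering (a filtering
signature), positive indicates overdispersion.

Two nulls are supported:

* ``taxa_labels`` — shuffle the taxon labels of the distance matrix,
  destroying phylogenetic structure while keeping community structure.
* ``independent_swap`` — checkerboard swaps of the presence pattern that
  preserve both per-sample richness and per-taxon occurrence frequency,
  carrying abundances with the presences (the conservative null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_io import CommunityTable, PhyloDistances, RelAbundanceTable

__all__ = [
    "SesResult",
    "GroupTest",
    "mntd_weighted",
    "null_taxa_labels",
    "null_independent_swap",
    "ses_mntd",
    "t_test_vs_zero",
    "dispersion_analysis",
]


@dataclass
class SesResult:
    unit_id: str
    group: str
    obs: float
    null_mean: float
    null_sd: float
    ses: float
    n_perm: int


@dataclass
class GroupTest:
    group: str
    mean: float
    df: int
    t: float
    p: float
    n: int


def mntd_weighted(weights, dist: PhyloDistances | np.ndarray) -> float:
    """Abundance-weighted mean nearest taxon distance for one sample.

    ``sum_i f_i * min_{j != i, f_j > 0} d_ij`` over present taxa, with the
    weights renormalized over present taxa.  Requires >= 2 present taxa.
    """
    w = np.asarray(weights, dtype=float)
    D = dist.dist if isinstance(dist, PhyloDistances) else np.asarray(dist, dtype=float)
    if w.shape[0] != D.shape[0]:
        raise ValueError("weights and distance matrix are not aligned")
    present = np.flatnonzero(w > 0)
    if present.size < 2:
        raise ValueError("MNTD needs at least 2 taxa with positive weight")
    sub = D[np.ix_(present, present)].copy()
    np.fill_diagonal(sub, np.inf)
    nn = sub.min(axis=1)
    f = w[present] / w[present].sum()
    return float(f @ nn)


def null_taxa_labels(dist: PhyloDistances, rng: np.random.Generator) -> PhyloDistances:
    """Jointly permute rows/columns of the distance matrix (label shuffle)."""
    perm = rng.permutation(len(dist.ids))
    return PhyloDistances(list(dist.ids), dist.dist[np.ix_(perm, perm)])


def _independent_swap_array(counts: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    """Checkerboard-swap the taxa x sample matrix, carrying abundances.

    Performs up to ``n_swaps`` successful 2x2 swaps; occurrence row and column
    sums are exactly preserved.  A matrix with no checkerboard submatrix is
    returned unchanged.
    """
    M = counts.copy()
    n, m = M.shape
    if n < 2 or m < 2:
        return M
    swaps = 0
    attempts = 0
    max_attempts = max(20_000, 200 * n_swaps)
    chunk = 4096
    while swaps < n_swaps and attempts < max_attempts:
        r = rng.integers(0, n, size=(chunk, 2))
        c = rng.integers(0, m, size=(chunk, 2))
        attempts += chunk
        # vectorized prefilter; candidates are re-checked sequentially since
        # an earlier swap in the batch can invalidate a later one
        a = M[r[:, 0], c[:, 0]]
        b = M[r[:, 0], c[:, 1]]
        cc = M[r[:, 1], c[:, 0]]
        d = M[r[:, 1], c[:, 1]]
        distinct = (r[:, 0] != r[:, 1]) & (c[:, 0] != c[:, 1])
        cand = distinct & (((a > 0) & (d > 0) & (b == 0) & (cc == 0))
                           | ((b > 0) & (cc > 0) & (a == 0) & (d == 0)))
        for idx in np.flatnonzero(cand):
            if swaps >= n_swaps:
                break
            r1, r2 = r[idx]
            c1, c2 = c[idx]
            va, vb, vc, vd = M[r1, c1], M[r1, c2], M[r2, c1], M[r2, c2]
            if va > 0 and vd > 0 and vb == 0 and vc == 0:
                M[r1, c2], M[r1, c1] = va, 0
                M[r2, c1], M[r2, c2] = vd, 0
                swaps += 1
            elif vb > 0 and vc > 0 and va == 0 and vd == 0:
                M[r1, c1], M[r1, c2] = vb, 0
                M[r2, c2], M[r2, c1] = vc, 0
                swaps += 1
    return M


def null_independent_swap(table: CommunityTable, n_swaps: int, rng: np.random.Generator) -> CommunityTable:
    """Independent-swap null table (fixed richness and occurrence frequencies)."""
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    arr = _independent_swap_array(table.counts.to_numpy(), n_swaps, rng)
    return CommunityTable(pd.DataFrame(arr, index=table.asv_ids, columns=table.sample_ids),
                          table.metadata.copy())


def _null_mntd_taxa_labels(W: np.ndarray, D: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Null MNTD matrix (n_perm x n_samples) under shared label shuffles."""
    n = D.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    out = np.full((n_perm, W.shape[1]), np.nan)
    present_sets = [np.flatnonzero(W[:, s] > 0) for s in range(W.shape[1])]
    for s, P in enumerate(present_sets):
        if P.size < 2:
            continue
        f = W[P, s] / W[P, s].sum()
        for r in range(n_perm):
            idx = perms[r][P]
            sub = D[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, np.inf)
            out[r, s] = f @ sub.min(axis=1)
    return out


def _null_mntd_independent_swap(W: np.ndarray, D: np.ndarray, n_perm: int, n_swaps: int, rng) -> np.ndarray:
    out = np.full((n_perm, W.shape[1]), np.nan)
    for r in range(n_perm):
        Wn = _independent_swap_array(W, n_swaps, rng)
        for s in range(W.shape[1]):
            P = np.flatnonzero(Wn[:, s] > 0)
            if P.size < 2:
                continue
            sub = D[np.ix_(P, P)].copy()
            np.fill_diagonal(sub, np.inf)
            f = Wn[P, s] / Wn[P, s].sum()
            out[r, s] = f @ sub.min(axis=1)
    return out


def ses_mntd(table: RelAbundanceTable, dist: PhyloDistances, null_model: str = "taxa_labels",
             n_perm: int = 1000, group_by: str | None = "host_plant", seed: int | None = None,
             n_swaps: int = 1000) -> pd.DataFrame:
    """Per-sample ses.MNTD with randomizations confined to each group.

    Returns a DataFrame with one row per sample (columns ``sample_id, group,
    obs, null_mean, null_sd, ses, n_perm``).  Samples with < 2 present taxa
    are skipped with a warning; degenerate nulls (sd = 0) yield NaN SES.
    """
    if list(table.asv_ids) != list(dist.ids):
        raise ValueError("table and distances are not aligned (run align_table_tree)")
    if null_model not in ("taxa_labels", "independent_swap"):
        raise ValueError(f"unknown null model {null_model!r}")
    rng = np.random.default_rng(seed)
    W_all = table.proportions.to_numpy()
    D = dist.dist
    meta = table.metadata
    if group_by is None:
        groups = pd.Series("all", index=table.sample_ids)
    else:
        groups = meta[group_by].astype(str)
    rows = []
    sample_ids = np.array(table.sample_ids)
    for g in groups.unique():
        cols = np.flatnonzero((groups == g).to_numpy())
        W = W_all[:, cols]
        obs = np.full(cols.size, np.nan)
        for k in range(cols.size):
            P = np.flatnonzero(W[:, k] > 0)
            if P.size < 2:
                warnings.warn(f"sample {sample_ids[cols[k]]} has <2 taxa; skipped")
                continue
            obs[k] = mntd_weighted(W[:, k], D)
        if null_model == "taxa_labels":
            null = _null_mntd_taxa_labels(W, D, n_perm, rng)
        else:
            null = _null_mntd_independent_swap(W, D, n_perm, n_swaps, rng)
        mu = np.nanmean(null, axis=0)
        sd = np.nanstd(null, axis=0, ddof=1)
        for k in range(cols.size):
            if np.isnan(obs[k]):
                continue
            ses = (obs[k] - mu[k]) / sd[k] if sd[k] > 0 else np.nan
            if sd[k] == 0:
                warnings.warn(f"degenerate null (sd=0) for sample {sample_ids[cols[k]]}")
            rows.append(SesResult(sample_ids[cols[k]], g, obs[k], float(mu[k]), float(sd[k]),
                                  float(ses) if not np.isnan(ses) else np.nan, n_perm))
    return pd.DataFrame([vars(r) for r in rows]).rename(columns={"unit_id": "sample_id"})


def t_test_vs_zero(values, group: str = "") -> GroupTest:
    """Two-sided one-sample t-test of the mean against zero."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValueError("t-test needs at least 3 values")
    if np.allclose(v, v[0]):
        raise ValueError("t-test undefined for constant values")
    res = stats.ttest_1samp(v, 0.0)
    return GroupTest(group=group, mean=float(v.mean()), df=int(v.size - 1),
                     t=float(res.statistic), p=float(res.pvalue), n=int(v.size))


def dispersion_analysis(table: RelAbundanceTable, dist: PhyloDistances, null_model: str = "taxa_labels",
                        n_perm: int = 1000, group_by: str = "host_plant",
                        test_by: str = "fly_species", seed: int | None = None,
                        n_swaps: int = 1000, report_nti: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ses.MNTD per sample (nulls within host-plant groups) plus per-species
    t-tests of SES against zero — the layout of the dispersion summary table.

    ``report_nti`` adds an ``nti`` column (= -ses) for the sign convention
    where positive values indicate clustering.
    """
    ses = ses_mntd(table, dist, null_model=null_model, n_perm=n_perm,
                   group_by=group_by, seed=seed, n_swaps=n_swaps)
    if report_nti:
        ses["nti"] = -ses["ses"]
    labels = table.metadata[test_by].astype(str)
    tests = []
    for sp, sub in ses.join(labels, on="sample_id").groupby(test_by):
        vals = sub["ses"].dropna()
        try:
            tests.append(vars(t_test_vs_zero(vals, group=str(sp))))
        except ValueError as exc:
            warnings.warn(f"t-test skipped for group {sp}: {exc}")
    return ses, pd.DataFrame(tests)
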