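"""Between-sample phylogenetic turnover: abundance-weighted betaMNTD and its
standardized effect size under a tip-shuffle null.

betaMNTD is the between-community analogue of MNTD: each taxon's nearest
relative is sought in the *other* community, so shared taxa contribute zero.
SES below zero means communities are phylogenetically closer than expected
(low turnover despite possible compositional turnover); above zero means
phylogenetically distinct communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .community_io import PhyloDistances, RelAbundanceTable
from .phylo_dispersion import t_test_vs_zero

__all__ = ["PairSes", "bmntd_weighted", "null_tip_shuffle", "ses_bmntd", "turnover_analysis"]


@dataclass
class PairSes:
    sample_k: str
    sample_l: str
    group: str
    obs: float
    null_mean: float
    null_sd: float
    ses: float
    n_perm: int


def bmntd_weighted(f_k, f_l, dist: PhyloDistances | np.ndarray) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two samples.

    ``0.5 * [ sum_{i in k} f_ik * min_{j in l} d_ij
            + sum_{j in l} f_jl * min_{i in k} d_ij ]``
    with weights renormalized over each community's present taxa.
    """
    D = dist.dist if isinstance(dist, PhyloDistances) else np.asarray(dist, dtype=float)
    fk = np.asarray(f_k, dtype=float)
    fl = np.asarray(f_l, dtype=float)
    Pk = np.flatnonzero(fk > 0)
    Pl = np.flatnonzero(fl > 0)
    if Pk.size == 0 or Pl.size == 0:
        raise ValueError("betaMNTD needs at least one present taxon in each community")
    cross = D[np.ix_(Pk, Pl)]
    wk = fk[Pk] / fk[Pk].sum()
    wl = fl[Pl] / fl[Pl].sum()
    return float(0.5 * (wk @ cross.min(axis=1) + wl @ cross.min(axis=0)))


def null_tip_shuffle(dist: PhyloDistances, rng: np.random.Generator) -> PhyloDistances:
    """Shuffle tips across the tree: jointly permute the distance matrix labels."""
    perm = rng.permutation(len(dist.ids))
    return PhyloDistances(list(dist.ids), dist.dist[np.ix_(perm, perm)])


def _pair_bmntd(W: np.ndarray, D: np.ndarray, pairs, present, weights) -> np.ndarray:
    out = np.empty(len(pairs))
    for idx, (k, l) in enumerate(pairs):
        cross = D[np.ix_(present[k], present[l])]
        out[idx] = 0.5 * (weights[k] @ cross.min(axis=1) + weights[l] @ cross.min(axis=0))
    return out


def ses_bmntd(table: RelAbundanceTable, dist: PhyloDistances, n_perm: int = 1000,
              group_by=("fly_species", "host_plant"), seed: int | None = None,
              per_pair: bool = False) -> pd.DataFrame:
    """ses.betaMNTD for every unordered within-group sample pair.

    By default one shared set of ``n_perm`` tip shuffles per group is reused
    across that group's pairs (the marginal null per pair is identical to
    independent shuffles); ``per_pair=True`` draws a fresh set for each pair.
    Groups with fewer than two samples are skipped with a warning.
    """
    if list(table.asv_ids) != list(dist.ids):
        raise ValueError("table and distances are not aligned")
    rng = np.random.default_rng(seed)
    W_all = table.proportions.to_numpy()
    D = dist.dist
    n = D.shape[0]
    meta = table.metadata
    if group_by is None:
        groups = pd.Series("all", index=table.sample_ids)
    else:
        cols = [group_by] if isinstance(group_by, str) else list(group_by)
        groups = meta[cols].astype(str).agg("|".join, axis=1)
    sample_ids = np.array(table.sample_ids)
    rows: list[PairSes] = []
    for g in groups.unique():
        cols_idx = np.flatnonzero((groups == g).to_numpy())
        if cols_idx.size < 2:
            warnings.warn(f"group {g!r} has <2 samples; skipped")
            continue
        W = W_all[:, cols_idx]
        present = [np.flatnonzero(W[:, s] > 0) for s in range(cols_idx.size)]
        weights = [W[present[s], s] / W[present[s], s].sum() for s in range(cols_idx.size)]
        pairs = list(combinations(range(cols_idx.size), 2))
        obs = _pair_bmntd(W, D, pairs, present, weights)
        if per_pair:
            null = np.empty((n_perm, len(pairs)))
            for idx, pair in enumerate(pairs):
                for r in range(n_perm):
                    perm = rng.permutation(n)
                    null[r, idx] = _pair_bmntd(W, D[np.ix_(perm, perm)], [pair], present, weights)[0]
        else:
            null = np.empty((n_perm, len(pairs)))
            for r in range(n_perm):
                perm = rng.permutation(n)
                null[r] = _pair_bmntd(W, D[np.ix_(perm, perm)], pairs, present, weights)
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        for idx, (k, l) in enumerate(pairs):
            ses = (obs[idx] - mu[idx]) / sd[idx] if sd[idx] > 0 else np.nan
            rows.append(PairSes(sample_ids[cols_idx[k]], sample_ids[cols_idx[l]], g,
                                float(obs[idx]), float(mu[idx]), float(sd[idx]), float(ses), n_perm))
    return pd.DataFrame([vars(r) for r in rows])


def turnover_analysis(table: RelAbundanceTable, dist: PhyloDistances, n_perm: int = 1000,
                      group_by=("fly_species", "host_plant"), pool_by: str = "fly_species",
                      seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-group pair SES plus per-species t-tests against zero.

    Pairs are formed within (species x host plant) groups; their SES values
    are then pooled per species for the t-test, matching the per-species rows
    of the turnover summary table.
    """
    pair_ses = ses_bmntd(table, dist, n_perm=n_perm, group_by=group_by, seed=seed)
    if pair_ses.empty:
        return pair_ses, pd.DataFrame()
    species_of = table.metadata[pool_by].astype(str)
    pair_ses[pool_by] = pair_ses["sample_k"].map(species_of)
    tests = []
    for sp, sub in pair_ses.groupby(pool_by):
        vals = sub["ses"].dropna()
        try:
            tests.append(vars(t_test_vs_zero(vals, group=str(sp))))
        except ValueError as exc:
            warnings.warn(f"t-test skipped for group {sp}: {exc}")
    return pair_ses, pd.DataFrame(tests)
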