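"""Abundance-weighted Raup-Crick turnover on Bray-Curtis distances (RC-Bray).

The observed Bray-Curtis dissimilarity of a sample pair is ranked against a
null distribution obtained by probabilistically reassembling each community
from its group's regional pool while holding the sample's richness and read
total fixed: taxa are first drawn without replacement with probability
proportional to their occurrence frequency in the group, then the remaining
reads are distributed across the drawn taxa proportionally to their regional
relative abundance (each drawn taxon is guaranteed its first read).

RC = 2 * (fraction of null draws below obs + 0.5 * fraction equal) - 1, so
values near +1 mean more turnover than expected, near -1 less, and |RC| <=
0.95 is conventionally read as consistent with stochastic assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .community_io import CommunityTable
from .phylo_dispersion import t_test_vs_zero

__all__ = ["RcResult", "bray_curtis", "rc_pair", "rc_bray", "rc_threshold_flags", "rc_analysis",
           "assemble_null_community"]

_TIE_TOL = 1e-12


@dataclass
class RcResult:
    sample_k: str
    sample_l: str
    group: str
    obs_bray: float
    rc: float
    n_reps: int


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``1 - 2*sum(min(x,y)) / (sum x + sum y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    tot = x.sum() + y.sum()
    if tot == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / tot)


def assemble_null_community(richness: int, n_reads: int, occ_freq: np.ndarray,
                            rel_abund: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One null community with fixed richness and read total.

    Membership: ``richness`` taxa sampled without replacement with probability
    proportional to ``occ_freq``.  Reads: one guaranteed read per member, the
    remaining ``n_reads - richness`` multinomial with weights ``rel_abund``.
    """
    n_pool = occ_freq.size
    if richness > np.count_nonzero(occ_freq):
        raise ValueError("sample richness exceeds the regional pool size")
    if n_reads < richness:
        raise ValueError("read total smaller than richness")
    p = occ_freq / occ_freq.sum()
    members = rng.choice(n_pool, size=richness, replace=False, p=p)
    counts = np.zeros(n_pool, dtype=np.int64)
    counts[members] = 1
    a = rel_abund[members]
    if a.sum() == 0:
        a = np.ones(richness)
    counts[members] += rng.multinomial(n_reads - richness, a / a.sum())
    return counts


def rc_pair(x, y, occ_freq: np.ndarray, rel_abund: np.ndarray, n_reps: int,
            rng: np.random.Generator) -> tuple[float, float]:
    """Observed Bray-Curtis and RC for one pair against a given regional pool."""
    x = np.asarray(x)
    y = np.asarray(y)
    obs = bray_curtis(x, y)
    rx = int(np.count_nonzero(x))
    ry = int(np.count_nonzero(y))
    nx = int(x.sum())
    ny = int(y.sum())
    below = ties = 0
    for _ in range(n_reps):
        nk = assemble_null_community(rx, nx, occ_freq, rel_abund, rng)
        nl = assemble_null_community(ry, ny, occ_freq, rel_abund, rng)
        b = bray_curtis(nk, nl)
        if b < obs - _TIE_TOL:
            below += 1
        elif abs(b - obs) <= _TIE_TOL:
            ties += 1
    rc = 2.0 * ((below + 0.5 * ties) / n_reps) - 1.0
    return obs, rc


def rc_bray(table: CommunityTable, group_by=("fly_species", "host_plant"),
            n_reps: int = 999, seed: int | None = None) -> pd.DataFrame:
    """RC-Bray for every unordered within-group sample pair.

    The regional pool (occurrence frequencies and read shares) is defined by
    the group's samples.  For efficiency a single set of ``n_reps`` null
    assemblies is drawn per sample and the r-th draws of the two samples are
    compared, which gives the same pair-level null distribution as drawing
    per pair.
    """
    rng = np.random.default_rng(seed)
    meta = table.metadata
    counts_all = table.counts.to_numpy()
    if group_by is None:
        groups = pd.Series("all", index=table.sample_ids)
    else:
        cols = [group_by] if isinstance(group_by, str) else list(group_by)
        groups = meta[cols].astype(str).agg("|".join, axis=1)
    sample_ids = np.array(table.sample_ids)
    rows: list[RcResult] = []
    for g in groups.unique():
        cols_idx = np.flatnonzero((groups == g).to_numpy())
        if cols_idx.size < 2:
            warnings.warn(f"group {g!r} has <2 samples; skipped")
            continue
        sub = counts_all[:, cols_idx]
        in_group = sub.sum(axis=1) > 0
        pool_counts = sub[in_group]
        occ_freq = (pool_counts > 0).mean(axis=1)
        rel_abund = pool_counts.sum(axis=1) / pool_counts.sum()
        nulls = []
        for s in range(cols_idx.size):
            richness = int(np.count_nonzero(pool_counts[:, s]))
            n_reads = int(pool_counts[:, s].sum())
            draws = np.empty((n_reps, occ_freq.size), dtype=np.int64)
            for r in range(n_reps):
                draws[r] = assemble_null_community(richness, n_reads, occ_freq, rel_abund, rng)
            nulls.append(draws)
        for k, l in combinations(range(cols_idx.size), 2):
            obs = bray_curtis(pool_counts[:, k], pool_counts[:, l])
            a, b = nulls[k], nulls[l]
            mins = np.minimum(a, b).sum(axis=1)
            tots = a.sum(axis=1) + b.sum(axis=1)
            null_bray = 1.0 - 2.0 * mins / tots
            below = np.count_nonzero(null_bray < obs - _TIE_TOL)
            ties = np.count_nonzero(np.abs(null_bray - obs) <= _TIE_TOL)
            rc = 2.0 * ((below + 0.5 * ties) / n_reps) - 1.0
            rows.append(RcResult(sample_ids[cols_idx[k]], sample_ids[cols_idx[l]], g,
                                 obs, float(rc), n_reps))
    return pd.DataFrame([vars(r) for r in rows])


def rc_threshold_flags(results: pd.DataFrame, cutoff: float = 0.95) -> pd.DataFrame:
    """Flag each pair as turnover greater / smaller than expected, or neutral."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    out = results.copy()
    out["flag"] = np.select([out["rc"] > cutoff, out["rc"] < -cutoff],
                            ["greater", "smaller"], default="neutral")
    return out


def rc_analysis(table: CommunityTable, group_by=("fly_species", "host_plant"),
                pool_by: str = "fly_species", n_reps: int = 999,
                seed: int | None = None, cutoff: float = 0.95) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-group RC-Bray plus per-species t-tests of RC against zero."""
    res = rc_bray(table, group_by=group_by, n_reps=n_reps, seed=seed)
    if res.empty:
        return res, pd.DataFrame()
    res = rc_threshold_flags(res, cutoff)
    species_of = table.metadata[pool_by].astype(str)
    res[pool_by] = res["sample_k"].map(species_of)
    tests = []
    for sp, sub in res.groupby(pool_by):
        try:
            tests.append(vars(t_test_vs_zero(sub["rc"], group=str(sp))))
        except ValueError as exc:
            warnings.warn(f"t-test skipped for group {sp}: {exc}")
    return res, pd.DataFrame(tests)
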