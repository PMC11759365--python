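"""Phylogenetic beta diversity and permutational ANOVA.

UniFrac distances are computed branch-by-branch from the tree: for every
branch, the fraction of each sample's abundance descending from it.  The
unweighted variant uses presence only (fraction of unshared branch length);
the generalized variant (Chen et al.) tempers branch weights by
``(p_A + p_B)^alpha``, with ``alpha = 0.5`` the usual "d(0.5)" compromise
between rare- and abundant-lineage sensitivity.

PERMANOVA partitions the total sum of squared distances among the terms of a
crossed two-factor design (A, B, AxB, residual) using the Gower-centred inner
product matrix and projection ("hat") matrices of an effect-coded design;
p-values come from permutations (raw labels, or Freedman-Lane residual
permutation under the reduced model per term).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .community_io import RelAbundanceTable, read_tree

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrixResult",
    "branch_structure",
    "unweighted_unifrac",
    "generalized_unifrac",
    "unifrac_matrix",
    "pcoa",
    "permanova_two_way",
    "pairwise_permanova",
    "bh_fdr",
]


@dataclass
class DistanceMatrixResult:
    metric: str
    ids: list[str]
    dist: np.ndarray
    params: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dist, index=self.ids, columns=self.ids)


def branch_structure(tree, ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and tip-membership masks aligned to ``ids``.

    Returns ``(lengths, membership)`` where ``membership[b, i]`` is True when
    tip ``ids[i]`` descends from branch ``b``.  The tree's tip set must cover
    ``ids``; extra tips are allowed (their branches simply carry no mass).
    """
    tree = read_tree(tree)
    pos = {a: i for i, a in enumerate(ids)}
    tip_labels = {t.taxon.label for t in tree.leaf_node_iter()}
    missing = set(ids) - tip_labels
    if missing:
        raise ValueError(f"tree is missing tips for: {sorted(missing)[:5]}")
    lengths, masks = [], []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask = np.zeros(len(ids), dtype=bool)
            if node.taxon.label in pos:
                mask[pos[node.taxon.label]] = True
        else:
            mask = np.zeros(len(ids), dtype=bool)
            for ch in node.child_nodes():
                mask |= below[id(ch)]
        below[id(node)] = mask
        if node is tree.seed_node:
            continue
        bl = node.edge.length
        if bl is None:
            raise ValueError("tree has edges with missing branch lengths")
        lengths.append(float(bl))
        masks.append(mask)
    return np.asarray(lengths), np.vstack(masks)


def unweighted_unifrac(pres_a, pres_b, lengths: np.ndarray, membership: np.ndarray) -> float:
    """Fraction of branch length unique to either sample's spanned set."""
    a = np.asarray(pres_a, dtype=bool)
    b = np.asarray(pres_b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("UniFrac undefined for an empty sample")
    span_a = membership @ a > 0
    span_b = membership @ b > 0
    union = span_a | span_b
    denom = lengths[union].sum()
    if denom == 0:
        return 0.0
    return float(lengths[span_a ^ span_b].sum() / denom)


def generalized_unifrac(prop_a, prop_b, lengths: np.ndarray, membership: np.ndarray,
                        alpha: float = 0.5) -> float:
    """Generalized UniFrac with abundance-tempering exponent ``alpha``."""
    pa = membership @ np.asarray(prop_a, dtype=float)
    pb = membership @ np.asarray(prop_b, dtype=float)
    tot = pa + pb
    keep = tot > 0
    if not keep.any():
        raise ValueError("UniFrac undefined for two empty samples")
    w = lengths[keep] * np.power(tot[keep], alpha)
    num = float((w * np.abs(pa[keep] - pb[keep]) / tot[keep]).sum())
    den = float(w.sum())
    return num / den if den > 0 else 0.0


def unifrac_matrix(table: RelAbundanceTable, tree, metric: str = "generalized",
                   alpha: float = 0.5) -> DistanceMatrixResult:
    """All-pairs UniFrac distance matrix over the table's samples."""
    lengths, membership = branch_structure(tree, table.asv_ids)
    P = table.proportions.to_numpy()
    n = P.shape[1]
    D = np.zeros((n, n))
    if metric == "unweighted":
        pres = P > 0
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = unweighted_unifrac(pres[:, i], pres[:, j], lengths, membership)
    elif metric == "generalized":
        # precompute per-branch proportions once
        BP = membership.astype(float) @ P
        for i in range(n):
            for j in range(i + 1, n):
                tot = BP[:, i] + BP[:, j]
                keep = tot > 0
                w = lengths[keep] * np.power(tot[keep], alpha)
                den = w.sum()
                D[i, j] = D[j, i] = (w * np.abs(BP[keep, i] - BP[keep, j]) / tot[keep]).sum() / den if den > 0 else 0.0
    else:
        raise ValueError(f"unknown UniFrac metric {metric!r}")
    return DistanceMatrixResult(metric, list(table.sample_ids), D,
                                {"alpha": alpha} if metric == "generalized" else {})


def _gower(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def pcoa(dist: DistanceMatrixResult | np.ndarray, n_axes: int = 2):
    """Principal coordinates: Gower-centred eigendecomposition.

    Returns ``(coordinates DataFrame, pct_variation per axis)``; percent
    variation is each positive eigenvalue's share of the positive eigenvalue
    mass.  Negative eigenvalues are logged, not corrected.
    """
    D = dist.dist if isinstance(dist, DistanceMatrixResult) else np.asarray(dist, dtype=float)
    ids = dist.ids if isinstance(dist, DistanceMatrixResult) else [str(i) for i in range(D.shape[0])]
    if D.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    G = _gower(D)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_neg = int((evals < -1e-10).sum())
    if n_neg:
        logger.info("pcoa: %d negative eigenvalues (min %.3g); reported, not corrected",
                    n_neg, float(evals.min()))
    pos = evals > 1e-12
    pct = np.zeros(evals.size)
    if pos.any():
        pct[pos] = 100.0 * evals[pos] / evals[pos].sum()
    n_axes = min(n_axes, int(pos.sum())) or 1
    coords = evecs[:, :n_axes] * np.sqrt(np.clip(evals[:n_axes], 0, None))
    frame = pd.DataFrame(coords, index=ids, columns=[f"PCo{i + 1}" for i in range(n_axes)])
    return frame, pct[:n_axes]


def _effect_code(labels: pd.Series) -> np.ndarray:
    """Sum-to-zero (deviation) coding; (n, levels-1)."""
    levels = sorted(labels.unique())
    n = len(labels)
    X = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        X[:, j] = (labels == lev).to_numpy().astype(float)
    X[(labels == levels[-1]).to_numpy(), :] = -1.0
    return X


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova_two_way(dist: DistanceMatrixResult, metadata: pd.DataFrame,
                      factor_a: str, factor_b: str, n_perm: int = 9999,
                      seed: int | None = None, scheme: str = "residual") -> pd.DataFrame:
    """Crossed two-factor PERMANOVA with interaction and variance components.

    Partial sums of squares per term come from comparing the full-model
    projection with the model lacking that term (effect coding); p-values
    from ``n_perm`` permutations (``scheme='raw'`` permutes sample labels,
    ``'residual'`` applies Freedman-Lane permutation of reduced-model
    residuals per term).  Components of variation are method-of-moments
    estimates from expected mean squares, reported as percent of their sum.
    """
    if scheme not in ("raw", "residual"):
        raise ValueError("scheme must be 'raw' or 'residual'")
    rng = np.random.default_rng(seed)
    ids = dist.ids
    meta = metadata.loc[ids]
    la = meta[factor_a].astype(str)
    lb = meta[factor_b].astype(str)
    cells = la + "|" + lb
    cell_counts = cells.value_counts()
    if (cell_counts < 2).any():
        raise ValueError(f"cells with <2 samples: {list(cell_counts.index[cell_counts < 2])}")
    n = len(ids)
    a_lev, b_lev = la.nunique(), lb.nunique()
    Xa = _effect_code(la)
    Xb = _effect_code(lb)
    Xab = np.concatenate([Xa[:, i:i + 1] * Xb for i in range(Xa.shape[1])], axis=1)
    ones = np.ones((n, 1))
    X_full = np.concatenate([ones, Xa, Xb, Xab], axis=1)
    H_full = _hat(X_full)
    G = _gower(dist.dist)
    terms = {
        factor_a: (np.concatenate([ones, Xb, Xab], axis=1), a_lev - 1, n / a_lev),
        factor_b: (np.concatenate([ones, Xa, Xab], axis=1), b_lev - 1, n / b_lev),
        f"{factor_a} x {factor_b}": (np.concatenate([ones, Xa, Xb], axis=1),
                                     (a_lev - 1) * (b_lev - 1), n / (a_lev * b_lev)),
    }
    df_res = n - 1 - sum(df for _, df, _ in terms.values())
    I = np.eye(n)
    R_full = I - H_full
    ss_res = float(np.sum(R_full * G))
    ss_total = float(np.trace(G))
    ms_res = ss_res / df_res

    rows = []
    comps = {}
    for name, (X_red, df_t, k_t) in terms.items():
        H_red = _hat(X_red)
        H_diff = H_full - H_red
        ss_t = float(np.sum(H_diff * G))
        F_obs = (ss_t / df_t) / ms_res
        if scheme == "raw":
            G_p = G
            H_d, R_f = H_diff, R_full
        else:
            R_red = I - H_red
            G_p = R_red @ G @ R_red
            H_d, R_f = H_diff, R_full
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G_p[np.ix_(perm, perm)]
            ss_tp = np.sum(H_d * Gp)
            ss_rp = np.sum(R_f * Gp)
            Fp = (ss_tp / df_t) / (ss_rp / df_res) if ss_rp > 0 else np.inf
            if Fp >= F_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        comp = max((ss_t / df_t - ms_res) / k_t, 0.0)
        comps[name] = comp
        rows.append({"term": name, "df": df_t, "SS": ss_t, "pseudo_F": F_obs, "p": p})
    comps["Residual"] = ms_res
    total_comp = sum(comps.values())
    for row in rows:
        row["pct_variation"] = 100.0 * comps[row["term"]] / total_comp if total_comp > 0 else np.nan
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res, "pseudo_F": np.nan,
                 "p": np.nan, "pct_variation": 100.0 * comps["Residual"] / total_comp if total_comp > 0 else np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "pseudo_F": np.nan,
                 "p": np.nan, "pct_variation": np.nan})
    return pd.DataFrame(rows)


def permanova_one_way(dist: np.ndarray, labels: pd.Series, n_perm: int = 999,
                      seed: int | None = None) -> tuple[float, float]:
    """Classic one-factor PERMANOVA (Anderson's pseudo-F, raw permutation)."""
    rng = np.random.default_rng(seed)
    labels = labels.astype(str)
    n = dist.shape[0]
    X = np.concatenate([np.ones((n, 1)), _effect_code(labels)], axis=1)
    H = _hat(X)
    I = np.eye(n)
    G = _gower(dist)
    df_t = labels.nunique() - 1
    df_r = n - labels.nunique()
    H_c = H - np.ones((n, n)) / n
    ss_t = float(np.sum(H_c * G))
    ss_r = float(np.sum((I - H) * G))
    F_obs = (ss_t / df_t) / (ss_r / df_r)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_tp = np.sum(H_c * Gp)
        ss_rp = np.sum((I - H) * Gp)
        if (ss_tp / df_t) / (ss_rp / df_r) >= F_obs - 1e-12:
            count += 1
    return F_obs, (count + 1) / (n_perm + 1)


def pairwise_permanova(dist: DistanceMatrixResult, labels: pd.Series, n_perm: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """All group pairs, one-factor permutation tests, BH-FDR adjusted."""
    rng = np.random.default_rng(seed)
    labels = labels.loc[dist.ids].astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            mask = labels.isin([groups[i], groups[j]]).to_numpy()
            if (labels[mask] == groups[i]).sum() < 2 or (labels[mask] == groups[j]).sum() < 2:
                raise ValueError(f"group pair ({groups[i]}, {groups[j]}) has a group of size < 2")
            sub = dist.dist[np.ix_(mask, mask)]
            F, p = permanova_one_way(sub, labels[mask], n_perm=n_perm,
                                     seed=int(rng.integers(2**31 - 1)))
            rows.append({"group_1": groups[i], "group_2": groups[j],
                         "t": float(np.sqrt(F)), "pseudo_F": F, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p"].to_numpy())
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
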