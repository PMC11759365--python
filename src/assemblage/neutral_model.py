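"""Sloan neutral community model: fit, prevalence partitioning, comparisons.

The model predicts a taxon's prevalence across communities (fraction of
samples in which it is detected) from its mean relative abundance ``p``: in a
local community of ``N`` individuals receiving immigrants at rate ``m`` from
a regional pool, the stationary local relative abundance is Beta(N*m*p,
N*m*(1-p)) distributed, so the probability of exceeding the detection limit
``d = 1/N`` is ``1 - BetaCDF(d; N*m*p, N*m*(1-p))``.  The single free
parameter ``m`` is estimated by least squares on observed prevalences
(Burns-style fitting); goodness of fit is summarized by RMSE and compared
with zero-parameter binomial and Poisson sampling models.

Taxa whose observed prevalence lies above the Wilson confidence band around
the neutral prediction are candidates for positive host selection ("above");
those below it for negative selection or dispersal limitation ("below").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .community_io import CommunityTable

__all__ = [
    "NeutralFit",
    "predict_frequency",
    "binomial_frequency",
    "poisson_frequency",
    "wilson_ci",
    "fit_sloan",
    "partition",
    "shared_signatures",
]


@dataclass
class NeutralFit:
    group: str
    m: float
    N: float
    d: float
    rmse: float
    rmse_binomial: float
    rmse_poisson: float
    n_asv: int
    n_samples: int
    records: pd.DataFrame = field(repr=False)


def predict_frequency(p, N: float, m: float, d: float):
    """Neutral prediction of prevalence for mean relative abundance ``p``.

    ``1 - BetaCDF(d; N*m*p, N*m*(1-p))``; by convention 0 at p=0 and 1 at p=1.
    Vectorized over ``p``.
    """
    p = np.asarray(p, dtype=float)
    if N <= 0 or m <= 0 or not 0 < d < 1:
        raise ValueError("require N > 0, m > 0, 0 < d < 1")
    out = np.empty_like(p)
    inner = (p > 0) & (p < 1)
    out[p <= 0] = 0.0
    out[p >= 1] = 1.0
    pi = p[inner]
    out[inner] = stats.beta.sf(d, N * m * pi, N * m * (1.0 - pi))
    return out if out.ndim else float(out)


def binomial_frequency(p, N: float):
    """Detection probability under binomial sampling: ``1 - (1-p)^N``."""
    p = np.asarray(p, dtype=float)
    out = 1.0 - np.power(np.clip(1.0 - p, 0.0, 1.0), N)
    return out if out.ndim else float(out)


def poisson_frequency(p, N: float):
    """Detection probability under Poisson sampling: ``1 - exp(-N*p)``."""
    p = np.asarray(p, dtype=float)
    out = 1.0 - np.exp(-N * p)
    return out if out.ndim else float(out)


def wilson_ci(freq_pred, n_samples: int, level: float = 0.95):
    """Wilson score interval around a predicted prevalence with ``n_samples``
    Bernoulli observations; always within [0, 1]."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    freq_pred = np.asarray(freq_pred, dtype=float)
    count = freq_pred * n_samples
    lwr, upr = proportion_confint(count, n_samples, alpha=1 - level, method="wilson")
    return np.clip(lwr, 0, 1), np.clip(upr, 0, 1)


def _sse(m: float, p: np.ndarray, freq_obs: np.ndarray, N: float, d: float) -> float:
    resid = freq_obs - predict_frequency(p, N, m, d)
    return float(resid @ resid)


def fit_sloan(table: CommunityTable, sample_ids=None, group: str = "all",
              community_size: str = "mean", ci_level: float = 0.95) -> NeutralFit:
    """Fit the neutral model to one group of samples.

    ``N`` is the mean (or median) of the group's per-sample read totals, the
    detection limit ``d = 1/N``, ``p_i`` the mean of per-sample proportions
    and ``freq_obs,i`` the fraction of samples with a nonzero count.  ``m`` is
    estimated by bounded least squares with three log-spaced starts.  Taxa
    absent from every group sample are excluded (logged).
    """
    if sample_ids is not None:
        table = table.subset_samples(sample_ids)
    counts = table.counts.to_numpy().astype(float)
    n_samples = counts.shape[1]
    if n_samples < 10:
        warnings.warn(f"group {group!r} has only {n_samples} samples; fit may be unstable")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-read sample in group")
    N = float(np.mean(totals) if community_size == "mean" else np.median(totals))
    d = 1.0 / N
    props = counts / totals
    present = counts.sum(axis=1) > 0
    n_dropped = int((~present).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} taxa absent from every sample of group {group!r}")
    ids = np.array(table.asv_ids)[present]
    p = props[present].mean(axis=1)
    freq_obs = (counts[present] > 0).mean(axis=1)
    # canonical taxon order: the fitted m (and hence every class) is invariant
    # to the input row ordering despite float summation
    order = np.argsort(ids)
    ids, p, freq_obs = ids[order], p[order], freq_obs[order]
    if p.size < 2:
        raise ValueError("need at least 2 taxa with nonzero prevalence")
    if np.all(freq_obs == 1.0) or np.all(freq_obs == freq_obs[0]):
        raise ValueError("degenerate prevalence pattern: no variation to fit")

    # log-spaced scan guards against flat regions at tiny m, then a bounded
    # refinement inside the best bracket
    grid = np.logspace(-8, 0, 33)
    sse_grid = np.array([_sse(mm, p, freq_obs, N, d) for mm in grid])
    k = int(np.argmin(sse_grid))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(_sse, bounds=(lo, hi), method="bounded",
                                   args=(p, freq_obs, N, d), options={"xatol": 1e-12})
    m_hat = float(res.x)
    if _sse(grid[k], p, freq_obs, N, d) < _sse(m_hat, p, freq_obs, N, d):
        m_hat = float(grid[k])
    freq_pred = predict_frequency(p, N, m_hat, d)
    rmse = float(np.sqrt(np.mean((freq_obs - freq_pred) ** 2)))
    bino = binomial_frequency(p, N)
    pois = poisson_frequency(p, N)
    rmse_b = float(np.sqrt(np.mean((freq_obs - bino) ** 2)))
    rmse_p = float(np.sqrt(np.mean((freq_obs - pois) ** 2)))
    lwr, upr = wilson_ci(freq_pred, n_samples, ci_level)
    blwr, bupr = wilson_ci(bino, n_samples, ci_level)
    cls = np.select([freq_obs > upr, freq_obs < lwr], ["above", "below"], default="neutral")
    records = pd.DataFrame({
        "asv_id": ids, "p": p, "freq": freq_obs, "freq.pred": freq_pred,
        "pred.lwr": lwr, "pred.upr": upr,
        "bino.pred": bino, "bino.lwr": blwr, "bino.upr": bupr,
        "pois.pred": pois, "type": cls,
    }).set_index("asv_id")
    return NeutralFit(group=group, m=m_hat, N=N, d=d, rmse=rmse, rmse_binomial=rmse_b,
                      rmse_poisson=rmse_p, n_asv=int(p.size), n_samples=n_samples,
                      records=records)


def partition(fit: NeutralFit, table: CommunityTable | None = None, sample_ids=None) -> pd.DataFrame:
    """Unweighted (taxon-count) and read-weighted class fractions.

    Weighted fractions attribute each class the share of the group's reads
    held by its member taxa; both schemes sum to one.
    """
    rec = fit.records
    classes = ["neutral", "above", "below"]
    unweighted = {c: float((rec["type"] == c).mean()) for c in classes}
    if table is not None:
        if sample_ids is not None:
            table = table.subset_samples(sample_ids)
        reads = table.counts.reindex(rec.index).fillna(0).sum(axis=1)
        grand = float(reads.sum())
        weighted = {c: float(reads[rec["type"] == c].sum() / grand) for c in classes}
    else:
        weighted = {c: np.nan for c in classes}
    return pd.DataFrame({"class": classes,
                         "unweighted": [unweighted[c] for c in classes],
                         "weighted": [weighted[c] for c in classes]})


def shared_signatures(fits: list[NeutralFit], cls: str = "above") -> set[str]:
    """ASVs carrying the same selection signature in every fitted group."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to intersect")
    if cls not in ("above", "below"):
        raise ValueError("cls must be 'above' or 'below'")
    sets = [set(f.records.index[f.records["type"] == cls]) for f in fits]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
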