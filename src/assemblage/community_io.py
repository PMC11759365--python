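"""Reading, validation and basic transforms of community data.

The central object is the :class:`CommunityTable`: an ASV-by-sample matrix of
integer read counts together with aligned per-sample metadata (fly species,
host plant, site, altitude, ...).  Downstream stages consume either the raw
counts, per-sample proportions (:class:`RelAbundanceTable`) or cophenetic
distances between ASVs derived from a rooted phylogeny
(:class:`PhyloDistances`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "RelAbundanceTable",
    "PhyloDistances",
    "read_community_table",
    "write_community_table",
    "abundance_filter",
    "normalize_proportions",
    "read_tree",
    "cophenetic_matrix",
    "align_table_tree",
]


def _check_ids(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")
    for i in ids:
        if not isinstance(i, str) or i != i.strip() or i == "" or any(c.isspace() for c in i):
            raise ValueError(f"invalid {what} id {i!r}: empty or contains whitespace")


@dataclass
class CommunityTable:
    """ASV x sample read counts plus aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame with ASV ids as index and sample ids as columns; integer,
        non-negative entries.
    metadata
        DataFrame indexed by sample id.  Must cover every sample in
        ``counts``; extra metadata rows are tolerated and trimmed.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_ids(self.counts.index, "ASV")
        _check_ids(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.asarray(vals, dtype=float) == np.floor(np.asarray(vals, dtype=float))):
                raise ValueError("non-integer count encountered")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative count encountered")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata mismatch: samples without metadata: {sorted(missing)[:5]}")
        # trim + order metadata to the count columns
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "CommunityTable":
        """Restrict to the given samples (order preserved)."""
        return CommunityTable(self.counts[list(sample_ids)].copy(), self.metadata.loc[list(sample_ids)].copy())


@dataclass
class RelAbundanceTable:
    """Per-sample proportions; same shape, ids and zero pattern as the source counts."""

    proportions: pd.DataFrame
    metadata: pd.DataFrame = field(repr=False, default=None)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class PhyloDistances:
    """Symmetric cophenetic (summed branch length) distances over ASV ids."""

    ids: list[str]
    dist: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        n = len(self.ids)
        if self.dist.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.dist) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.dist < 0).any():
            raise ValueError("negative phylogenetic distance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dist, index=self.ids, columns=self.ids)

    def subset(self, ids) -> "PhyloDistances":
        idx = [self.ids.index(i) for i in ids]
        return PhyloDistances(list(ids), self.dist[np.ix_(idx, idx)])


def read_community_table(counts_path, metadata_path) -> CommunityTable:
    """Read a TSV count table (rows = ASVs, first column ``asv_id``) and a
    sample metadata TSV keyed by ``sample_id``."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return CommunityTable(counts, meta)


def write_community_table(table: CommunityTable, counts_path, metadata_path) -> None:
    c = table.counts.copy()
    c.index.name = "asv_id"
    c.to_csv(counts_path, sep="\t")
    m = table.metadata.copy()
    m.index.name = "sample_id"
    m.to_csv(metadata_path, sep="\t")


def abundance_filter(table: CommunityTable, threshold: float = 0.001, scope: str = "overall") -> CommunityTable:
    """Remove rare ASVs below a relative-abundance threshold.

    ``scope="overall"`` (default): an ASV is kept iff its study-wide share of
    reads (ASV total / grand total) is >= ``threshold`` (boundary inclusive).
    ``scope="per-sample"``: kept iff its within-sample proportion reaches the
    threshold in at least one sample.  Samples whose column sum drops to zero
    are removed with a warning.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    counts = table.counts
    if scope == "overall":
        grand = counts.to_numpy().sum()
        keep = counts.sum(axis=1) / grand >= threshold
    elif scope == "per-sample":
        props = counts / counts.sum(axis=0)
        keep = (props >= threshold).any(axis=1)
    else:
        raise ValueError(f"unknown filter scope {scope!r}")
    if threshold == 0:
        keep[:] = True
    filtered = counts.loc[keep]
    if filtered.shape[0] == 0:
        raise ValueError("abundance filter removed every ASV")
    nonempty = filtered.sum(axis=0) > 0
    if not nonempty.all():
        dropped = list(filtered.columns[~nonempty])
        warnings.warn(f"dropping {len(dropped)} sample(s) emptied by the abundance filter: {dropped[:5]}")
        filtered = filtered.loc[:, nonempty]
    logger.info("abundance_filter: kept %d/%d ASVs at threshold %g (%s)",
                filtered.shape[0], counts.shape[0], threshold, scope)
    return CommunityTable(filtered.copy(), table.metadata.loc[list(filtered.columns)].copy())


def normalize_proportions(table: CommunityTable) -> RelAbundanceTable:
    """Divide each sample column by its read total."""
    sums = table.counts.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"zero-sum sample column(s): {bad[:5]}")
    props = table.counts / sums
    return RelAbundanceTable(props, table.metadata)


def read_tree(source) -> dendropy.Tree:
    """Load a newick tree from a path or string."""
    if isinstance(source, dendropy.Tree):
        return source
    src = str(source)
    looks_like_newick = "(" in src or ";" in src
    try:
        if not looks_like_newick and Path(src).exists():
            return dendropy.Tree.get(path=src, schema="newick")
        if looks_like_newick:
            return dendropy.Tree.get(data=src, schema="newick")
    except Exception as exc:
        if "uplicate" in str(exc):
            raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
        raise
    raise FileNotFoundError(f"tree file not found: {src}")


def cophenetic_matrix(tree) -> PhyloDistances:
    """Path-length (cophenetic) distances between all tip pairs of a tree.

    Every non-root edge must carry a branch length; tip labels must be unique.
    """
    tree = read_tree(tree)
    tips = tree.leaf_nodes()
    labels = [t.taxon.label if t.taxon is not None else None for t in tips]
    if any(l is None for l in labels):
        raise ValueError("tree has unlabeled tips")
    _check_ids(labels, "tip")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges with missing branch lengths")
        if edge.length < 0:
            raise ValueError("negative branch length")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    dist = np.zeros((n, n))
    taxa = {t.taxon.label: t.taxon for t in tips}
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            dist[i, j] = dist[j, i] = d
    return PhyloDistances(labels, dist)


def align_table_tree(table: CommunityTable, dist: PhyloDistances) -> tuple[CommunityTable, PhyloDistances]:
    """Restrict both objects to their common ASV set with a consistent ordering."""
    common = [a for a in table.asv_ids if a in set(dist.ids)]
    if not common:
        raise ValueError("no ASV ids shared between table and tree")
    dropped_tab = len(table.asv_ids) - len(common)
    dropped_tree = len(dist.ids) - len(common)
    if dropped_tab or dropped_tree:
        lost = int(table.counts.loc[[a for a in table.asv_ids if a not in set(common)]].to_numpy().sum()) if dropped_tab else 0
        logger.info("align_table_tree: dropped %d table ASVs (%d reads) and %d tree tips",
                    dropped_tab, lost, dropped_tree)
    new_tab = CommunityTable(table.counts.loc[common].copy(), table.metadata.copy())
    return new_tab, dist.subset(common)
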