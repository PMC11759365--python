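"""Synthetic microbial communities with known assembly process.

Two generative regimes are provided:

* **Neutral, dispersal-limited** assembly: each sample's latent relative
  abundance of taxon *i* is drawn from ``Beta(N*m*p_i, N*m*(1-p_i))`` around
  the regional pool abundance ``p_i`` — the marginal distribution of the Sloan
  neutral community model with migration rate ``m`` and community size ``N``
  — and reads are then sampled multinomially.  Because this is exactly the
  model the neutral-model stage fits, the generating ``m`` is recoverable and
  parameter-recovery tests are meaningful.
* **Phylogenetically conserved habitat filtering**: a trait evolves on the
  tree by Brownian motion; each habitat has an optimum, and taxa are weighted
  by a Gaussian filter around it.  Small filter widths produce phylogenetic
  clustering (negative ses.MNTD), the deterministic signature the null-model
  stage is designed to detect.

Default scenario parameters mirror the structure of the fruit-fly larval
microbiome study this pipeline targets: ~2085 ASVs after filtering, three fly
species with 48/26/48 larvae, three host plants crossed unbalanced with the
species, and ~1e5 reads per sample.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .community_io import CommunityTable, PhyloDistances, cophenetic_matrix

__all__ = [
    "SimScenario",
    "SimOutput",
    "simulate_tree",
    "simulate_pool",
    "simulate_neutral_sloan",
    "simulate_filtered",
    "brownian_trait",
    "simulate_scenario",
]

# Study-structure constants: species group sizes and the unbalanced
# species x host-plant design (one empty cell: the third species is never found
# on the first host plant).
DEFAULT_SPECIES_SIZES = {"sp_A": 48, "sp_B": 26, "sp_C": 48}
DEFAULT_PLANTS = ("cucumber", "watermelon", "squash")


@dataclass
class SimScenario:
    """Parameters of one simulated study.

    ``filter_strength`` is the Gaussian habitat-filter width sigma; 0 switches
    the filter off, reducing the generator to neutral sampling.
    """

    n_taxa: int = 2085
    n_samples: int = 122               # 48 + 26 + 48 larvae
    reads_per_sample: int = 102_187
    m_true: float = 0.0005             # within the fitted 2e-4..7e-4 range
    pool_shape: float = 0.999
    filter_strength: float = 0.0
    bm_sigma: float = 1.0
    n_habitats: int = 3
    seed: int = 0
    species_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_SIZES))

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0 < self.m_true <= 1:
            raise ValueError("m_true must be in (0, 1]")
        if not 0 < self.pool_shape < 1:
            raise ValueError("pool_shape must be in (0, 1)")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")
        if self.reads_per_sample < 10:
            raise ValueError("reads_per_sample must be >= 10")


@dataclass
class SimOutput:
    """A generated study: counts+metadata, the tree, the pool, and ground truth."""

    table: CommunityTable
    tree: str                     # newick
    pool: pd.Series               # per-ASV regional relative abundance
    truth: dict                   # scenario echo + per-ASV traits etc.


def _asv_labels(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"ASV{i + 1:0{width}d}" for i in range(n)]


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-component child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def simulate_tree(n_taxa: int, seed: int) -> str:
    """Yule (pure-birth) tree with ``n_taxa`` tips labelled ASV0001..., as newick.

    Branch lengths are strictly positive; the same seed yields a
    byte-identical newick string.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2 to build a tree")
    rng = random.Random(seed)
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace(_asv_labels(n_taxa))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    # guard against zero-length edges from simultaneous events
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = 1e-8
    # no root edge: keeps every branch a genuine bipartition of the tip set
    tree.seed_node.edge.length = None
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_pool(n_taxa: int, pool_shape: float, seed: int) -> np.ndarray:
    """Long-tailed regional pool: log-series draws, normalized to sum one."""
    if not 0 < pool_shape < 1:
        raise ValueError("pool_shape must be in (0, 1)")
    rng = np.random.default_rng(seed)
    draws = rng.logseries(pool_shape, size=n_taxa).astype(float)
    return draws / draws.sum()


def _table_from_counts(counts: np.ndarray, asv_ids, sample_ids, metadata: pd.DataFrame | None = None) -> CommunityTable:
    frame = pd.DataFrame(counts.astype(np.int64), index=list(asv_ids), columns=list(sample_ids))
    if metadata is None:
        metadata = pd.DataFrame(index=list(sample_ids))
    return CommunityTable(frame, metadata)


def simulate_neutral_sloan(pool: np.ndarray, N: int, m: float, n_samples: int, seed: int,
                           asv_ids=None, sample_ids=None) -> SimOutput:
    """Neutral dispersal-limited samples from a regional pool.

    For each sample, latent relative abundances are Beta(N*m*p_i,
    N*m*(1-p_i)) draws renormalized across taxa, then ``N`` reads are drawn
    multinomially.  Column sums are exactly ``N``.
    """
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if N < 10:
        raise ValueError("N must be >= 10")
    pool = np.asarray(pool, dtype=float)
    pool = pool / pool.sum()
    rng = np.random.default_rng(seed)
    n_taxa = pool.size
    a = N * m * pool
    b = N * m * (1.0 - pool)
    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        latent = rng.beta(a, b)
        tot = latent.sum()
        if tot == 0:  # pathological tiny-m draw; fall back to the pool
            latent = pool.copy()
            tot = 1.0
        counts[:, s] = rng.multinomial(N, latent / tot)
    asv_ids = asv_ids if asv_ids is not None else _asv_labels(n_taxa)
    sample_ids = sample_ids if sample_ids is not None else [f"S{s + 1:03d}" for s in range(n_samples)]
    table = _table_from_counts(counts, asv_ids, sample_ids)
    truth = {"m": m, "N": N, "model": "neutral_sloan", "seed": seed}
    return SimOutput(table=table, tree="", pool=pd.Series(pool, index=asv_ids), truth=truth)


def brownian_trait(tree, bm_sigma: float, seed: int) -> pd.Series:
    """Evolve a single continuous trait along the tree by Brownian motion."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    vals: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        parent = vals[id(node.parent_node)]
        vals[id(node)] = parent + rng.normal(0.0, bm_sigma * np.sqrt(max(bl, 0.0)))
    out = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = vals[id(leaf)]
    return pd.Series(out)


def simulate_filtered(tree, pool: np.ndarray, N: int, n_samples: int, n_habitats: int,
                      bm_sigma: float, filter_strength: float, seed: int,
                      sample_ids=None, habitat_of_sample=None) -> SimOutput:
    """Samples assembled under a phylogenetically conserved habitat filter.

    A Brownian trait is evolved on the tree; habitat optima are placed at
    evenly spaced quantiles of the tip trait distribution; sampling weights
    are ``p_i * exp(-(trait_i - theta_h)^2 / (2 sigma^2))`` and reads are
    multinomial.  ``filter_strength == 0`` turns the filter off and reduces to
    plain multinomial sampling from the pool.
    """
    if filter_strength < 0:
        raise ValueError("filter_strength must be >= 0")
    if isinstance(tree, str):
        tree_obj = dendropy.Tree.get(data=tree, schema="newick")
        newick = tree
    else:
        tree_obj = tree
        newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    seeds = child_seeds(seed, 2)
    trait = brownian_trait(tree_obj, bm_sigma, seeds[0])
    asv_ids = list(trait.index)
    pool = np.asarray(pool, dtype=float)
    pool = pool / pool.sum()
    rng = np.random.default_rng(seeds[1])
    if habitat_of_sample is None:
        habitat_of_sample = np.arange(n_samples) % n_habitats
    habitat_of_sample = np.asarray(habitat_of_sample)
    qs = np.linspace(0.15, 0.85, n_habitats)
    optima = np.quantile(trait.to_numpy(), qs)
    t = trait.to_numpy()
    counts = np.empty((len(asv_ids), n_samples), dtype=np.int64)
    for s in range(n_samples):
        if filter_strength == 0:
            w = pool
        else:
            theta = optima[habitat_of_sample[s]]
            w = pool * np.exp(-((t - theta) ** 2) / (2.0 * filter_strength**2))
            if w.sum() == 0:
                w = pool
        counts[:, s] = rng.multinomial(N, w / w.sum())
    sample_ids = sample_ids if sample_ids is not None else [f"S{s + 1:03d}" for s in range(n_samples)]
    meta = pd.DataFrame({"habitat": [f"H{h + 1}" for h in habitat_of_sample]}, index=sample_ids)
    table = _table_from_counts(counts, asv_ids, sample_ids, meta)
    truth = {
        "model": "filtered",
        "filter_strength": filter_strength,
        "bm_sigma": bm_sigma,
        "optima": optima.tolist(),
        "trait": trait.to_dict(),
        "seed": seed,
    }
    return SimOutput(table=table, tree=newick, pool=pd.Series(pool, index=asv_ids), truth=truth)


def simulate_scenario(scenario: SimScenario) -> SimOutput:
    """Generate a full study: tree, pool, and a crossed (unbalanced) design.

    Fly-species group sizes follow ``scenario.species_sizes``; host plants are
    assigned within species with one empty cell (the third species never
    occurs on the first plant), mirroring the unbalanced field design.  Under
    habitat filtering the host plant is the habitat.
    """
    sc = scenario
    seeds = child_seeds(sc.seed, 4)
    newick = simulate_tree(sc.n_taxa, seeds[0])
    pool = simulate_pool(sc.n_taxa, sc.pool_shape, seeds[1])
    asv_ids = _asv_labels(sc.n_taxa)

    species, plants = [], []
    names = list(sc.species_sizes)
    for k, (sp, n_sp) in enumerate(sc.species_sizes.items()):
        allowed = list(DEFAULT_PLANTS[1:]) if sp == names[-1] else list(DEFAULT_PLANTS)
        for j in range(n_sp):
            species.append(sp)
            plants.append(allowed[j % len(allowed)])
    n_samples = len(species)
    sample_ids = [f"S{s + 1:03d}" for s in range(n_samples)]
    habitat_idx = np.array([DEFAULT_PLANTS.index(p) for p in plants])

    if sc.filter_strength > 0:
        out = simulate_filtered(newick, pool, sc.reads_per_sample, n_samples, sc.n_habitats,
                                sc.bm_sigma, sc.filter_strength, seeds[2],
                                sample_ids=sample_ids, habitat_of_sample=habitat_idx)
        counts = out.table.counts
        truth = out.truth
    else:
        out = simulate_neutral_sloan(pool, sc.reads_per_sample, sc.m_true, n_samples,
                                     seeds[2], asv_ids=asv_ids, sample_ids=sample_ids)
        counts = out.table.counts
        truth = out.truth

    rng = np.random.default_rng(seeds[3])
    meta = pd.DataFrame(
        {
            "fly_species": species,
            "host_plant": plants,
            "site": rng.choice(["site1", "site2", "site3"], size=n_samples),
            "altitude": rng.choice([650, 900, 1200], size=n_samples),
        },
        index=sample_ids,
    )
    table = CommunityTable(counts, meta)
    truth = dict(truth)
    truth["scenario"] = dataclasses.asdict(sc)
    return SimOutput(table=table, tree=newick, pool=pd.Series(pool, index=asv_ids), truth=truth)
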