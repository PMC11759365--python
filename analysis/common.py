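"""Shared configuration for the numbered analysis scripts.

Two matched scenarios: ``filtered`` (Gaussian habitat filter on a Brownian
trait, host plant = habitat) and ``neutral`` (same sizes, filter off).  Sizes
are scaled down from the study's (2085 taxa, ~1e5 reads) so the full script
sequence runs in minutes; the statistical structure is unchanged.
"""

from pathlib import Path

from assemblage.community_io import (
    abundance_filter,
    align_table_tree,
    cophenetic_matrix,
    read_community_table,
)

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

BASE = {
    "n_taxa": 150,
    "reads_per_sample": 2000,
    "pool_shape": 0.995,
    "bm_sigma": 1.0,
    "n_habitats": 3,
    "species_sizes": {"sp_A": 12, "sp_B": 9, "sp_C": 12},
}
SCENARIOS = {
    "filtered": {**BASE, "filter_strength": 0.6, "m_true": 0.05, "seed": 101},
    "neutral": {**BASE, "filter_strength": 0.0, "m_true": 0.05, "seed": 102},
}
N_PERM = 199
N_REPS_RC = 199
N_PERM_PERMANOVA = 999
FILTER_THRESHOLD = 0.001


def load_scenario(name: str):
    """Load a simulated scenario, apply the 0.1% filter, align to the tree."""
    d = DATA_DIR / name
    table = read_community_table(d / "counts.tsv", d / "metadata.tsv")
    table = abundance_filter(table, FILTER_THRESHOLD)
    dist = cophenetic_matrix((d / "tree.nwk").read_text())
    table, dist = align_table_tree(table, dist)
    return table, dist, d
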