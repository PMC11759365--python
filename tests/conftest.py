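import numpy as np
import pandas as pd
import pytest

from assemblage.community_io import (
    CommunityTable,
    PhyloDistances,
    cophenetic_matrix,
    normalize_proportions,
)

TOY_NEWICK = "((A:0.5,B:0.5):1.5,C:2);"


@pytest.fixture(scope="session")
def toy_dist() -> PhyloDistances:
    """Cophenetic distances of the 3-tip toy tree: d(A,B)=1, d(A,C)=d(B,C)=4."""
    return cophenetic_matrix(TOY_NEWICK)


@pytest.fixture()
def small_table() -> CommunityTable:
    counts = pd.DataFrame(
        {"S1": [2, 3, 5], "S2": [7, 0, 3]},
        index=["A", "B", "C"],
    )
    meta = pd.DataFrame(
        {"fly_species": ["sp1", "sp1"], "host_plant": ["squash", "squash"],
         "site": ["x", "x"], "altitude": [650, 650]},
        index=["S1", "S2"],
    )
    return CommunityTable(counts, meta)


def random_table(rng: np.random.Generator, n_taxa: int = 12, n_samples: int = 6,
                 density: float = 0.6) -> CommunityTable:
    counts = rng.poisson(8, size=(n_taxa, n_samples))
    counts[rng.random((n_taxa, n_samples)) > density] = 0
    # keep every sample non-empty
    for s in range(n_samples):
        if counts[:, s].sum() == 0:
            counts[rng.integers(n_taxa), s] = 1
    ids = [f"T{i:02d}" for i in range(n_taxa)]
    samples = [f"S{j:02d}" for j in range(n_samples)]
    meta = pd.DataFrame({"fly_species": ["sp1"] * n_samples,
                         "host_plant": ["squash"] * n_samples}, index=samples)
    return CommunityTable(pd.DataFrame(counts, index=ids, columns=samples), meta)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_rel(small_table):
    return normalize_proportions(small_table)
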