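# assemblage

Community-assembly analysis for host-associated microbiomes: did deterministic
processes (habitat filtering, host selection) or stochastic ones (drift,
dispersal limitation) shape an observed set of communities?  The package was
built around a tephritid fruit-fly larval gut-microbiome study design — an
ASV count table over larvae of three fly species feeding on three cucurbit
host plants, with a bacterial phylogeny — but every stage works on any
ASV-by-sample table, sample metadata and rooted newick tree.

It implements, as a tested library plus a numbered analysis pipeline:

- **Phylogenetic dispersion** — abundance-weighted MNTD (mean nearest taxon
  distance) per sample and its standardized effect size
  `ses.MNTD = (MNTD_obs − mean(MNTD_null)) / sd(MNTD_null)` under two nulls:
  *taxa labels* (shuffle tip labels of the distance matrix) and *independent
  swap* (checkerboard swaps preserving richness and occupancy).  Mean SES
  significantly below 0 (one-sample t-test) indicates phylogenetic
  clustering, the classic filtering signature.
- **Phylogenetic turnover** — abundance-weighted βMNTD between within-group
  sample pairs with a tip-shuffle null (ses.βMNTD / βNTI sign convention:
  negative = less turnover than expected).
- **Taxonomic turnover** — abundance-weighted Raup–Crick on Bray–Curtis
  (RC-Bray ∈ [−1, 1]), ranking observed dissimilarity against communities
  reassembled from the group's pool with fixed richness and read totals;
  |RC| > 0.95 flags non-random turnover.
- **Sloan neutral model** — per-group fit of the migration rate `m` from the
  prevalence–abundance relation `freq(p) = 1 − BetaCDF(1/N; N·m·p, N·m·(1−p))`,
  RMSE comparison against binomial/Poisson sampling models, partitioning of
  taxa into neutral / above / below the Wilson prediction band (taxon-count
  and read-weighted), and intersection of selection signatures across groups.
- **β-diversity** — unweighted and generalized (α = 0.5) UniFrac, PCoA,
  crossed two-way PERMANOVA with components of variation, pairwise post-hoc
  tests with Benjamini–Hochberg FDR.
- **Synthetic communities** (`assemblage.synthetic_data`) — a generator with
  known ground truth: a Yule tree, a log-series regional pool, neutral
  dispersal-limited sampling (the Sloan beta marginal, so the fitted `m` is
  comparable to the generating one), and optionally a Gaussian habitat filter
  on a Brownian-motion trait that induces tunable phylogenetic clustering.
  Every statistical claim the package makes is validated against this
  generator.

## Worked example

The numbered scripts analyse two matched synthetic studies (150 taxa,
33 larvae in a 3 species × 3 host-plant unbalanced design, 2000 reads per
sample): `filtered` assembles communities under a host-plant habitat filter
(σ = 0.6) on a phylogenetically conserved trait, `neutral` switches the
filter off.

```bash
python analysis/01_simulate.py       # writes results/data/
python analysis/02_dispersion.py     # ses.MNTD + t-tests
python analysis/03_turnover.py       # ses.betaMNTD + RC-Bray
python analysis/04_neutral_fit.py    # Sloan fits, partitioning, shared taxa
python analysis/05_beta_diversity.py # UniFrac, PERMANOVA, PCoA
```

Key output of `02_dispersion.py` (dispersion-table layout; one row per fly
species, SES pooled across host plants):

```
[filtered | taxa_labels] mean ses.MNTD = -0.578
group      mean  df         t        p  n
 sp_A -0.909771  11 -2.414074 0.034366 12
 sp_B -0.940477   8 -2.059948 0.073366  9
 sp_C  0.025225  11  0.270608 0.791703 12
[neutral | taxa_labels] mean ses.MNTD = -0.116
```

The habitat-filtered scenario shows the clustering signature (negative mean
ses.MNTD) under the taxa-labels null while its neutral twin sits near zero;
the conservative independent-swap null, which conditions on the occupancy
pattern, absorbs most of the filter signal — the same liberal/conservative
contrast the two nulls are known for.  `04_neutral_fit.py` prints, for the
neutral twin:

```
[neutral | sp_A] m = 0.06577, RMSE = 0.115 (binomial 0.284, Poisson 0.284), 79 taxa
```

i.e. the fitted migration rate is near the generating `m_true = 0.05` and the
one-parameter neutral curve beats the zero-parameter binomial model, while
the filtered scenario fits the neutral curve much worse (RMSE ≈ 0.29).
`05_beta_diversity.py` attributes ~99 % of generalized-UniFrac variation to
host plant in the filtered scenario (PERMANOVA p = 0.001) and nothing in the
neutral one.

A single call runs the whole pipeline from one config and writes a markdown
report: `python -c "from assemblage import RunConfig, run_all; run_all(RunConfig(out_dir='results/run'))"`.

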