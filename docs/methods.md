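# Methods

This note documents the statistical machinery, the synthetic-data model used
to validate it, and the numerical and design choices a maintainer should know
about.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

The central object is an ASV-by-sample matrix of integer read counts with
aligned sample metadata (fly species, host plant, site, altitude; extra
columns pass through).  Counts are validated strictly: ids are
case-sensitive, whitespace in ids is an error, negative or non-integer
counts are errors, and every sample must have a metadata row — silent
normalization hides data bugs.

Rare-taxon filtering removes ASVs whose **study-wide** share of reads falls
below a threshold (default 0.1 %), boundary inclusive.  The threshold's scope
is configurable (`overall` | `per-sample`) because the field uses both
readings; `overall` is the default as the single reproducible rule.  Samples
emptied by the filter are dropped with a warning.  Normalization is plain
per-sample proportions (total-sum scaling); rarefaction is deliberately out
of scope.

Phylogenies are consumed, never built: a rooted newick tree with branch
lengths is turned into a cophenetic (summed-branch-length) distance matrix,
and table and tree are aligned on their common ASV set with dropped read
counts logged.  A root edge length, if present, is ignored — only edges that
bipartition the tip set are branches.

## Phylogenetic dispersion (ses.MNTD)

For one sample with relative abundances `f_i` over present taxa and
cophenetic distances `d_ij`, the abundance-weighted mean nearest taxon
distance is `MNTD = Σ_i f_i · min_{j≠i, f_j>0} d_ij`.  The standardized
effect size is computed against `n_perm` (default 1000) randomizations:

- **taxa labels**: one joint row/column permutation of the distance matrix
  per draw — randomizes phylogenetic structure, conditions on community
  structure (the liberal null);
- **independent swap**: repeated random 2×2 checkerboard swaps of the
  occupancy pattern, carrying abundances with the presences — preserves both
  sample richness and taxon occurrence frequencies exactly (the conservative
  null).  Default 1000 successful swaps per null matrix with an attempt cap;
  matrices without checkerboards are returned unchanged.

Randomizations are confined to each host-plant group's submatrix (different
host plants plausibly sample different source pools), one shared draw set per
group.  Degenerate nulls (sd = 0) yield NaN SES with a warning and are
excluded from tests.  Group-level inference is a two-sided one-sample t-test
of SES against zero, pooled per fly species; mean SES < 0 reads as
phylogenetic clustering.  An `nti` column (= −SES) is available for the
sign-flipped convention.

## Phylogenetic turnover (ses.βMNTD)

βMNTD seeks each taxon's nearest relative in the *other* community:
`0.5·[Σ_{i∈k} f_ik·min_{j∈l} d_ij + Σ_{j∈l} f_jl·min_{i∈k} d_ij]`; shared
taxa contribute zero.  The null is a tip shuffle (equivalent to the
taxa-labels relabeling).  Pairs are formed within (species × host-plant)
groups and their SES values pooled per species for the t-test — this
reconciles stratified nulls with per-species inference and matches the
degrees of freedom such pooling implies.  By default one shared set of
shuffles per group is reused across that group's pairs; the per-pair
marginal null distribution is identical to independent shuffling (each draw
is one uniform permutation either way) at a large speedup, and a
`per_pair=True` flag restores the literal procedure.  Note that a pair of
identical communities is identical under every relabeling, so its null is
degenerate at zero and SES is flagged rather than reported as 0.

## Taxonomic turnover (RC-Bray)

For a within-group pair, the observed Bray–Curtis dissimilarity
`1 − 2Σmin(x,y)/(Σx+Σy)` is ranked against `n_reps` (default 999) null
pairs.  Each null community preserves its sample's richness `S` and read
total `N`: membership is `S` taxa drawn without replacement with probability
proportional to the group occurrence frequency `o_i`; each member gets one
guaranteed read and the remaining `N − S` reads are multinomial with weights
proportional to the group read share `a_i`.  Then
`RC = 2·(frac(null < obs) + 0.5·frac(null = obs)) − 1`, ties at half weight
(floating-point ties use a 1e-12 tolerance; counts are integers so true ties
are exact).  The pool is the (species × host-plant) group, consistent with
the stratification of the other null models.  As with the tip shuffles, one
set of `n_reps` assemblies is drawn per sample and the r-th draws of the two
samples are compared — the pair-level null distribution is unchanged.
Pairs are flagged `greater`/`smaller`/`neutral` at |RC| > 0.95, and per-species
t-tests of RC against zero are reported alongside.

## Sloan neutral model

With community size `N` (mean of the group's per-sample read totals; median
by option), detection limit `d = 1/N`, per-taxon mean relative abundance
`p_i` (mean of per-sample proportions; a pooled-reads variant exists) and
observed prevalence `freq_i`, the neutral prediction is
`freq(p) = 1 − BetaCDF(d; N·m·p, N·m·(1−p))`.  The single parameter `m` is
fitted by least squares on a 33-point log grid over [1e−8, 1] followed by
bounded refinement in the best bracket (guards against the flat SSE region
at tiny `m`); taxa absent from every group sample are excluded with a log
message, and an all-present prevalence pattern is a hard error (nothing to
fit).  Taxa are computed in a canonical (sorted-id) order so the fit — and
therefore every classification — is bit-identical under row permutations.

Goodness of fit is the RMSE of prevalence residuals, compared against the
zero-parameter binomial `1 − (1−p)^N` and Poisson `1 − e^{−Np}` detection
models.  The 95 % band around the predicted prevalence is the Wilson score
interval with the group's sample count as denominator; taxa above/below the
band are read as positive/negative selection candidates, summarized as
taxon-count ("unweighted") and read-share ("weighted") fractions, and
selection signatures are intersected across groups.

## β-diversity

UniFrac is computed branch-by-branch from per-branch descendant proportions:
unweighted = unshared spanned branch length / union spanned branch length;
generalized = Chen's formula with weight `L_b(p_A+p_B)^α` and α = 0.5 (the
"d(0.5)" matrix).  PCoA is the Gower-centred eigendecomposition; percent
variation is reported over the positive eigenvalue mass and negative
eigenvalues are logged, not corrected.

PERMANOVA partitions the Gower matrix of squared distances with projection
matrices of an effect-coded crossed design (A, B, A×B, residual; partial SS
per term = full model vs model without the term).  The publication-grade
reference implementation permutes "residuals under the full model" with
type-III SS inside PRIMER, whose exact algorithm is proprietary; here the
default is Freedman–Lane permutation of reduced-model residuals per term
(`scheme="residual"`), with raw-label permutation as the alternative, and a
type-I-error calibration test guards the approximation.  P-values use the
bias-avoiding `(b+1)/(n_perm+1)` estimator.  Components of variation are
method-of-moments estimates from expected mean squares with multiplier
`k_T = n/levels(T)` (exact for balanced designs, an approximation otherwise),
negatives clamped to zero, reported as percent of the summed components.
Pairwise post-hoc tests are one-factor PERMANOVAs per group pair with
`t = √F` and Benjamini–Hochberg adjustment.

## Synthetic communities

The generator provides the ground-truth data every statistical claim is
tested against.

- **Tree**: Yule (pure-birth) with tips labelled `ASV0001…`; zero-length
  edges from simultaneous events are floored at 1e−8 and the root edge is
  stripped.
- **Pool**: log-series draws normalized to sum 1.  Larger shape parameter
  (toward 1) gives a heavier tail, i.e. stronger dominance.
- **Neutral regime**: per sample, latent relative abundances
  `Beta(N·m·p_i, N·m·(1−p_i))`, renormalized across taxa, then `N` reads
  multinomially.  This is the beta marginal of the fitted neutral model, so
  parameter recovery is meaningful; a forward Moran/Hubbell simulation is a
  non-goal.
- **Filtered regime**: a trait evolves on the tree by Brownian motion (rate
  `bm_sigma`); habitat optima sit at evenly spaced quantiles (0.15–0.85) of
  the tip-trait distribution; sampling weights are
  `p_i·exp(−(t_i−θ_h)²/2σ²)` and reads are multinomial.  `σ = 0` switches
  the filter off and reduces exactly to multinomial sampling from the pool.
- **Study scenario**: three "fly species" groups (default sizes 48/26/48)
  crossed unbalanced with three "host plants" (the last species never occurs
  on the first plant), reads per sample defaulting to the study scale
  (~1e5), `m` defaulting to 5e-4 (within the range such fits report for
  strongly dispersal-limited gut communities), 2085 taxa.  Host plant is the
  habitat in the filtered regime.  Site and altitude metadata are carried
  but excluded as analysis factors by default.

What the generator does **not** emulate: sequencing error and chimeras,
compositional artifacts of amplification, taxon-specific read-depth
variation, contamination, or any covariance between pool abundance and tree
position.  Passing calibration on it therefore shows the statistics are
internally correct and calibrated under their own assumptions — not that
real data meet those assumptions.

Seeding: one master seed per scenario; per-component child seeds are derived
with `numpy.random.SeedSequence` and kept below 2³¹, so any stage can be
replayed in isolation and full pipeline runs are byte-identical.

## Problem sizes used in validation

The test-suite and acceptance experiments run at deliberately reduced sizes,
chosen so each check has adequate statistical resolution:

- Neutral calibration of ses.MNTD / ses.βMNTD: SES values of samples sharing
  one tree and pool are strongly correlated (the tree/pool draw shifts the
  whole scenario's SES by ~±0.6–0.9), so calibration averages over **50
  independent replicates** (fresh tree, pool and 4 samples each; 60 taxa,
  500 reads, m = 0.1) rather than many samples of one scenario.  The grand
  mean is required to lie within ±0.3 of zero.
- RC-Bray and PERMANOVA type-I rates: 500 replicates each at nominal
  α = 0.05 with 199 permutations, tolerance ±0.02.
- Habitat-filter detection: 100 taxa, 50 samples, σ = 0.3, 199 permutations.
- Migration-rate recovery: 10 simulations at 500 taxa, 100 samples,
  N = 10,000, m = 0.1.
- The default pipeline scenario (150 taxa, 33 samples, 2000 reads) and the
  analysis scripts complete in minutes on one core.

## Known limitations

- The Sloan fit shows a systematic upward bias in `m̂` of roughly a quarter
  of its value under the exact generative conditions above.  Two structural
  causes, both inherent to the standard fitting recipe rather than to this
  implementation: the model treats detection as a hard threshold at `d = 1/N`
  on the latent relative abundance while real (and simulated) detection is
  multinomial (`P(detect|q) = 1 − (1−q)^N`), and `p_i` must be estimated from
  the same finite, renormalized samples being fitted.  The acceptance suite
  reports the measured median relative error honestly; at these conditions it
  straddles 25 %.
- Independent-swap sampling uses sequential random checkerboard swaps; like
  all swap algorithms it mixes, but uniformity over the fixed-margin
  ensemble is approximate at finite swap counts.
- The PERMANOVA residual-permutation scheme and the components-of-variation
  multipliers are standard approximations for unbalanced designs, not a
  reimplementation of PRIMER's proprietary algorithm.
- Cophenetic-matrix construction is quadratic in tip count via dendropy's
  distance table; at the full study scale (~2000 tips) it takes tens of
  seconds.
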