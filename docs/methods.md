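# Methods

## Pedigree path-counting relatedness

The kinship index between two individuals is the sum over genetic paths of
(1/2)^N, where N is the number of edges on the path.  A legal path is
simple (no repeated individual), ascends child→parent from one individual
to a single apex ancestor, then descends to the other; either leg may be
empty, so a direct ancestor is its own apex (parent–offspring: one path,
N = 1, value 1/2).  Two paths are distinct iff their edge sets differ.
Maternal relatedness is the same sum over paths made entirely of dam
edges; since those paths are a subset of all paths, maternal ≤ genetic
always.

On pedigrees with no inbred individual this path sum equals the classical
coefficient of relationship, i.e. twice the kinship coefficient Φ defined
by Φ(x,x) = 1/2 and Φ(a,b) = ½[Φ(sire(a),b) + Φ(dam(a),b)] (recursing on
the member that is not an ancestor of the other; unknown parents
contribute 0).  The test suite asserts this identity exhaustively on
random non-inbred pedigrees and validates textbook pairs (full sibs 0.5,
half sibs 0.25, avuncular 0.25, first cousins 0.125) against a
200,000-replicate gene-dropping Monte Carlo.  On inbred pedigrees the
implementation computes the literal path sum, which omits Wright's
(1 + F) apex correction; the simple-path restriction is what keeps the
sum finite on loops.  This is a deliberate reading of the formula as
stated, and the divergence from the textbook coefficient on inbred
pedigrees is accepted and documented rather than patched.

Conventions: the diagonal of a relatedness matrix is fixed at 1 (self
pairs never enter the analyses); individuals absent from the pedigree are
isolated founders with relatedness 0 to everyone; path listings are
sorted lexicographically for reproducible output.

## Diversity

Alpha diversity per sample: observed OTUs (count of nonzero taxa),
Shannon index in bits (log base 2, the classic amplicon default;
switchable), and Faith's PD (total branch length of the minimal rooted
subtree spanning the observed leaves), computed through scikit-bio.

Beta diversity is UniFrac on a rooted tree, in three modes: unweighted
(unique branch length over observed branch length), weighted raw
(Σ l_b |p_A,b − p_B,b| over branches, p the subtree relative abundance),
and weighted normalized (raw divided by Σ l_b (p_A,b + p_B,b), bounded by
1) — the pipeline default is weighted normalized.  Table taxa missing
from the tree are a hard error (silently dropping them would bias
distances); tree tips missing from the table are harmless.  No
rarefaction is applied by default; a seeded rarefy-to-common-depth helper
exists because depth standardisation is a legitimate alternative
convention.

PCoA is classical scaling implemented directly: double-center −D²/2,
eigendecompose, scale eigenvectors by √eigenvalue; negative eigenvalues
are clamped to zero for coordinates but reported, so non-Euclidean
distance matrices are visible rather than hidden.  Euclidean inputs
round-trip to 1e-9; eigenvalues cross-check against scikit-bio's
implementation in the tests.

## Group statistics

* **Mann-Whitney U** (two-sided): exact enumeration when both groups have
  n ≤ 8 and the pooled values are tie-free, otherwise the normal
  approximation with tie and continuity corrections.  The direction
  reported is the sign of the median difference (means break ties).
* **Benjamini–Hochberg** step-up q-values for every multiple-testing
  context (pairwise PERMANOVA, age screen).
* **PERMANOVA** in the McArdle–Anderson projection form: the Gower-centered
  matrix G = −½ C D² C is partitioned by hat matrices of a sequential
  design (one or two terms, in the order given; categorical factors as
  dummies, numeric covariates with more than 8 distinct values as
  standardized continuous columns).  Pseudo-F per term uses the residual
  of the full model; p-values permute sample labels freely
  (p = (#{F* ≥ F} + 1)/(n_perm + 1), default n_perm = 999, seeded;
  exhaustive enumeration available for tiny n).  Free permutation is the
  simplest defensible null here — no blocking structure is specified for
  the design.  Single-factor results agree with scikit-bio's PERMANOVA
  and, on 1-D Euclidean data, with the classical ANOVA F.
* **IndVal** (Dufrêne–Legendre): A = group mean abundance over the sum of
  group means, B = within-group occurrence fraction, IndVal = √(A·B),
  best group by argmax, significance by permuting group labels.  The
  group-size-corrected variant is not implemented; the classical form is
  the default choice.

## Consensus screen

One differential pool per non-reference population: taxa with Mann-Whitney
p < α (default 0.05) against the wild reference at the chosen taxonomic
rank, tested on relative abundances (configurable to raw counts; rank
tests are not invariant to per-sample renormalisation when depths differ,
so the choice is explicit).  No multiplicity correction is applied within
pools — the cross-pool consensus is the error control, and raw per-pool
p-values keep the pools comparable across population sizes.  Taxa in at
least `min_support` pools (default 6 of 8) are retained with a majority
direction; direction conflicts are kept but flagged.  Populations with
fewer than 2 samples produce a pool with a logged low-power warning, not
an error.  The "at least six" reading of the support threshold follows
the executed workflow description; the alternative "more than six" is one
configuration flag away.

## Host associations

Sex is a factor, age a continuous covariate (an optional binned mode
exists).  Two-factor models enter population first, so the trait is
assessed conditional on the population differences.  The kinship
association is a plain Spearman correlation between per-pair microbiota
distance and per-pair relatedness over pairs with relatedness > 0,
exactly as the screening analysis defines it; pairs are unordered and
counted once.  Zero-relatedness exclusion exists because cross-population
pairs are always 0 and between-population dissimilarity would otherwise
manufacture a positive association.

Limitation, stated plainly: pairs sharing an individual are not
independent, so the analytic Spearman p is approximate.  With many small
families it is close to nominal (measured ≈5% type-I at α = 0.05 in the
null calibration); with few large families it is anticonservative
(measured ≈12% in a two-big-colony design).  A seeded Mantel-style
permutation p (permuting individuals, not pairs) is available as a
robustness option and is the recommended check when family structure is
concentrated.

The one-individual outlier exclusion is configuration-driven (an explicit
sample list in the run config), not automated: the original exclusion was
a judgement call from an ordination plot, which is not an algorithm.

## Synthetic-study generator

The generator emulates the nine-population design: wild (n = 10,
status `wild`), wild-fed (n = 14, AD), and seven captive colonies
(7/3/24/6/33/17/9, AD); one sample per individual; ages uniform on
[1, 25] years; sexes Bernoulli(1/2) with no planted sex effect (only
marginal sex effects are expected, so none are planted).

**Pedigree.**  Wild and wild-fed individuals are isolated founders (their
ancestry is unobserved).  Each colony starts from unrelated founders
(~40% of colony size, both sexes guaranteed) and fills the remainder over
3 generations; offspring join breeding couples (reused with probability
0.6, producing full sibships) and sires occasionally come from another
colony (probability 0.1), creating cross-colony kin.

**Tree.**  Random binary coalescence within each phylum block, then
across blocks, exponential(1) branch lengths — phylum blocks are clades,
so phylum-level composition shifts register in UniFrac.

**Counts.**  Per-sample expected log relative abundance =
baseline (N(0, 1.5²) per taxon) + population effect (N(0, 0.6²) per
population × taxon) + AD shift + age slope × (age − 13) + genetic value +
sample noise (N(0, 0.4²)), softmaxed to proportions; counts are
Dirichlet-multinomial with concentration 200 at a uniform random depth in
[15000, 30000] — realistic overdispersion (per-taxon Dirichlet mass
c·p_i is of order 1, so rare-taxon log noise exceeds 1).

**Planted effects and their calibration.**  Defaults are fixed by the
generator's contract that each planted effect is recoverable by the stage
that targets it:

* *Phylum shifts* (AD samples): Bacteroidetes +1.0, Firmicutes −0.8,
  Actinobacteria −1.0, Verrucomicrobia −1.0, Tenericutes −0.8 log units;
  three neutral filler phyla.  This reproduces the expected direction of
  the F/B ratio contrast in >95% of replicates.
* *Consensus genera*: 12 planted genera at ±6.0 log units (an
  order-of-magnitude-plus, presence/absence-scale contrast, as befits
  consistently differential genera), drawn from the rarer half of the
  community, with the contrast centered (reference −δ/2, AD +δ/2) and
  signs alternating along the baseline ranking.  The centering and
  balancing make the planted set compositionally neutral: without them,
  softmax renormalisation displaces every null taxon and the "null" taxa
  of the recovery benchmark stop being null.  The weakest pool (n = 3
  vs 10) needs near-complete separation for p < 0.05, which sets the
  effect scale.
* *Age genera*: 12 genera at ±0.15 log/year (≈36-fold across the age
  range), drawn from the commoner half — count noise on rare taxa would
  bury the trend.
* *Heritable component*: for each of 60 designated taxa (the commoner
  half; abundance-weighted UniFrac cannot see rare taxa) an independent
  across-individual draw from N(0, σ_g² K), σ_g² = 0.8, expressed with
  loading ±1.5.  K is the package's own path-counting kinship matrix —
  deliberately, so the association stage is tested against exactly the
  statistic the pipeline computes.  One draw per taxon (not one scalar
  liability per individual) is the standard additive-genetic form; a
  single shared liability would cap the attainable distance–kinship
  correlation near −0.16 regardless of expression strength, because one
  Gaussian draw per individual is irreducibly noisy.

Named configurations: `null_config()` zeroes every effect (populations
exchangeable — the null-calibration condition) and
`consensus_benchmark_config()` keeps only the 12 planted genera among 188
null taxa (phylum shifts and population effects off; with population
effects on, every taxon differs between populations and the notion of a
null taxon dissolves).

**What the generator does not emulate:** real phylogenetic signal in
abundances beyond block structure, covariance between taxa other than
compositional closure and the planted structure, longitudinal sampling,
and sequencing artefacts (chimeras, contamination).  Passing tests
therefore demonstrate that the analysis recovers the modelled structure
at realistic noise levels — not that real data meet the model.

## Problem sizes used by the test and acceptance runs

Chosen to give stable verdicts at interactive runtimes: kinship identity
on 100 random pedigrees of ≤ 40 individuals (all pairs); gene dropping at
200,000 replicates; PERMANOVA null calibration on 500 replicates of a
20-sample Euclidean design at 99 permutations; pool-inclusion null on 2
full null studies (3200 taxon × pool trials); kinship-association null on
200 replicates of a reduced dispersed-family design (wild 6 + 3 colonies
of 14, 64 taxa); recovery on 50 benchmark replicates, F/B direction on
100 default replicates, heritability detection on 50 default replicates.
Permutation counts in the pipeline default to 999 with a mandatory master
seed; every stage derives its own substream from the master seed plus a
stage tag, so adding a stage never perturbs earlier draws.
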