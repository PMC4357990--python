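# Methods

## The model

A locus with joint copy-number and allelic variation (CNAV) is described as
the static summary of a dynamic generative process.  The user defines a
directed graph with one start state, one end state, silent states and
emitting states; each visit to an emitting state increments the count of one
symbol (an allele probed by an MLPA-style assay).  A *haplotype* is the
emission tally of one random start-to-end walk under a row-stochastic
transition matrix A; a diploid *genotype* is the element-wise sum of two
independent walks.  Deletions are silent bypass branches; duplications are
recursion loops that revisit an emitting block.  Wiring the loops so that
every directed cycle contains at least one emitting state guarantees that
walks terminate almost surely (and that bounded enumeration terminates).

The construction extends the Hardy-Weinberg equilibrium by three
independence assumptions: between chromosomes (the two walks), between
individual gene copies (a fresh allele draw per duplication), and between
copy-number events (Markov transitions), with the copy-number process taken
to be at steady state.  Under a shared duplication probability g the
per-haplotype copy number is geometric, P(k | not deleted) = (1−g)·g^(k−1).
Deviations from these assumptions are expressed as alternative wirings:
loss-of-heterozygosity duplication (per-allele repeat loops), first-order
allele dependence (interconnected allele states), composite tandem alleles
(two-state emit chains), and fully interconnected gene blocks for
gene-order discovery.

### Haplotype-pair convention

Haplotype pairs are **ordered** everywhere — simulation, likelihood,
enumeration and the latent-variable sampler all count (h1, h2) and (h2, h1)
separately.  Likewise all likelihoods are for the ordered sample of N
individuals, with no multinomial coefficient.  One convention everywhere
means no symmetry factor can be dropped or double-counted, and the HMM and
reference-model evidences are defined on the same event space and hence
comparable.

## Inference

Transition probabilities carry a MatrixDirichlet prior (an independent
Dirichlet on each row; default concentration 1.0 per edge, Jeffreys 0.5
available).  The latent variables are the path pairs compatible with each
observed genotype.  One Metropolis-within-Gibbs cycle:

1. **Pool (incomplete Gibbs) update.**  For each individual, up to n
   candidate pairs are simulated from the current A; the first pair whose
   emission sum matches the observed genotype replaces that individual's
   latent pair.  This is rejection sampling from the exact conditional
   P(pair | A, genotype), so acceptance is 1; individuals with no match in
   the pool keep their pair (identity kernel).  Pools are independent
   across individuals, which keeps the conditional updates independent
   given A.  The implementation draws candidates in growing chunks
   (4, 8, 16, …, capped at n) and retires each individual at its first
   match, which preserves the sequential-rejection law exactly while doing
   near-minimal work when A is close to an optimum.
2. **Squirrel backup.**  Individuals the pool missed get a symmetric
   Metropolis update: a proposal drawn uniformly from the set of compatible
   pairs found by a deterministic bounded tree search that depends only on
   the genotype (never on the current pair — that is the symmetry
   certificate, and it is tested), accepted with min(1, P(prop|A)/P(cur|A)).
   If the search exceeds its node budget the identity kernel is used.
3. **Conjugate draw of A** from Dirichlet(prior + latent transition counts),
   row by row; single-edge rows are pinned at probability 1.

When every observed genotype has a unique compatible pair the augmentation
collapses and the draws are i.i.d. from the closed-form MatrixDirichlet
posterior; this conjugate case is used as an exactness oracle in the tests.
On ambiguous models the posterior means are validated against grid
quadrature with the exactly enumerated likelihood (feasible at ≤ 2 free
parameters).

Initialization is not part of the model: by default each individual starts
from a uniformly random compatible pair.  The restart driver for multimodal
problems instead uses deterministic *stratified* starts — run r initializes
every individual at the decomposition preferred under the r-th lexicographic
permutation of the emitting-state ids — so that on label-symmetric graphs
the restarts cover the symmetry-related basins systematically rather than by
coupon-collecting (with 12 uniform restarts on 6 basins, the chance of
covering all 6 would only be ≈ 0.44).

Diagnostics (ESS, integrated autocorrelation time, split-chain PSRF) are
computed with ArviZ on the post-burn-in draws; burn-in defaults to the first
50% of cycles.

## Likelihood and model comparison

The HMM likelihood P(y | A) has no closed form in general.  Two evaluators:

* **Exact:** genotype probabilities from bounded exhaustive path
  enumeration.  Because any haplotype contributing to an observed genotype
  y satisfies e_k ≤ y_k per symbol, capping the enumeration at the observed
  per-symbol maxima loses nothing — the value is exact (raw path
  probabilities, no renormalization).  On densely connected graphs the path
  count explodes and this route raises an overflow error.
* **Simulated:** relative genotype frequencies over M simulated ordered
  pairs, with additive smoothing 1/(2M) on the observed cells so that a
  genotype unseen in the simulation contributes a large-but-finite penalty
  instead of −∞ (the zero-frequency pathology).  The standard error comes
  from the multinomial delta method and was verified against replicate
  spread.

The marginal likelihood uses the Chib–Jeliazkov two-block identity
log m(y) = log f(y|A*) + log π(A*) − log π̂(A*|y), with the posterior
ordinate Rao-Blackwellized over the recorded per-cycle latent transition
counts (the MatrixDirichlet full-conditional density averaged at A*).  A*
defaults to the posterior-mean matrix projected strictly inside the simplex
(floor 1e-6, rows renormalized); the estimate is invariant (within Monte
Carlo error) to the choice of interior A*, which is tested.  The posterior
ordinate's Monte Carlo error is estimated by batch means.

The reference model (naive enumeration model, NEM) is a
Dirichlet-multinomial over the distinct observed genotypes plus one pooled
unobserved category, Jeffreys concentration 1/2 per category, evaluated in
closed form for the ordered sample.  Bayes factors require matching data
fingerprints (an order-insensitive digest of the genotype multiset).

## Phase translation

Graphs may attach an alternative (phased) emission symbol to each emitting
state; two loci whose assay probes cannot be separated share primary
symbols but carry locus-tagged alternative symbols.  After fitting, a very
large set of path pairs is simulated at the posterior-mean matrix; pairs
are grouped by their non-phased genotype, and within each observed
genotype's group the alternative-symbol tallies give the phased genotypes
and their probabilities.  Every simulated pair is checked to marginalize
back to its primary genotype.  Genotypes matched by fewer than `min_hits`
pairs (default 100) are reported as unresolved with the advice to raise M.

## Multimodal dissection

On a fully interconnected m-gene graph the data contain no ordering
information, so the posterior has at least m! modes (forward/reverse pairs
of m!/2 orders).  The procedure mirrors repeated-restart practice: R
stratified restarts, pooling of post-burn-in draws, k-means (k-means++, 10
restarts, fixed seed) on the free-parameter coordinates, majority
assignment of runs to clusters, and per-cluster ranking by the CJ marginal
likelihood of member runs evaluated at the cluster's interior-projected
mean matrix.  The likelihood ordinate depends only on the cluster's A* and
is computed once per cluster (simulated evaluator, since exact enumeration
is infeasible on these graphs).  Each cluster also reports its
highest-probability path (best-first search over partial paths, admissible
because extension never increases probability; ties broken
lexicographically; verified against brute-force enumeration) and the gene
order it emits.

A caveat established empirically while validating this module: a chain
confined to one basin estimates log m(y) + log w, where w is that basin's
posterior mass.  On finite data simulated with fully independent gene copy
numbers, the basin masses of *different* gene orders genuinely differ by
O(1–3) log units, because each fitted mode adapts to the sample's
accidental inter-gene correlations; only in expectation are all six equal.
What is exact at any sample size is the reversal symmetry — a path and its
reverse emit the same counts, so forward/reverse basins have identical
mass.  The acceptance checks therefore assert the recovery of all six
orders and the equivalence of the three forward/reverse pairs, and report
(without asserting) the spread across all six.

## Synthetic data

No real cohort ships with the package.  The fixtures module generates
MLPA-style tables from canonical graphs at known transition matrices, with
a default cohort size of N = 387 mirroring the scale of the motivating
study.  Default rates — haplotype deletion ≈ 0.1–0.15, duplication ≈
0.05–0.15, intermediate allele frequencies — are of the order reported for
the low-affinity Fc-gamma-receptor region.  The generator emulates integer
allele-count tables only; it does **not** emulate MLPA intensity noise,
probe dropout, or genotyping error, so passing tests demonstrate
correctness of the inferential machinery given correct integer counts, not
robustness to assay noise.  Individuals with all-zero counts are legal
(double null haplotypes are real for these loci).

## Numerical choices and problem sizes

* Walks are simulated in lock-step batches (vectorized over walkers) with a
  10,000-step guard against near-absorbing loops.
* Per-symbol copy caps default to 5 per haplotype (the practical resolution
  range of the assay); enumeration limits: 2×10^5 paths for user-facing
  enumeration, 4×10^5 for the shared compatible-pair cache; the squirrel
  node budget defaults to 20,000.
* Row-stochasticity is enforced to 1e-12 on exact constructions and 1e-9
  after renormalizations; density ordinates require interior points
  (tolerance 1e-6).
* Statistical test sizes were chosen once for desk-scale runtimes: the
  conjugate check at N=200 with 1000 cycles; the quadrature check at N=150
  on a 120×120 grid; oracle equivalence at M=10^6 draws; evidence
  replication at N=500 over 50 replicates; mode recovery at N=120 with
  R=12 restarts and block-linkage replication at N=50 over 50 replicates
  with R=6.  The chi-square occupancy test thins the kernel's trajectory
  by 10 to decorrelate counts before comparing with the exact conditional.

## Known limitations

* The sampler assumes independence between chromosomes; inbreeding or
  population structure is out of scope.
* The squirrel search is a faithful implementation of the stated contract
  (symmetric, bounded, genotype-determined) but no published reference
  implementation of the original tree search was available for a
  line-by-line comparison.
* Genotypes whose compatible-pair set exceeds the budget mix only through
  the pool kernel; for pathological caps this can slow mixing for rare
  high-copy genotypes.
* Exact likelihood evaluation is infeasible on densely connected graphs;
  the simulated evaluator's smoothing introduces O(1/M) bias for very rare
  genotypes.
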