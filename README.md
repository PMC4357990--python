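# cnavhmm

Bayesian hidden-Markov modelling of genotype distributions with joint
copy-number and allelic variation (CNAV).

Assays such as multiplex ligation-dependent probe amplification (MLPA)
report, per individual, integer copy counts of allele-specific sequence
motifs — e.g. the seven genes and nine SNPs of the low-affinity
Fc-gamma-receptor region, where genes vary both in how many copies a
chromosome carries and in which alleles those copies bear.  Enumerating
such genotypes runs into the zero-frequency problem (genotypes absent from
a sample get probability zero), and classical Hardy-Weinberg calculations
do not apply once copy numbers vary.

`cnavhmm` treats a genotype as the static summary of a dynamic process: a
user-defined directed HMM graph — one start state, one end state, silent
states, and states that each emit one counting event per visit — is walked
randomly twice per individual, and the two walks' emission tallies are
summed.  Deletions are silent bypass branches, duplications are recursion
loops, and the transition probabilities A extend the Hardy-Weinberg
haplotype frequencies with two further independence assumptions (between
gene copies and between copy-number events, at steady state).  With a
shared duplication probability g, per-haplotype copy numbers are geometric:
P(k | not deleted) = (1 − g) g^(k−1).

The package provides, for users analysing CNAV count tables or studying
such models:

* **graph_model** — graph data model, a JSON dialect, validation,
  canonical builders (Hardy-Weinberg, CNAV with loss/gain loops, LOH,
  first-order allele dependence, tandem alleles, two-locus phasing,
  fully connected gene blocks), and exhaustive bounded path enumeration;
* **simulate** — vectorized random walks, synthetic data sets, and exact
  (enumeration) vs empirical (simulation) genotype distributions;
* **inference** — a data-augmented Metropolis-within-Gibbs sampler for A:
  an incomplete-Gibbs pool update of latent path pairs (acceptance 1,
  identity fallback), a symmetric bounded tree-search backup kernel
  ("squirrel"), conjugate MatrixDirichlet draws, diagnostics and
  credible-interval summaries;
* **evidence** — exact and simulation-approximated likelihoods, the
  Chib–Jeliazkov marginal likelihood, a closed-form Dirichlet-multinomial
  reference model (NEM, Jeffreys prior, one pooled unobserved category),
  and Bayes factors;
* **phasing** — translation of non-phased genotypes into phased genotypes
  via alternative emission sets, with translation probabilities;
* **modes** — multimodal posterior dissection: stratified restarts,
  k-means clustering of draws, per-mode evidence ranking, and
  highest-probability-path gene ordering;
* **fixtures** — synthetic scenarios (graph + true matrix + simulated
  table) mirroring the Fc-gamma-receptor panel, at the study scale of
  N = 387 by default.

## Worked example

Simulate 387 individuals from a biallelic copy-number model whose true
haplotype deletion probability is 0.15, duplication probability 0.1 and
allele frequencies 0.5/0.5; then infer A and compare the model against the
naive enumeration model:

```sh
cnav simulate --scenario cnav_multiallele --seed 42 -N 387 \
     -o data.tsv --graph-out graph.json --param loss=0.15 --param gain=0.1
cnav fit --graph graph.json --data data.tsv \
     --cycles 1000 --pool 1000 --seed 7 --out fit
cnav evidence --graph graph.json --data data.tsv --method cj \
     --cycles 600 --pool 500 --seed 8 --out cj.json
cnav evidence --graph graph.json --data data.tsv --method nem --out nem.json
cnav compare -a cj.json -b nem.json
```

The fit summary (`fit.summary.json`) contains the posterior mean and 95%
credible interval per graph edge; this run prints

```
in->del        mean 0.146  95% CI [0.122, 0.175]
choose->A      mean 0.517  95% CI [0.479, 0.551]
post->gain     mean 0.103  95% CI [0.081, 0.127]
mean match fraction 0.998
```

— the deletion edge recovers the true 0.15, the allele bifurcation the true
0.5, and the duplication loop the true 0.1; a match fraction near 1 means
the pool update refreshed nearly every individual's latent path pair each
cycle.  The evidence comparison prints

```
log marginal likelihood (chib_jeliazkov): -801.6823 +- 0.0082
log marginal likelihood (nem_closed_form): -818.7748 +- 0.0000
BF(cj.json over nem.json) = 2.64978e+07 (log = 17.0926, log10 = 7.4232)
```

a Bayes factor of ~2.6×10^7 in favour of the structured HMM over the naive
enumeration of observed genotypes — the HMM describes the same data with
3 free parameters instead of one frequency per distinct genotype, and
assigns positive probability to every reachable genotype.

The same library surface is available in Python
(`cnavhmm.run_sampler`, `cnavhmm.chib_log_marginal`, …); `cnav phase`
translates genotypes into phased genotypes after a fit, and `cnav modes`
runs the restart/cluster/rank analysis for gene-order discovery.

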