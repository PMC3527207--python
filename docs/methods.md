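# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer would want to know.

## 1. The generative model (synthetic_cytoplasm)

The synthetic world realises the hypothesis the analysis is built to test:
a single ancestral endosymbiont infection transmitted strictly through the
maternal cytoplasm alongside the mitochondrial genome.

* **Genealogy.** A Kingman coalescent for `n_strains` haploid lineages with
  effective size `effective_size` (time in host generations; waiting time
  with k lineages ~ Exp(k(k−1)/(2N))).  Default N = 40,000 puts the
  expected sample TMRCA near 2N(1−1/n) ≈ 76,000 generations ≈ 7,600 years
  at ten generations/year — the magnitude of the root age the dating
  analysis reports on real data.
* **Infection loss.** The root lineage is infected.  Each branch carries
  Poisson(λ · branch length) loss events; a strain is uninfected iff any
  loss lies on its root-to-tip path; loss is never reversed.  No empirical
  loss rate exists, so the default λ = 7×10⁻⁶ per generation is a
  documented convention; at the default tree depth it yields a mean
  infected fraction of ≈ 0.67, close to the 62% observed in the study
  system.  Because losses near the root are shared, replicate worlds have
  heavy-tailed infected fractions (occasionally all strains uninfected);
  downstream stages degrade gracefully (stages needing infected strains are
  skipped).
* **Sequences.** HKY+Γ, one kappa/frequency set genome-wide (default
  kappa 5, AT-rich frequencies (0.40, 0.10, 0.10, 0.40), Γ shape 0.5 with
  4 equal-probability categories, one category multiplier drawn per site).
  Each site's substitution rate is its class rate: defaults are the
  reported median per-generation rates (mt codon 1+2: 1.36×10⁻⁸,
  mt codon 3: 6.2×10⁻⁸, symbiont classes ≈ 6.4–8×10⁻¹⁰).  Symbiont rows
  exist only for infected strains; evolving the full tree and discarding
  uninfected rows is distributionally identical to evolving the induced
  subtree (Markov property).
* **Coverage.** Per-base depth ~ Poisson(mean) with defaults
  mtDNA 55×, symbiont 20×, nuclear control 10× (the mtDNA:nuclear ratio
  ≈ 5.5 mirrors the reported copy-number contrast).  Uninfected strains
  have zero symbiont coverage except a configurable `contamination_fraction`
  that receives patchy coverage (Bernoulli(0.5) patches at Poisson(12)
  depth), reproducing the "intermediate breadth" libraries that the
  classification rule must score uninfected.  Read base counts put the true
  base at each covered site with per-read error 0.1%, so consensus support
  at depth 20 is ≈ 99.9%, matching the heteroplasmy-proxy values the
  analysis reports.
* **Scaled genome sizes.** Defaults are 3 kb mtDNA and 10 kb symbiont
  (reality: 14.5 kb and 1.2 Mb).  This is a runtime choice; see §6 for
  where tests deliberately enlarge either the genome or the tree.

What the generator does **not** emulate: read-level artefacts (mapping
bias, duplicates, indels — deletions enter only through the consensus N
rule), recombination, selection, paternal or horizontal transmission, and
population structure in the genealogy (strain-to-population assignment is
round-robin, independent of the tree).  A green test therefore establishes
correctness of the statistical machinery under the co-transmission model,
not robustness to real-data artefacts.

## 2. Coverage and infection calling

Consensus: per site, N if depth < 10 or > 100; N if the plurality call is a
deletion; otherwise the majority base, ties → N; the sequence is forced to
reference length by 3′ N-padding/truncation.  This majority-call rule is a
documented dialect of the original pileup-consensus tooling (the thresholds
are the published ones; the tie and deletion handling are ours).
Classification uses strict inequalities (breadth > 0.90, mean depth > 1);
both thresholds are configurable.  Mean depth averages over *all* reference
positions including zeros.  Insertions relative to the reference are
ignored throughout.  All on-disk coordinates are 1-based inclusive;
in-memory arrays are 0-based.

## 3. Phylogenetics

* **Alignment.** Consensus sequences are reference-anchored, so the MSA is
  a column stack; every column with an N in any strain is removed (the rule
  treats deletion and ambiguity alike).  Surviving columns keep reference
  coordinates and a site-class label.
* **Distances.** p-distance or Jukes–Cantor (error at p ≥ 3/4).
* **NJ.** Saitou–Nei with the Q-criterion; ties broken by the lowest
  label-order index pair (deterministic); negative branch-length estimates
  clamped to zero.  Cross-checked against scikit-bio's NJ in the tests.
* **Support.** Column-resampling bootstrap over NJ rebuilds; support =
  bipartition frequency on the full-data tree.  This replaces the original
  rapid-bootstrap ML procedure (out of scope) with a like-for-like
  resampling scheme.
* **Rooting.** Midpoint of the longest tip-to-tip path; diameter ties
  broken by the lexicographically smallest tip pair; zero-diameter trees
  root at the seed node with a warning.
* **Likelihood.** Felsenstein pruning, HKY+Γ per site class with a
  per-class rate multiplier on branch lengths; discrete Γ uses Yang-style
  equal-probability categories represented by category means (4 by
  default).  Site patterns are compressed per class; partials are rescaled
  every 8th internal node to avoid underflow.  The GTR model of the
  original ML search is deliberately narrowed to HKY+Γ everywhere, matching
  the Bayesian partition models.
* **Branch-length ML.** L-BFGS-B over all branch lengths (bounds [0, 20]),
  guarded so the returned tree is never worse than the input lengths.

## 4. Congruence test

The published test samples topologies in an MCMC; here (as specified) it is
an ML dialect: the two-topology model fits each partition's own NJ topology
with free branch lengths, the single-topology model fits the concatenated
data's NJ topology with shared branch lengths and a free symbiont/mtDNA
rate multiplier.  Each partition gets empirical base frequencies and its
own kappa and Γ shape.  Parameter counts: single = branches + 2×(kappa + α
+ 3 frequencies) + 1 multiplier; two = 2×branches + 2×(kappa + α + 3
frequencies).  All continuous parameters are optimised on the log scale
(branch lengths included) with the rate multiplier seeded by the
partitions' relative mean p-distance — without this the joint optimiser can
stall with the multiplier at 1.  AIC = 2k − 2lnL; log10 BF =
(lnML_single − lnML_two)/ln 10 with lnML from the harmonic-mean estimator
(log-sum-exp stabilised).  Plain AIC is used; the "AIC-through-MCMC"
variant of the original analysis uses an unrecoverable penalty and is not
implemented.

## 5. Dating and phylogeography

Fixed rooted topology; tips at age 0.  MCMC state: internal-node ages,
per-class rates, kappa and Γ shape per class, coalescent effective size.
Priors: calibrated class rate ln N(−16.59613, 1/3) (the implied central
rate exp(μ) = 6.2×10⁻⁸ is the distribution's median; this interpretation
reproduces the quoted rate exactly); uncalibrated rates log-uniform on
[10⁻¹³, 10⁻⁵]; kappa ~ LogNormal(ln 2, 1.25); α ~ LogNormal(0, 1);
N ~ 1/N on [10, 10⁹]; ages ~ constant-size Kingman coalescent given N.

Moves per sweep: uniform node-slides between each node's child/parent ages
(symmetric), a multiplicative root-age move, log-scale random walks on every
scalar, and a **joint scale move** (all ages ×f, all rates ÷f, N ×f) whose
likelihood is exactly invariant — it targets the age/rate ridge that is the
chain's slow mode and cuts the autocorrelation time of the calibrated rate
from ~70 sweeps to ~3.  Defaults: 4,000 sweeps, 10% burn-in, thin 2; the
pipeline and tests use shorter documented chains.  Empty site classes are
dropped with a warning.  Ages are reported in generations and in years
(÷10).  Acceptance-rate bookkeeping is attached to the sample frame.

Phylogeography is a separate ML fit on the dated tree: six free
off-diagonal log-rates of a 3-state non-reversible generator
(bounded in [e⁻²⁵, e⁸] to keep degenerate data sane), root state drawn from
the fitted chain's stationary distribution (with a uniform root the ML
degenerates on single-location data), marginal ancestral states by the
up-down algorithm.  Internal nodes are keyed `mrca(a,b)` by the smallest
tip labels of two child subtrees, which identifies each node uniquely.

## 6. Scaled-down experiment design

Two acceptance experiments need more signal than the default scaled-down
sizes provide, and the enlargement is part of their stated design, chosen
for identifiability, not tuned to outcomes:

* **Rate recovery** (mt codon 3 = 100× symbiont rates) keeps the 10 kb / 3
  kb class sizes but deepens the coalescent to N = 500,000.  At the default
  depth the 10 kb symbiont alignment carries < 1 expected mutation and the
  rate ratio is unidentifiable; at N = 500,000 it carries ≈ 20, the same
  order per class as the real 1.2 Mb alignment on the real tree.  The
  recovered ratio is summarised per replicate as the posterior median of
  rate_mt3 / (length-weighted mean symbiont rate) — the length weighting
  keeps a zero-mutation class from collapsing the summary.
* **Congruence power** uses a 300 kb symbiont partition (the real 1.2 Mb
  scaled by 4) and a fully infected sample.  At 10 kb the partition is
  nearly invariant and carries no topology information for either model;
  and when few strains per location are infected, a within-location
  permutation is frequently near-identity (or swaps symbionts that differ
  at no site), so the negative control would test nothing — the real
  randomization operated on ~90 infected strains in well-populated
  locations, which the fully infected scaled-down sample mirrors.

## 7. Population genetics

θ_W is based on the total number of mutations η (a k-allele site counts
k−1) as in the original analysis; Tajima's D uses S in its variance
constants (its derivation requires S).  The conditional null simulates a
coalescent genealogy and places exactly S mutations multinomially with
probability proportional to branch length; the default p-value is the lower
tail (excess of rare variants).  The conditional mean of D is *not* zero:
at n = 91, S = 115 it is ≈ −0.11 (confirmed against an independent
genealogy simulator), a property of the statistic's normalisation, so exact
neutrality tests should use the simulated distribution, not a N(0,1)
approximation.  Kst uses patristic distances (the specified variant);
the cross-population mean weights populations by sample size; the
permutation p-value carries the +1 correction.  The ambiguous "binomial
test" between the two panels is not implemented; the exact
Clopper–Pearson interval machinery is.

## 8. Marker genotyping

IS5 junction detection is alignment-free: a read supports an allelic state
if some gap-free placement on that state's haplotype has ≤ 2 mismatches and
crosses a junction with ≥ 20 bp on each side (both orientations tried).
Present/absent requires ≥ 3 junction reads on one side and < 3 on the
other; reads ≤ 75 bp, conflicts, and silence are indeterminate.  The
genotype truth table is: (present, absent) → wMel-like, (absent, present) →
wMelCS-like, (absent, absent) → wMel3, else indeterminate.  Diagnostic
mtDNA SNPs are read at mtDNA positions 2160/2187 (T/C → wMelCS-type, C/T →
wMel-type); the anchoring of these marker-study coordinates onto the mtDNA
reference is recorded here as an assumption and both positions are
arguments.  The COI window is mtDNA-local 1657–2211 (555 bp), derived from
the gene's scaffold anchors.  Haplotype matching ignores N positions in the
query; multi-matches are flagged ambiguous; novel haplotypes are numbered
from 20 in input order and appended to the working table.

## 9. Known limitations

* The congruence dialect plugs in NJ topologies rather than integrating
  over topologies; with very weak signal both models fit noise and the AIC
  comparison loses power (hence §6).
* The dating sampler is single-chain per call; convergence monitoring
  beyond acceptance rates and the tests' prior-recovery checks is the
  caller's job (run two seeds and compare).
* The harmonic-mean marginal-likelihood estimator is high-variance; it is
  provided because the original analysis used it, with its arithmetic
  tested, but no acceptance claim rests on its statistical quality.
* BAM/FASTQ ingestion is out of scope: inputs are pre-computed depth and
  base-count tables (what standard coverage tools emit).
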