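# Methods

This note documents the models behind `lowcovpop`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical conventions that matter for reproducing results.

## Low-coverage assignment model

A specimen is represented by per-site allele observations (one row per
sequencing read overlapping a diagnostic SNP). For a binary contrast with
per-SNP frequencies p₁, p₂ of `allele_a` in the two reference groups, an
observation of `allele_a` contributes ln(p₁ᶜ/p₂ᶜ) to the summed log-odds Λ,
and an observation of `allele_b` contributes ln((1−p₁)ᶜ/(1−p₂)ᶜ), where the
superscript c denotes clamping into [clamp, 1−clamp]. The score
s = 1/(1+e^(−Λ)) is the posterior probability of group 1 under equal priors
and independent observations. Properties that the test suite verifies
exactly: swapping groups maps s → 1−s; observations with equal clamped
frequencies leave s unchanged; the log-domain computation agrees with a
naive product-space posterior to 1e-12.

Choices:

* **Frequency clamp 0.001** — fixed differences otherwise contribute
  infinite weights; 0.001 keeps a single fixed-difference observation worth
  ln(999) ≈ 6.9 log-odds, decisive but finite, and makes the score robust to
  a single sequencing error or damage artifact at a fixed site.
* **Duplicate reads at one site are independent observations.** At ≤ 2.5×
  coverage duplicate hits on one SNP are rare; the sensitivity protocol
  quantifies any inflation this causes.
* **Damage-confusable sites are not excluded.** C→T/G→A damage simply adds
  noise at such sites; the generator produces them at their natural rate so
  the tests measure assignment accuracy under that noise.

**Classification.** score ≥ τ_high → group 1, score ≤ τ_low → group 2,
between the thresholds → "mid" when a middle class is allowed (the salinity
test; defaults τ = 0.3/0.7), otherwise the nearer side with exact ties going
to group 1. Binary tests use the 0.5/0.5 split. Zero informative sites is
always `no_call`. The τ defaults are package choices: the mid band is a
score region, not a third source population, so no planted truth exists to
calibrate it against; 0.3/0.7 makes "mid" mean "posterior odds within
roughly 2.3:1 either way".

**Hierarchy.** Season is tested first; the inversion test runs only for
autumn calls (only autumn spawners segregate informatively at the
inversion); salinity runs last with the mid band. Each test is gated on the
specimen's genome-wide aligned read count (defaults 50,000 for season and
inversion, 60,000 for salinity — the depths at which those tests reach
reliable classification). A test gated out for insufficient reads
contributes "NA" to the composite label but does not void it; a test that
ran and found no informative site voids the composite, as does an
unresolved season (the hierarchy cannot start).

**Site aggregation** reports count/n and a percentage rounded to one
decimal, with every sampled specimen in the denominator, including those
whose composite is incomplete.

## Sensitivity protocol

The read-depth grid is 500…10,000 in steps of 500, then 20,000…100,000 in
steps of 10,000 (29 depths; the coarse arm starts at 20,000 so 10,000 is not
duplicated). For each depth g, individual i and replicate b (20 replicates),
the individual's read set is binomially thinned to g total reads with a seed
derived by hashing (master seed, g, i, b) — replicates are independent yet
the whole curve is bit-reproducible. The minimum required depth is the
smallest grid value at which all replicates of all individuals are correct
*and which stays perfect at every larger depth*; the stability clause is a
package choice, made because the minimum is used as a gate for real
specimens and an isolated lucky depth should not qualify. A `no_call`
replicate counts as incorrect.

## Read model

Total aligned reads, not panel hits, are the unit of the grid, so the
generator models a genome: a read set of size R hits a panel of S sites with
footprint S × read-length; hits are Binomial(R, footprint/genome). Defaults:
genome 726 Mb (herring-scale), read length 60 bp (typical of degraded
libraries; used only for the footprint). Each hit lands on a uniform panel
site, observes one of the individual's two alleles, is replaced by a
uniformly chosen different base with probability `error_rate`, then suffers
C→T (or G→A) substitution with probability `damage_rate`. Damage is modeled
per observation rather than as a position-within-read decay curve because
the assignment arithmetic only ever sees per-site allele counts. The
fraction of reads overlapping a panel in real alignments is not knowable
from panel size alone; the footprint model is this package's construction
and is stated as such.

What the generator does **not** emulate: alignment and mapping error,
reference bias, contamination, within-read damage profiles, indels, linked
selection. Passing tests therefore demonstrate the statistical machinery
under its stated model, not robustness to those artifacts.

## Synthetic contrasts

`simulate_divergent_populations` draws per-SNP differentials d from a
configurable distribution, places the frequency pair (u+d, u) with
u ~ Uniform(0, 1−d), and randomizes which population is high. The assignment
and sensitivity harnesses use d ~ Uniform(0.9, 1.0) — "inversion-like":
diagnostic SNPs tagging a non-recombining inversion haplotype, or selected
for a strong phenotype contrast, behave as near-fixed differences. Weaker
panels are exercised in unit tests (d down to 0) but are not the reference
condition. Genotypes are Hardy–Weinberg draws at the population frequency;
a chi-square goodness-of-fit check at n = 10,000 is part of the suite.

## Wright–Fisher simulator

Diploid, neutral, random mating with selfing, standing variation only:
loci start at frequencies Uniform(0.05, 0.95) on independent backgrounds and
no mutation enters afterwards (LD-decay estimation uses segregating sites
only; fixed loci simply drop out). Recombination follows a constant rate
(default 2.54 cM/Mb, the herring population-wide rate) via Haldane's map;
crossover states along a gamete form a Markov chain resolved with a parity
scan, so the per-generation cost is O(population × loci). The
`ne_trajectory` is a list of (generation-before-sampling, Ne) change points;
the simulated span is the largest listed generation, so a constant-Ne run of
G generations is written `[(0, Ne), (G, Ne)]`. The suite verifies the
two-locus equilibrium E[r²] against 1/(1+4Nc) + 1/n by Monte Carlo, and
recovers constant and declining Ne(t) truths through the estimator below.

## Window statistics

* **π** per fixed window (default 100 kb, 0-based half-open BED windows):
  per site, the fraction of haplotype pairs differing — n_ref·n_alt/C(n,2),
  which depends only on allele counts and is therefore phase-free — summed
  over sites and divided by the window width. Monomorphic and absent sites
  contribute zero.
* **Kinship**: the robust estimator
  φ = (N_het,het − 2·N_opp_hom)/(N_het(i)+N_het(j)) over jointly called
  sites; φ(i,i) = 0.5 exactly, unrelated ≈ 0, parent–offspring ≈ 0.25
  (verified by pedigree simulation).
* **ROH**: sliding windows of 50 SNPs tolerating ≤ 1 heterozygote; windows
  sharing SNPs merge (two flagged windows overlap whenever their start
  indices differ by less than the window size); merged runs shorter than
  50 kb are dropped; segments never span chromosomes; missing calls count as
  non-heterozygous. These caller parameters are package defaults, sized so
  that at 2.54 cM/Mb the detectable tract lengths (≳ 50 kb ≈ 0.13 cM)
  correspond to coalescent ages within the last few hundred generations —
  the regime of interest. The planted-tract test requires a 200-kb tract in
  a 30%-heterozygous background to be recovered with boundary error under
  one window span in ≥ 45/50 replicates.
* **ROH dating**: g = 100/(2L) generations for a segment of L cM (exact
  inverse of L = 100/(2g)); years = g × generation time. Year bins are
  half-open [older, younger): a segment dated exactly on a shared edge falls
  in the younger bin. Defaults: 650–400 and 400–200 years before present.

## LD-decay Ne estimator

r² is the squared Pearson correlation of genotype dosages (phase-free;
appropriate for unphased data), computed for all within-chromosome pairs
with recombination fraction c ≤ 0.25, c being the inverse-Haldane transform
of the cM distance. Pairs are binned into 20 log-spaced bins over
[5×10⁻⁴, 0.25]; per bin, Sved's relation is inverted:

  N̂e(c̄) = (1/(r̄² − 1/n) − 1)/(4c̄),  reported at t = 1/(2c̄) generations,

with n = 2 × diploids. Bins with < 30 pairs, or with r̄² at or below the 1/n
sampling floor, are dropped with warnings. Bootstrap: each of 40 iterations
(default; desk-scale examples use fewer) samples 2,000 SNPs per chromosome
without replacement (50,000 retained as the full-data configuration value);
per-bin point estimates are geometric means across iterations with 2.5/97.5
percentile intervals. Geometric-mean aggregation is permutation-invariant
and, for the roughly log-normal spread of per-iteration Ne estimates, less
sensitive to occasional blow-ups near the sampling floor than the
arithmetic mean.

This is deliberately a transparent, classical estimator that shares the
aggregation and calibration conventions of published LD-based demography
software, not a re-implementation of any particular program's internals
(bin weighting and overlapping-generation corrections differ between tools
and are not public in all of them). Its validity here rests on parameter
recovery: on Wright–Fisher truth with constant Ne = 200 the median recovered
Ne across 20 replicate simulations falls within a factor 1.5 of truth in the
10–100-generation window, and a planted bottleneck is recovered in
direction. With exact Sved-form inputs the inversion is algebraically exact
(1e-9 relative error). Known bias: at large t the finite simulated history
and initial linkage equilibrium depress r² toward the 1/n floor, inflating
and destabilising the oldest bins — which is why calibration flags points
beyond 200 generations as low-confidence rather than dropping them.

**Calibration** is a pure unit transform: Ne values are untouched; the
trim_recent = 4 most recent generations are removed (LD-based estimators
produce artifactual near-zero bottlenecks there at small sample sizes);
years-before-sampling = t × generation time with minimum generation times
of 3 y (autumn spawners) and 2 y (spring spawners); the present is anchored
at the sampling year; the trusted horizon of 200 generations maps to
600/400 years for the two ecotypes.

## Problem sizes and determinism

Desk-scale defaults keep every stage fast while preserving the protocol
shape: the full sensitivity run (8 individuals × 29 depths × 20 replicates
= 4,640 assignments) completes in ~15 s; the 20-replicate Wright–Fisher
recovery study in ~1 min; the end-to-end demo in ~15 s. All stochastic
operations take explicit integer seeds; child streams derive via
`numpy.random.SeedSequence` spawn keys from (seed, structural indices), so
every result in the test suite, the demo manifest and the acceptance script
is bit-reproducible given its seed.

## Known limitations

* Assignment assumes independent observations and exactly two source
  groups per test; no contamination or genotype-likelihood modeling with
  base qualities.
* The read model's panel-hit probability is an idealisation (uniform
  mappability, no duplicate-read structure).
* The Ne estimator assumes a single unstructured population; admixture or
  substructure biases LD upward and the inferred Ne downward — a documented
  caveat of all LD-based demography, not modeled here.
* ROH calling at realistic SNP densities needs several individuals and
  long chromosomes; the defaults target the synthetic regime and should be
  re-tuned for real variant densities.
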