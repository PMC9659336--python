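# lowcovpop

Population assignment from ultra-low-coverage sequencing data and
recent-demography inference from linkage disequilibrium, for structured fish
populations — with synthetic-truth generators that let every stage of the
pipeline be validated end to end.

## The problem

Archaeological fish bone can yield usable DNA at coverages as low as
0.002–2.5×, far too little for genotype calling, yet enough to place a
specimen within a structured species if one scores its few reads against
panels of diagnostic SNPs. Atlantic/Baltic herring is the motivating system:
its stocks separate by spawning season (autumn vs. spring), by a chromosomal
inversion haplotype that distinguishes Atlantic from Baltic autumn spawners,
and by alleles associated with salinity adaptation. Combining three such
binary tests hierarchically turns a handful of read observations into a
composite stock label, and modern whole-genome data from the same stocks
supports reconstruction of their recent effective population sizes
N<sub>e</sub>(t) from the decay of linkage disequilibrium (LD) with
recombination distance.

`lowcovpop` implements that full inference chain as a tested, reusable
library plus CLI:

1. **synthetic truth** — divergent population pairs with known per-SNP
   allele-frequency differentials, Hardy–Weinberg diploid genotypes, a
   forward Wright–Fisher simulator with recombination under a
   piecewise-constant N<sub>e</sub>(t), and a low-coverage read model with
   sequencing error and post-mortem C→T / G→A damage;
2. **panel construction** — select SNPs whose between-group differential
   |Δp| passes a threshold, or import published diagnostic loci;
3. **low-coverage assignment** — each observed allele contributes the
   log-likelihood ratio ln(p₁ᶜ/p₂ᶜ) of its clamped group frequencies; the
   logistic transform of the sum is the posterior weight of group 1 under
   equal priors; three tests combine hierarchically (season → inversion for
   autumn fish → salinity with a "mid" band);
4. **sensitivity protocol** — downsample each test individual's reads to a
   grid of 500…10,000 (step 500) then 20,000…100,000 (step 10,000) total
   reads, 20 bootstrap replicates each, and report the smallest depth from
   which every replicate of every individual classifies correctly;
5. **window statistics** — nucleotide diversity π in 100-kb windows, robust
   pairwise kinship φ = (N_het,het − 2·N_opp_hom)/(N_het(i)+N_het(j)), and
   runs of homozygosity (ROH) whose genetic length L (cM) dates the
   underlying coalescent event via g = 100/(2L) generations;
6. **LD demography** — bin locus pairs by recombination fraction c, invert
   Sved's relation E[r²] ≈ 1/(1 + 4N<sub>e</sub>c) + 1/n to
   N<sub>e</sub>(c̄) reported at t = 1/(2c̄) generations, aggregate 40
   bootstrap iterations by geometric mean, and calibrate to calendar years
   with per-ecotype generation times (3 y autumn, 2 y spring spawners),
   trimming the four most recent generations and flagging points beyond the
   200-generation trusted horizon.

## Worked example

```python
import lowcovpop as lcp

# inversion-like contrast: 4,500 near-fixed diagnostic SNPs
truth = lcp.simulate_divergent_populations(
    4_500, ("uniform", 0.9, 1.0), seed=7, labels=("atlantic", "baltic"))
ref = lcp.sample_genotypes(truth, 100, seed=8)
panel = lcp.select_divergent_snps(ref, ("atlantic", "baltic"), contrast="inversion")

# an 80,000-read "ancient" specimen from the baltic side, with 1% sequencing
# error and 5% deamination
geno = lcp.sample_genotypes(truth, 1, seed=9, prefix="specimen")
obs = lcp.simulate_reads(geno, 1, total_reads=80_000,
                         error_rate=0.01, damage_rate=0.05, seed=10)
res = lcp.classify(lcp.score_assignment(obs, panel))
print(obs.n_records, res.score, res.call)
```

prints `39 0.0000 baltic`: of 80,000 genome-wide reads only 39 hit panel
sites, yet the posterior weight of the Atlantic side is ≈ 0 and the specimen
is confidently assigned Baltic.

Demography, statsmodels-style (model object → fitted results object):

```python
from lowcovpop.wright_fisher import PopulationModel, simulate_wright_fisher

model = PopulationModel(ne_trajectory=[(0, 150), (80, 600), (280, 600)],
                        n_loci=500, seed=11)   # decline 600 -> 150 at gen 80
wf = simulate_wright_fisher(model, 60)
traj = lcp.LDNe(wf).fit(n_boot=8, snps_per_chromosome=400, seed=12)
print(traj.calibrate(generation_time_years=3.0, sampling_year=2010).summary())
```

The summary table reports, per recombination-fraction bin, the geometric-mean
N<sub>e</sub> with bootstrap percentiles and its calendar placement; for this
truth it recovers ≈ 115–190 in the recent (trusted) range against a planted
recent N<sub>e</sub> = 150, rising toward the planted ancestral 600 at older
time points:

```
       c  t_generations    ne    lo    hi  ...  years_before_sampling  calendar_year  low_confidence
  0.1163            4.3 116.7 112.4 120.2  ...                   12.9           1997           False
 0.04608          10.85 119.8 115.8 125.2  ...                  32.55           1977           False
0.005178          96.56 190.9 170.1   210  ...                  289.7           1720           False
0.002809            178 400.5 333.8 494.7  ...                  534.1           1476           False
```

The same stages are scriptable from a shell (`lowcovpop simulate|panel|
assign|sensitivity|stats|demography`), and `lowcovpop demo --seed 5 --out
demo_out` runs the whole chain — panels, sensitivity curve, 24 synthetic
specimens across three "sites", per-site aggregation, π/kinship/ROH and a
calibrated N<sub>e</sub> trajectory — writing a manifest with per-output
checksums.

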