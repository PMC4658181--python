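# mhcrq

Individual-based simulation of MHC–pathogen coevolution, separating the two
classical forms of pathogen-driven balancing selection on vertebrate MHC
genes — **heterozygote advantage** and the **Red Queen process** (negative
frequency-dependent selection emerging from host–pathogen arms races) — and
measuring their consequences for polymorphism, positive selection on novel
alleles, and the persistence of allelic lineages.

The package is for population geneticists and evolutionary immunologists who
want a forward-time, mechanistic null model of MHC evolution in which the
form and strength of selection *emerge* from antigen recognition rather than
being imposed as a fitness function.

## Model

Hosts are diploid at a single MHC locus and reproduce sexually in a
population of constant size *N*. Each MHC allele is a 16-bit string standing
in for the antigen-binding sites. Hosts coevolve with *S* = 50 haploid,
asexual pathogen species (population size *N* each, ten pathogen generations
per host generation). Each pathogen individual expresses 20 antigens, also
16-bit strings. An MHC molecule *presents* an antigen when at least 7
contiguous aligned bits match; presenting any antigen of a pathogen blocks
that infection, and extra recognized antigens confer no further benefit. A
random molecule therefore presents a random antigen with probability
2811/65536 ≈ 0.043, and each pathogen offers 10 × 20 = 200 recognizable
7-bit motifs.

Every pathogen generation, each host is attacked by one randomly drawn
individual of each species. Host fitness is the proportion of the
*S* × 10 encounters presented, with resistance either

- **dominant** — one recognizing allele gives full credit (heterozygote
  advantage), or
- **additive** — 0.5 credit per recognizing allele copy (no heterozygote
  advantage, ploidy retained).

Pathogens reproduce either proportionally to the number of hosts they
infected (Red Queen selection) or by uniform resampling (pathogen drift).
The four scenarios are HA+RQ (dominant, selection), HA (dominant, drift),
RQ (additive, selection) and Drift (no pathogens). Host alleles mutate
per site at *p*ₜ = 6.25·10⁻⁷ per generation (≈ 10⁻⁵ per molecule); pathogen
antigens mutate at 2·10⁻⁴, 10⁻³ or 5·10⁻³ per antigen per pathogen
generation. Every allele origination is recorded with its parent allele and
birth generation, so allele genealogies and pairwise coalescence times can
be computed for the full population.

## Worked example

```python
from mhcrq import ScenarioConfig, run_simulation, recruitment_probability

config = ScenarioConfig(
    scenario="RQ", n_hosts=500, mu_pathogen=5e-3,
    burn_in=250, recorded_generations=250,
    host_site_mutation_rate=1e-5, seed=505,
)
result = run_simulation(config)
s = result.summaries
print(f"mean distinct alleles:   {s['n_distinct_alleles'].mean():.1f}")
print(f"mean heterozygosity:     {s['observed_heterozygosity'].mean():.3f}")
print(f"mean host fitness:       {s['mean_fitness'].mean():.3f}")
print(f"recruitment probability: {recruitment_probability(result.fates):.2f}")
```

prints

```
mean distinct alleles:   14.1
mean heterozygosity:     0.699
mean host fitness:       0.053
recruitment probability: 0.89
```

Under the additive Red Queen at a high pathogen mutation rate, pathogens
track the common host alleles closely (host fitness ~0.05), which keeps many
alleles circulating (~14 at *N* = 500) and strongly favours novel mutants:
nearly nine out of ten new alleles survive at least 10 host generations,
versus ~0.2 under heterozygote advantage at the same settings.

The same run is available from the shell:

```sh
mhcrq run --scenario RQ --host-n 500 --pathogen-mu 5e-3 --host-mu 1e-5 \
          --burn-in 250 --generations 250 --seed 505 --out runs/rq
mhcrq stats --run runs/rq
mhcrq coalesce --run runs/rq --window 400
```

`mhcrq plan --preset desk --out runs/desk` runs a scaled-down scenario grid
with replicate means and bootstrap 95% confidence intervals;
`--preset polymorphism` and `--preset coalescence` mirror the full-scale
population-size sweep and the long genealogy runs.

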