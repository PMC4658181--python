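# Methods

## Model structure

The simulator is a forward-time, individual-based model of a single diploid
MHC locus coevolving with a community of haploid pathogen species. Nothing
about the shape or strength of selection is imposed; fitness emerges from
bit-string antigen recognition.

**Recognition.** MHC molecules and antigens are binary strings of length
*L* = 16 (each bit abstracts residues of the antigen-binding sites). A
molecule presents an antigen when the two strings agree at ≥ *k* = 7
contiguous aligned positions. Aligned positions of two independent uniform
strings agree independently with probability 1/2, so the presentation
probability of a random pair is the fraction of 16-bit agreement-indicator
strings containing a run of ≥ 7 ones: 2811/65536 ≈ 0.043. This is computed
both by the run-avoidance recurrence f(n) = Σ_{j=1..k} f(n−j) and by full
enumeration; the two are asserted equal for all geometries up to L = 16.
Matching polarity is *equality* of bits. A complementarity convention would
give identical statistics (complementing one string is a measure-preserving
bijection), so the choice is conventional; it is fixed here and documented.
Runs are counted in aligned position with no offsets, which is what makes an
antigen expose exactly L − k + 1 = 10 windows, or 200 motifs over a
20-antigen pathogen.

**Populations and the generation cycle.** N hosts; S = 50 pathogen species
of N individuals each; 10 pathogen generations per host generation. Each
pathogen generation, every host is attacked by one uniformly drawn
individual of each species (with replacement). Host fitness is the
proportion of encounters presented, accumulated over all 10 pathogen
generations (S × 10 = 500 encounters per host generation). The alternative
reading — fitness from the final pathogen generation only — is available as
`fitness_window="last"`; the accumulated window is the default because hosts
are attacked in every pathogen generation and fitness is defined by the
number of pathogens recognized.

Resistance is **dominant** (credit 1 if either allele presents) in the HA
and HA+RQ scenarios and **additive** (credit 0.5 per presenting allele copy,
so a presenting homozygote still earns 1) in RQ. Pathogen reproduction is
multinomial, proportional to the number of hosts each individual infected
(encounters not presented), independently within species; in the HA scenario
it is uniform resampling instead, which removes the pathogens' ability to
adapt while keeping their standing variation drifting. A species in which no
individual infected any host falls back to uniform resampling (logged).
Host reproduction draws, for each of N offspring, two *distinct* parents
with probability proportional to fitness (uniform under Drift or when all
fitnesses are zero); each parent transmits one of its two alleles with
probability 1/2. If only one host has positive fitness, the co-parent is
drawn uniformly, since proportional sampling of a distinct second parent
would be undefined.

**Mutation.** Host: each transmitted allele copy flips each bit
independently at p_t = 6.25·10⁻⁷ per site per host generation, i.e.
1 − (1 − p_t)¹⁶ ≈ 10⁻⁵ per molecule. A macro-mutation mode replaces the
whole string with a fresh uniform string at the equivalent per-molecule
rate. Pathogen: each antigen mutates with probability μ ∈ {2·10⁻⁴, 10⁻³,
5·10⁻³} per pathogen generation and a mutating antigen flips exactly one
uniformly chosen bit. The rates are quoted per antigen, so the per-antigen
Bernoulli trial is the primary model; a per-bit variant (μ/16 per bit) is
available as `pathogen_mutation_model="per_bit"`. Pathogens mutate in every
scenario that has pathogens, including HA — this keeps standing pathogen
variation comparable between HA and the selection scenarios.

**Identity and genealogy.** Every mutation (and every founder copy) creates
an origination record: unique id, parent id, birth generation, sequence.
Genealogy and mutant-fate statistics operate on origination ids (a
back-mutation recreating an existing sequence is a new lineage node);
polymorphism and heterozygosity statistics count distinct sequences.
Initialization registers all 2N founder copies as independent uniform
sequences — maximal polymorphism, decaying to the selection-determined
level during burn-in.

## Summary statistics

- **Richness / heterozygosity** per generation: distinct sequences among the
  2N copies; observed heterozygosity is the fraction of hosts whose two
  sequences differ (expected heterozygosity 1 − Σp² is also emitted).
- **Heterozygote advantage**: ratio of mean realized fitness of heterozygous
  to homozygous hosts. Realized fitness over the 500 encounters of a host
  generation is used as the recognition measure; it estimates the same
  expectation as scoring against the whole pathogen population but is
  already accumulated by the engine, and it is the fitness-relevant measure
  under both dominance modes.
- **Frequency dependence**: at snapshot generations (default: the end of
  burn-in; configurable as a tuple, and tests pool several snapshots), each
  distinct allele contributes (frequency, fraction of all S × N pathogen
  individuals presented). The trend is an OLS slope with a two-sided t-test.
  Recognition ability is measured against all pathogen individuals, not
  just realized attackers — it is an expected proportion.
- **Mutant fates**: for every origination in the recorded window, lifespan
  (generations with ≥ 1 copy), recruitment (lifespan ≥ 10; the cutoff is
  configurable), censoring for undecided fates at the end of the run, the
  frequency trajectory over the first 25 generations, and the
  **presentation spectrum at birth** — pathogens recognized by the mutant
  divided by the frequency-weighted mean recognized by resident alleles
  (1 = parity). The spectrum is scored against the whole pathogen
  population (lower variance than realized encounters).
- **Coalescence**: the registry forms a parent-pointer forest. Two lineages
  coalesce at the *divergence event* — the birth of the younger branch node
  immediately below their most recent shared ancestor; for a parent–child
  pair this is the child's birth (the lineages were one allele until then).
  Measuring to the shared ancestor's own birth instead is available via the
  chain structure but divergence-event timing is the default, matching the
  usual semantics of allelic genealogies. All unordered pairs of the 2N
  final allele copies are evaluated by weighting distinct-id pairs with
  copy-count products (within-id pairs coalesce at time 0); this equals the
  naive all-copy-pairs loop exactly and is tested against it. Pairs whose
  divergence predates the scanning window, or which descend from different
  founders, count as "no common ancestor within the window". The
  **oldest-lineage age** (generations since the birth of the oldest
  origination still segregating) is reported alongside: it upper-bounds all
  pairwise coalescence times and remains well-defined when a population is
  nearly monomorphic.

## Numerical implementation

Sequences are bit-packed integers; single-antigen presentation is a lookup
table over XOR patterns (2^L booleans), and the encounter loop is a small
numba kernel that is deterministic given the attacker indices — its output
is asserted identical to the plain numpy implementation, which in turn is
asserted against the scalar per-encounter operations. All randomness flows
from one `numpy.random.Generator` seeded by (seed, replicate_index); runs
are bitwise reproducible. Per-antigen mutation draws a Binomial count and a
uniform subset of positions, which realizes the exact i.i.d. Bernoulli law
without generating a random number per antigen. Replicate seeds within an
experiment plan derive from `SeedSequence([base_seed, cell_index])`.

## Study conditions and reduced-scale testing

The full-scale experiment grid (N up to 5000, 2000 + 6000 host generations,
10 replicates; genealogy runs at N = 2500 for 40 000–250 000 generations)
is available through the `polymorphism` and `coalescence` presets and is
sized for cluster time, not a laptop. The test suite exercises the scenario
contrasts on a reduced grid chosen once, before freezing the tests:

- N = 500, burn-in 250 + 250 recorded generations, 3 replicates, for the
  heterozygote-advantage ratio, frequency-dependence slopes (four pooled
  snapshots), recruitment contrasts, and the high-rate polymorphism
  ordering;
- N = 100, burn-in 300 + 500 recorded, 5 replicates, for the low-rate
  polymorphism ordering, the drift reference, and lineage persistence;
- host site mutation rate raised to 10⁻⁵ (≈ 1.6·10⁻⁴ per molecule) so that
  enough origination events accrue per replicate for recruitment and
  genealogy statistics at these population sizes. The host rate only sets
  the mutant supply; the model's contrasts are driven by the pathogen rates,
  which stay at their standard values.

What the reduced grid does and does not show: the qualitative contrasts
(HA ratio ≈ 1.3–1.4 vs ≈ 1 under additive resistance; negative
frequency dependence, strong novel-allele recruitment and complete lineage
turnover only under Red Queen selection; richness orderings flipping
between low and high pathogen mutation rates; richness increasing with N)
are stable across replicates at these sizes. Quantities that are
intrinsically large-scale — the printed coalescence percentages at
N = 2500 over 40 000–250 000 generations, and the equivalence of HA with
drift recruitment at N > 1000 — are not reproduced at desk scale; at small
N, heterozygote advantage measurably exceeds drift recruitment (as at the
low-N end of the full-scale sweep), so the tests assert the weaker, scale-
robust statement that HA recruitment lies closer to drift than Red Queen
recruitment does. Near-monomorphic drift populations make pairwise
coalescence-time comparisons against drift degenerate (almost all pairs are
copies of one allele, coalescing at time 0), so the Red-Queen-faster-than-
neutral turnover trend is asserted on the oldest-lineage age, which the
pairwise times can never exceed.

## Known limitations

- Single MHC locus; no recombination, demography, overlapping generations,
  or virulence weighting of multiple infections.
- Pathogen species have host-sized populations; larger real pathogen
  populations are emulated by the mutation-rate range.
- The per-generation recognition summaries use realized encounter credits;
  snapshot statistics use the full pathogen population. Both estimate the
  same expectations but differ in sampling noise.
- Genealogy analysis holds the full origination history in memory; for
  multi-hundred-thousand-generation runs the registry grows linearly in the
  number of origination events (not in N), which is modest but not free.
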