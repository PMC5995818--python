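# Methods

`ldscape` characterizes linkage disequilibrium (LD) in diploid biallelic SNP
panels and derives the population-genetic quantities that are conventionally
read off an LD survey: the decay of r² and |D′| with physical distance, an
effective-population-size history, haplotype-block structure, inbreeding, and
genomic relatedness.  This note records the models implemented, the defaults
and why they hold, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Data model

Genotypes are allele-A dosages in {0, 1, 2} with a missing code, plus a
marker map (chromosome, identifier, 1-based bp position, strictly increasing
within chromosomes).  Allele A is the first allele encountered in a .ped
file or REF in a VCF; every reported statistic is invariant to that
orientation.  Missing genotypes are never imputed: each statistic uses
pairwise- or individual-complete observations, except the relationship
matrix, where a missing dosage contributes zero to the centered matrix (it
sits at its expectation — the convention of standard GRM software).

## Quality control

Filters run in a fixed order so audit counts are deterministic: non-autosomal
markers out first, then samples with call rate < 0.90, then — on statistics
recomputed from the retained samples — SNPs with call rate < 0.90, MAF
< 0.05, and Hardy–Weinberg χ² p < 0.1 (plain one-degree-of-freedom test, no
continuity correction; a monomorphic marker has no defined test and passes,
though the MAF filter removes it first anyway).  All three thresholds are
strict inequalities.  A SNP failing several filters is attributed to the
first in order.

## Two-locus LD from unphased genotypes

A marker pair reduces to a 3×3 joint dosage table.  Only double
heterozygotes are phase-ambiguous (AB/ab vs Ab/aB), so the likelihood
profiles over a single parameter, the haplotype frequency ρ_AB, on
[max(0, ρ_A+ρ_B−1), min(ρ_A, ρ_B)]; the margins are fixed by the observed
dosages.  The EM algorithm splits double heterozygotes between the two phase
resolutions in the E-step proportionally to ρ_AB·ρ_ab vs ρ_Ab·ρ_aB and
re-estimates ρ_AB from expected haplotype counts in the M-step, stopping when
the frequency moves less than 10⁻⁸ or after 1,000 iterations.

Two numerical points matter.  First, the profile likelihood is bimodal for
many tables (a coupling and a repulsion mode), and an EM started at linkage
equilibrium can converge to the minor mode; the implementation therefore runs
three deterministic starts (linkage equilibrium and near each admissible
boundary) and keeps the highest-likelihood iterate — still seed-free.
Second, the constrained MLE may lie exactly on a boundary, which EM only
approaches geometrically; both endpoints are evaluated in closed form and
win if strictly better.  A table consisting solely of double heterozygotes
carries no phase information; it is held at the linkage-equilibrium
stationary point, reported as D = 0, and flagged (`saddle`).  An exhaustive
test against a brute-force likelihood grid over every 3×3 table with n ≤ 8
(23,684 admissible tables) pins this behaviour.

From fitted frequencies: D = ρ_AB − ρ_A·ρ_B; D_max = min(ρ_A ρ_b, ρ_a ρ_B)
for D > 0 and min(ρ_A ρ_B, ρ_a ρ_b) in magnitude for D < 0; |D′| = |D|/D_max
with |D′| ≡ 0 when D = 0 (the case the D_max split leaves unassigned);
r² = D²/(ρ_A ρ_a ρ_B ρ_b).  The geometric-mean bound on D_max gives
r² ≤ |D′| always, a property-tested invariant.  Pairs whose
pairwise-complete subset is monomorphic (or has n < 2) are skipped and
counted.  LD is computed within chromosomes only, for adjacent pairs or all
pairs; summaries bin by distance downstream.

### |D′| confidence limits

The Gabriel block criterion consumes confidence limits on |D′|.  These are
likelihood-based: the genotype log-likelihood is evaluated on a grid of the
admissible ρ_AB interval (201 points in the batched block path, 2,001 in the
scalar API), normalized to unit mass, mapped to |D′|, and the equal-tail
0.90-mass interval is returned.  A flat weighting over the grid is used; no
asymptotic approximation is involved, so the limits behave sensibly at n as
small as 2 (where the interval correctly spans most of [0, 1]).

## LD summaries

Per-chromosome tables report unweighted means and sample SDs (n−1) of r² and
|D′| for adjacent and all pairs, with a genome row that pools all pairs
(pair-weighted) and, because conventions differ, also a chromosome-averaged
variant.  Distance bins are left-closed right-open in Mb.  LD categories
follow closed bounds: low r² ≤ 0.16, high r² ≥ 0.70, medium in between;
per-chromosome category frequencies sum to 100%.  The r²-vs-|D′| association
is the product-moment correlation, undefined (flagged) under zero variance.

## Inbreeding and relatedness

F_i = (O_i − E_i)/(L_i − E_i), with O_i the observed homozygous loci among
individual i's non-missing markers, L_i that marker count, and E_i the sum of
1 − 2p(1−p) over those same markers at in-sample allele frequencies — so
missingness cannot bias E.  F is negative exactly when O < E.  The base
population is the sample itself; with in-sample frequencies the mean F of an
unrelated panel is biased by only O(1/2n), well inside the 3-SE band the
tests use.

The relationship matrix is VanRaden method 1: G = ZZ′ / (2Σp(1−p)) with
Z = X − 2p, frequencies in-sample, monomorphic markers dropped (counted).
The distribution summary works on the strict upper triangle and classifies
pairs into half-sib-like [0.15, 0.375), full-sib-like [0.375, 0.75) and
duplicate-like ≥ 0.75 bins.

## Effective population size

At drift–recombination equilibrium E[r²] = 1/(1 + 4N_e c).  Inverting per
distance bin gives N_e(t) = (4c_t)⁻¹(E[r²|c_t]⁻¹ − α), where f(c_t) = c_t
(the identity is the only reading consistent with the forward relation) and
α ∈ {1, 2, 2.2} absorbs mutation: 1 for none (the simulator's regime), 2 or
2.2 at mutation–drift equilibrium.  The default is α = 2.2 for real panels;
every ground-truth recovery uses α = 1 because the generator is
mutation-free.  Physical distance maps to genetic distance at 1 cM/Mb by
default.  A sample-size correction (on by default) subtracts 1/n (n sampled
diploids) from the binned mean r², the standard adjustment for the sampling
inflation of unphased r̂²; it can be switched off to reproduce the raw
inversion.  Bins are 0.05 Mb wide from 0.05 to 4 Mb by default and need 50
pairs to be usable; a bin whose corrected r² (or N_e) is non-positive is
flagged unusable.  Each bin is dated t = 1/(2c) generations back; the table
carries the exact value (strictly monotone in c) and its half-up-rounded
integer, which can tie for neighbouring large-c bins.  Per-chromosome N_e is
the harmonic mean over that chromosome's usable bins; "recent" N_e is the
usable bin with the largest c.

Supporting closed forms: the inbreeding-LD relation
E(D²) = (1/15)p₀(1−p₀)q₀(1−q₀)[6(1−F) − 5(1−F)³ − (1−F)⁶], used to correlate
per-chromosome predicted D² (at the chromosome's mean allele frequency and
mean F) with observed mean D²; and the one-generation decay
E(D_t) = (1−c)(1 − 1/(2N_e))E(D_{t−1}).

## Haplotype blocks

Pairs within a 500-kb span (configurable) are classified from their |D′|
0.90-confidence limits: strong LD when lower ≥ 0.70 and upper ≥ 0.98; strong
recombination when upper < 0.90; otherwise uninformative (undefined-LD pairs
count as uninformative).  A candidate marker run is a block when it has at
least one informative pair and ≥ 95% of informative pairs are strong.
Non-overlapping blocks are chosen greedily, longest physical span first,
ties to the smaller start position — deterministic by construction.  Markers
under the MAF floor (default 0.05) are excluded before block finding.  The
density recommendation is round(genome size / mean within-block spacing),
both in Mb; genome size defaults to 2,615.52 Mb (ovine) and is configurable.

## The synthetic-data generator

`simulate_wright_fisher` is a forward, discrete-generation, neutral
Wright–Fisher population of N diploids: random mating with replacement, one
shared parent draw per generation across chromosomes, no mutation, no
selection, piecewise-constant N.  Recombination is a memoryless crossover
process, implemented as a per-interval two-state Markov switch with Haldane
fraction r = (1 − e^(−2d))/2 — probabilistically identical to drawing a
Poisson crossover count from the map length with uniform positions.  All
randomness flows through numpy's PCG64 `default_rng`, so a seed fully
determines the dataset on any platform.  Defaults emulate the structure of a
high-density ovine panel study: 26 autosomes, 1,470 markers per chromosome at
0.07-Mb spacing (~38k SNPs), 395 diploids sampled from a census of 400, and
initial allele-A frequencies uniform on [0.2, 0.8], which yields a mean MAF
of 0.35.

`make_pedigreed_sample` draws founders in linkage equilibrium and produces a
final generation by specified sire × dam matings (full sibs within a dam,
paternal half sibs across dams), recording the truth pedigree.
`plant_ld_block` draws within-block haplotypes from a restricted pool (two
complementary haplotypes ⇒ every within-block |D′| = 1) with independent
flanks.

What the generator does **not** emulate: mutation (so old, small-c bins of a
long run drift toward fixation and the α > 1 regimes cannot be ground-truth
tested), variable recombination rate and marker spacing, selection,
migration, genotyping error, and the ascertainment bias of commercial SNP
chips.  Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to real-data artefacts.

## Recovery study designs (problem sizes)

Chosen once as the smallest designs where the estimators are in their valid
regime:

* **Recent N_e** (N ∈ {50, 100, 200}): 12 chromosomes × 100 markers, marker
  spacing 25/N Mb so adjacent pairs sit at 4Nc = 1 and the assessed bins span
  4Nc ∈ [1, 2] — the regime where the Sved inversion is a faithful estimator
  (at 4Nc ≫ 1 it is biased upward); 2N generations, which equilibrates those
  bins (their look-back time is ≤ N generations) while most markers stay
  polymorphic despite the absence of mutation; min(100, N) diploids sampled;
  QC applied before LD as in the pipeline; α = 1, sample-size correction on.
  Tolerance ±30% of truth at fixed seeds.
* **Planted blocks**: 12 markers at 0.05-Mb spacing, one 4-marker
  complete-LD block (pool frequencies 0.6/0.4), n = 200; exact boundary
  recovery in ≥ 18/20 seeds.
* **F and G panels**: linkage-equilibrium founders, 500–800 markers,
  200 sampled individuals (40 half-sib pairs + 120 unrelated for the G
  mode check); assertions within 3 empirical standard errors.

## Known limitations

* All-pairs LD is O(m²) per chromosome; the batched EM keeps ~30k pairs per
  second per core, comfortable for the scales above and for chromosome-wise
  runs of dense panels, but a 50k-SNP genome-wide all-pairs run is a long
  batch job.
* The |D′| confidence limits use a flat grid weighting of the profile
  likelihood; with very small n they are honest but conservative.
* The Sved inversion inherits its literature biases: estimates from bins
  with 4Nc ≫ 1 overestimate N_e; the trajectory should be read
  comparatively, not as calibrated history.
* Sample-size correction subtracts exactly 1/n; for phased data 1/(2n)
  would be appropriate, but phased input is out of scope.
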