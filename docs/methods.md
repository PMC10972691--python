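# Methods

## Scope and model

`invcoal` fits two-population demographies to the blockwise site frequency
spectrum (bSFS) of a heterospecific pair of diploid genomes.  A block of
ℓ callable sites is scored by the four folded mutation-type counts (hetA,
hetB, hetAB, fixed); the bSFS is the histogram of these configurations
over blocks, truncated at `kmax` copies per type with an explicit residual
class per type so the total block count is conserved.

The demographic models are the strict-divergence (DIV) and unidirectional
isolation-with-migration (IM) models: an ancestral panmictic population of
diploid size `Ne_anc` splits `t` generations ago into populations of sizes
`Ne_A` and `Ne_B`; under IM, individuals additionally move from the donor
into the recipient population at probability `m` per recipient lineage per
generation, constant since the split.  Assumptions inherited from the bSFS
framework: a constant mutation rate μ across blocks, no recombination
*within* a block, free recombination *between* blocks (the composite
likelihood multiplies across blocks), infinite sites within a block, and
neutrality of the analysed (intergenic, non-repetitive) sequence.

### Migration bookkeeping

`IM_AB` means forwards-in-time migration of individuals from A into B.
Backwards in time, a lineage sampled in B jumps into A at rate `m`.  In
msprime this is `set_migration_rate(source="B", dest="A", rate=m)`
(backwards-time convention).  The mapping is pinned twice: a test compares
msprime-simulated tallies against the exact probability table under strong
migration, and a label-swap symmetry test checks that exchanging
population labels and the migration direction transposes the probability
table in its hetA/hetB axes.

### Unit conversions

All internal computation uses absolute units (generations, diploid
individuals, per-generation rates).  Scaled duals follow the framework's
conventions: `Ne = θ/(4μ)`, `t = T · 2Ne_ref · g`, `M = 2 Ne_recipient m`,
and the total probability that a recipient lineage traces back to the
donor is `1 − exp(−T·M)` with `T` in units of `2 Ne_recipient`
generations.  Defaults: μ = 2.8×10⁻⁹ per site per generation, g = 1 year.

## Computing configuration probabilities

P(config) is the expectation over genealogies of a product of four Poisson
terms with means μℓ·L_k, where L_k is the branch length subtending leaf
subsets of mutation class k.  We compute it exactly by augmenting the
structured-coalescent Markov chain of the 4 lineages with the capped
counts:

* State: the multiset of ancestral lineages, each labelled by the number
  of A- and B-leaves it subtends and its deme, together with the four
  capped counts (0..kmax, residual).  Folding maps subtended-leaf pairs
  (i,j) and (2−i,2−j) to the same observable class.
* Transitions: pairwise coalescence within a deme at rate 1/(2Ne_deme),
  backwards migration of recipient-deme lineages at rate m, and mutation
  of class k at rate μℓ per class-k lineage (incrementing the count;
  counts at the residual stay put).
* Phase 1 (between the present and the split, duration t) is integrated
  as a matrix exponential of the sparse count-augmented generator, applied
  to the initial vector by uniformization (Poisson-weighted power series;
  scipy's `expm_multiply` as fallback for stiff corners).
* Phase 2 (ancestral population, run to the MRCA) is an absorbing-chain
  linear system.  Because counts only increase, the system is block
  lower-triangular in count levels: it is solved level by level with small
  dense per-configuration blocks, of which only 16 distinct matrices (one
  per residual pattern) need factorising.

The resulting table sums to 1 to within 1e-8 by construction (conservative
generator), which is asserted, not assumed.

### Monte-Carlo oracle

An independent implementation samples genealogies of the same chain by the
Gillespie algorithm (numba-compiled), accumulating the four class lengths,
and estimates the table as the average of the exact Poisson products given
those lengths (Rao-Blackwellised, so no mutation-sampling noise).  The
test suite compares the exact table against this oracle at 12 parameter
points (DIV/IM, both directions, asymmetric sizes, t from 0 to 8×10⁶
generations) at 10⁶ genealogies per point.  Because all cells of one
point share genealogy draws, families of cells fluctuate jointly;
agreement is therefore scored grid-wide (no cell beyond 5 SE, ≤2% of
pooled cells beyond 3 SE) rather than cell-by-cell at 3 SE, which a
correlated fluctuation would fail spuriously.

## Fitting

`fit_model` maximises lnCL by Nelder-Mead over log-parameters (DIV: 4
free; IM: 5 free), with bounds Ne ∈ [10³, 5×10⁷], t ∈ [10³, 5×10⁷]
generations, m ∈ [10⁻¹², 10⁻⁵].  The first start is a method-of-moments
guess (sizes from the heterozygosity means, t from mean d_xy); the
remaining starts (default 5 total) are log-uniform within bounds from the
given seed.  Convergence tolerance is 1e-4 in lnCL; ties between starts
break to the lexicographically smallest parameter vector.  A subset of
parameters can be pinned (`fixed=`) for profile fits; the parametric
bootstrap uses this and warm starts (`start_params=`).

Nesting (lnCL(IM) ≥ lnCL(DIV)) holds at the optimum by construction and is
asserted up to optimizer tolerance.

## Blocks, pairs and summary statistics

* Blocks contain exactly ℓ *callable* sites (not ℓ consecutive bp); a
  candidate block whose genomic span exceeds `max_span` (default 2ℓ) is
  skipped and packing restarts one site later; trailing sites are
  discarded.
* With multiple samples per species, tallies sum over heterospecific
  pairs (Cartesian), each pair blocked independently on its own callable
  intervals (the site-class mask minus 1-bp holes at either sample's
  missing genotypes).  Samples are female (diploid X), so the X needs no
  ploidy special-casing.
* `kmax` defaults to 2 per type: the configuration space stays small while
  retaining most of the likelihood information.
* Per block: d_xy = (hetA/2 + hetB/2 + hetAB/2 + fixed)/ℓ,
  π_A = (hetA + hetAB)/ℓ (the A individual is heterozygous at hetAB sites
  too), π_B symmetric.  F_ST uses Hudson's 1 − H_w/H_b on block-aggregated
  means and is reported as missing when d_xy = 0.  Sliding windows are
  5,000 blocks advancing by 500 by default, never spanning chromosomes,
  dropping incomplete trailing windows.
* The gene-enrichment test is the standard 2×2 G-test, G = 2ΣO·ln(O/E)
  against χ²₁, without Williams or Yates correction.  Note: on the
  published counts (45 of 1,997 selected genes inside inversions vs 112 of
  5,426 outside) this formula gives G ≈ 0.23, not the originally reported
  0.159; the exact variant behind that number is unstated, so the standard
  formula is implemented and the discrepancy documented rather than
  matched.

## Variant preprocessing

Mirrors the QC applied to freebayes calls before blocking: records are
decomposed to allelic primitives (MNPs split per differing offset; indel
and length-changing records become non-SNP footprints), remaining non-SNPs
are removed along with any SNP within 2 bp of a footprint, and genotypes
are set missing when FMT/DP < 8 or DP > mean + 2 SD of that sample's
coverage, or any of RPL, RPR, SAF, SAR is 0.  The depth ceiling is always
computed from the data.  The alternative two-sided reading
(DP ∈ [max(8, mean−2SD), mean+2SD]) is available behind
`two_sided_depth=True`.  Multiallelic primitives are dropped and counted.
Records that mix indel and SNP alleles are treated wholly as non-SNP
footprints — a conservative simplification of full primitive extraction.

## Simulation machinery

* `simulate_tally` has two modes: unlinked blocks (one structured-
  coalescent genealogy per block, the likelihood's own assumption — used
  for parameter-recovery experiments) and chunked blocks (msprime sequence
  simulation in n_chunks chunks, recombination rate r between and within
  blocks — used for bootstrap realism).  Defaults for the bootstrap: 100
  replicates, 1,000 chunks, r = 8.9×10⁻⁹ /bp/generation.
* The parametric bootstrap records the **raw** ΔlnCL = lnCL(IM) −
  lnCL(DIV) per replicate, not clamped at zero.  Under the null roughly
  half the probability mass sits at the m = 0 boundary; clamping would
  create ties there and make the (1+k)/(n+1) p-value conservative, whereas
  exchangeable raw differences (observed and replicates fitted by the
  identical procedure) keep it exactly uniform on the achievable grid.
  The calibration test verifies this with 50 experiments at n_reps = 20.
* The inversion null simulates the colinear background demography with
  gene conversion only (no crossover): initiation rate 3.59×10⁻⁸
  /bp/generation — equivalently 1.4×10⁻⁵ converted sites/bp/generation
  over tracts of mean 390 bp — with geometrically distributed tract
  lengths (the standard coalescent-simulator model; only the mean is
  specified by the estimate it reproduces).  Replicates are matched to the
  inversion's data size in block count, assembled from sequences of
  100 kb by default, and compared one-sided (elevated divergence is the
  hypothesis) with the (1+k)/(n+1) estimator; two-sided p-values are
  available behind a flag.

## Synthetic data generator

The generator encodes the study design as a truth scenario: six
chromosome arms (X, 2L, 2R, 3, 4, 5), five large (>0.5 Mb) alternatively
fixed inversions (three overlapping on the X — one carried by species A,
two by B — and one each on chromosomes 4 and 5), 12 + 9 diploid female
samples, and per-partition demographies in which inversions are older and
receive less migration than the colinear background (defaults are the
published sympatric best-fit estimates per partition).  Genome
partitioning pools colinear autosomal regions, keeps each autosomal
inversion separate, and merges the overlapping X inversions into one
partition.

`generate_dataset` simulates each partition independently with msprime
(recombination 8.9×10⁻⁹ within the simulated spans) and writes
VCFv4.2 (diploid unphased GT, one ALT per record, plus plausible
DP/RPL/RPR/SAF/SAR fields drawn around 30× coverage), BED masks (0-based
half-open), a sample table and a provenance record.  Because partitions
are tens of Mb while tests need seconds, each partition contributes a
configurable amount of simulated sequence (`max_sim_length`, default
200 kb) placed at the start of its intervals; the intergenic mask tiles
the simulated spans deterministically (70% of every 10 kb) and random
repeat intervals cover ~10%, so downstream masking retains a known
fraction.  Regeneration from the same scenario and seed is byte-identical.

What the generator does **not** emulate: read-level error (FORMAT fields
are draws around fixed coverage, not read alignments), reference bias,
callability variation (all simulated sites are callable in all samples),
selection or inversion-origin sweeps, and polytomies of real SV breakpoint
uncertainty beyond Gaussian jitter.  Passing end-to-end tests therefore
demonstrates correctness of the analysis pipeline, not robustness to
real-data artefacts.

`generate_sv_calls` derives two caller-style INV tables from the truth
inversions (per carrier sample per caller), with Gaussian breakpoint
jitter, per-call false-negative dropout and Poisson false positives.  The
consensus stage clusters events whose breakpoints agree within 1,000 bp
and whose reciprocal overlap is ≥0.8 (standard SV-merging defaults, stated
here because the original merging parameters are not), requires support
from both callers, size >0.5 Mb, and the carrier threshold (≥9/12 species
A, ≥6/9 species B) in exactly one species with at most one stray call in
the other — a rarity ceiling that tolerates isolated caller noise while
remaining effectively alternatively fixed.

## Problem sizes and numerical choices

* Parameter-recovery experiments (tests and `scripts/acceptance.py`) use
  2×10⁵ unlinked 64-bp blocks per seed, three seeds, kmax = 2 — enough
  that split-time error is well under the 10% acceptance band.
* The bootstrap-calibration experiment runs at reduced scale by design
  (2,000 blocks, kmax = 1, profile fits over t and (t, m) with the sizes
  pinned at their generating values): calibration is a property of the
  resampling procedure, not of the fit dimension, and the reduced profile
  keeps 50×21 replicate fits tractable.
* Gene-conversion null tests run on scaled-down sequences and population
  sizes (10–20 kb, Ne of order 10⁴–10⁵): the simulation cost grows
  steeply with the population-scaled conversion rate 4·Ne·g·L, and the
  tested properties (calibration, variance ordering in the conversion
  rate, detection of a tenfold-older inversion) are scale-free.
* Uniformization tolerance 1e-13 with a hard step cap (fallback to
  scipy); probability-table normalisation asserted at 1e-8; degenerate
  inputs (t = 0, μ = 0, m = 0) take the analytic short paths and are
  covered by tests.

## Known limitations

* Ignoring within-block recombination biases split-time estimates upward
  on linked data — visible here when fitting chunk-simulated (linked)
  data, and the reason bootstrap replicates are simulated with
  recombination.
* Composite-likelihood support values overstate certainty; model choice
  must go through the parametric bootstrap, and ΔlnCL is never compared to
  χ² asymptotics.
* Two populations, constant unidirectional migration, instantaneous
  split: no secondary contact, pulses, or time-varying rates.
* The inversion null conditions on the colinear point estimates; their
  uncertainty is not propagated.
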