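# invcoal

Blockwise-SFS demographic inference for dating chromosomal inversions
relative to a species split.

## The problem

When two sister species differ by large, alternatively fixed chromosomal
inversions, a central question is whether those inversions arose *before*
the species split (segregating in the common ancestor, possibly sheltering
incipient barriers to gene flow) or *after* it (incidental rearrangements).
The question is answerable from whole-genome resequencing data: partition
the genome into colinear regions and inversions, fit an explicit coalescent
model of divergence with and without gene flow to each partition, and
compare the inferred split times T and migration rates M between
partitions.

`invcoal` implements that analysis end to end for two diploid population
samples — variant QC, genome partitioning, blockwise-SFS construction,
composite-likelihood model fitting, parametric-bootstrap model comparison,
a gene-conversion-only simulation null for inversion divergence, and
consensus filtering of inversion calls from two structural-variant callers
— together with a synthetic-data generator so the whole pipeline is
testable without any external data.  It is aimed at population geneticists
who want a self-contained, verifiable reimplementation of this style of
inversion-dating analysis.

## The model

Data are summarised by the **blockwise site frequency spectrum (bSFS)**:
for one diploid genome per species, short blocks of ℓ callable sites
(ℓ = 64 or 128) are each scored by four folded mutation-type counts

* `hetA` — sites heterozygous in species A only,
* `hetB` — heterozygous in B only,
* `hetAB` — heterozygous in both (same two alleles),
* `fixed` — homozygous for different alleles,

truncated at `kmax` per type.  Two demographies are fitted by maximising
the composite log-likelihood lnCL = Σ n(config) · ln P(config):

* **DIV** — an ancestral population of size `Ne_anc` splits into `Ne_A`
  and `Ne_B` at time `t` (generations), no subsequent gene flow;
* **IM** — DIV plus constant unidirectional migration at probability `m`
  per lineage per generation (scaled rate `M = 2 Ne_recipient m`).

P(config) is computed exactly: the 4-lineage structured coalescent is
augmented with the capped mutation counts (mutations of class k are Markov
events at rate μℓ per class-k lineage) and the two phases of the chain are
integrated by sparse matrix exponentials and a blockwise linear solve.  An
independent Monte-Carlo genealogy sampler estimates the same probabilities
and serves as the test oracle.  Absolute units use
`Ne = θ/(4μ)` and `t = T · 2Ne · g` with μ = 2.8×10⁻⁹ /site/generation and
g = 1 year by default.

Support for gene flow (ΔlnCL between IM and DIV) is calibrated by a
parametric bootstrap under the fitted DIV model, with blocks simulated in
linked chunks at recombination rate r = 8.9×10⁻⁹.  Elevated inversion
d_xy/F_ST is tested against a conservative null that simulates the
colinear background demography with **gene conversion but no crossover**
(initiation 3.59×10⁻⁸ /bp/generation, mean tract 390 bp).

## Worked example

Simulate 50,000 unlinked 64-bp blocks under an IM history (migration from
A into B), then refit both models:

```python
from invcoal import mc
from invcoal.blocks import tally_from_block_counts
from invcoal.likelihood import (
    DemographicParams, fit_model, compare_models, migrant_fraction, to_scaled,
)

truth = DemographicParams(
    ne_a=735_000, ne_b=377_000, ne_anc=1_388_000,
    t=2_526_000, m=1.29e-8, model="IM_AB",
)
counts = mc.sample_block_counts(truth, n_blocks=50_000, block_length=64,
                                mu=2.8e-9, seed=7)
tally = tally_from_block_counts(counts, kmax=2, block_length=64)

fit_div = fit_model(tally, model="DIV", seed=0)
fit_im = fit_model(tally, model="IM_AB", seed=0)
cmp = compare_models(fit_im, fit_div)
```

Printing the fitted parameters and the model comparison gives:

```
DIV   lnCL =    -151408.9
IM_AB lnCL =    -151346.6   delta lnCL = 62.3
t_hat  =    2,586,367 generations (simulated: 2,526,000)
Ne_A   =      739,069   Ne_B =      374,450   Ne_anc =    1,356,963
m_hat  = 1.61e-08 per generation  (M = 0.0121)
migrant fraction 1-exp(-T*M) = 4.1%
```

The IM fit recovers the simulated split time within ~2.4% at this data
size and prefers IM over DIV by 62 composite-log-likelihood units; the
recovered migration rate implies that ~4% of lineages sampled in the
recipient species trace back to the donor.  At the 2×10⁵-block scale used
by `scripts/acceptance.py` the split-time error drops well below 1%.

A full file-based pipeline is available through the CLI:

```bash
invcoal simulate --out-dir data --seed 1          # VCF + masks + SV tables
invcoal preprocess --vcf data/synthetic.vcf --out-prefix work/qc
invcoal blocks --data-dir data --out work/tallies # per-partition bSFS
invcoal fit --tally work/tallies/autosome_colinear.tally.tsv --model IM_AB
invcoal sv-consensus --caller1 data/caller1.tsv --caller2 data/caller2.tsv \
    --out-prefix work/consensus
```

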