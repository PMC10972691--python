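"""msprime bridging: demography construction and genotype classification.

Migration bookkeeping (the classic place to get an IM model backwards):
``IM_AB`` states that, forwards in time, individuals move from A into B at
probability ``m`` per B-individual per generation.  Backwards in time a
lineage sampled in B therefore jumps into A at rate ``m``.  msprime's
``set_migration_rate(source, dest)`` uses the backwards-time convention
(lineages move from ``source`` to ``dest``), so IM_AB maps to
``source="B", dest="A"``.  This mapping is pinned by a test comparing
msprime-simulated tallies against the exact probability table.
"""

from __future__ import annotations

import msprime
import numpy as np

from .likelihood import DemographicParams

__all__ = ["demography", "sim_pair_ancestry", "classify_genotype_matrix"]


def demography(params: DemographicParams) -> msprime.Demography:
    d = msprime.Demography()
    d.add_population(name="A", initial_size=params.ne_a)
    d.add_population(name="B", initial_size=params.ne_b)
    d.add_population(name="anc", initial_size=params.ne_anc)
    if params.m > 0:
        if params.model == "IM_AB":
            d.set_migration_rate(source="B", dest="A", rate=params.m)
        elif params.model == "IM_BA":
            d.set_migration_rate(source="A", dest="B", rate=params.m)
    d.add_population_split(time=params.t, derived=["A", "B"], ancestral="anc")
    return d


def sim_pair_ancestry(
    params: DemographicParams,
    sequence_length: float,
    seed: int,
    n_a: int = 1,
    n_b: int = 1,
    recombination_rate: float = 0.0,
    gene_conversion_rate: float = 0.0,
    gene_conversion_tract: float = 390.0,
    num_replicates: int | None = None,
):
    kwargs = {}
    if gene_conversion_rate > 0:
        kwargs["gene_conversion_rate"] = gene_conversion_rate
        kwargs["gene_conversion_tract_length"] = gene_conversion_tract
    return msprime.sim_ancestry(
        samples={"A": n_a, "B": n_b},
        demography=demography(params),
        sequence_length=sequence_length,
        recombination_rate=recombination_rate,
        ploidy=2,
        random_seed=(int(seed) % (2**31 - 2)) + 1,
        num_replicates=num_replicates,
        **kwargs,
    )


def classify_genotype_matrix(G: np.ndarray, ia: int, ib: int) -> np.ndarray:
    """Folded mutation-type codes per site for a heterospecific diploid pair.

    ``G`` is the (n_sites, n_haplotypes) genotype matrix; individuals are
    consecutive haplotype pairs.  Codes: 0 hetA, 1 hetB, 2 hetAB, 3 fixed,
    -1 monomorphic, -2 more than two alleles within the pair (pre-filtered
    upstream in the real pipeline).
    """
    a0, a1 = G[:, 2 * ia], G[:, 2 * ia + 1]
    b0, b1 = G[:, 2 * ib], G[:, 2 * ib + 1]
    out = np.full(len(G), -1, dtype=np.int64)
    het_a = a0 != a1
    het_b = b0 != b1
    out[het_a & ~het_b] = 0
    out[~het_a & het_b] = 1
    out[het_a & het_b] = 2
    out[~het_a & ~het_b & (a0 != b0)] = 3
    # flag >2 alleles within the 4 haplotypes
    stacked = np.stack([a0, a1, b0, b1], axis=1)
    n_alleles = (np.sort(stacked, axis=1)[:, 1:] != np.sort(stacked, axis=1)[:, :-1]).sum(axis=1) + 1
    out[n_alleles > 2] = -2
    return out
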