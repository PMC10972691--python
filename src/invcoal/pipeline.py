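"""End-to-end glue: from a dataset directory (VCF + masks + truth) to
per-partition blockwise-SFS tallies.

This is the path the CLI drives and the integration tests exercise: QC and
decomposition of the VCF, intergenic-minus-repeats masking, genome
partitioning at inversion breakpoints, per-pair block cutting and tallying.
"""

from __future__ import annotations

import json
from collections import defaultdict
from itertools import islice, product
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import BlockSpec, block_count_matrix, cut_blocks, tally_from_block_counts
from .intervals import intersect, subtract
from .preprocess import (
    GenotypeFilterPolicy,
    decompose_and_filter,
    pair_callable_intervals,
    partition_genome,
)

__all__ = ["read_bed", "tally_dataset_directory"]


def read_bed(path) -> dict:
    out = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, *_ = line.split()
            out[chrom].append((int(s), int(e)))
    return {c: sorted(iv) for c, iv in out.items()}


def tally_dataset_directory(
    data_dir,
    block_length: int = 64,
    kmax: int = 2,
    max_pairs: int = 4,
    policy: GenotypeFilterPolicy | None = None,
) -> dict:
    """Tally the bSFS per genome partition from a `simulate` output directory.

    Tallies sum over up to ``max_pairs`` heterospecific sample pairs, each
    pair blocked independently on its own callable intervals (the site-class
    mask minus that pair's missing genotypes).  Returns
    ``{partition name: (BSFSTally, block-count matrix)}``.
    """
    data_dir = Path(data_dir)
    truth = json.loads((data_dir / "truth.json").read_text())
    lengths = {c: int(l) for c, l in truth["chromosomes"]}
    chrom_class = truth["chrom_class"]
    inversions = [(c, int(s), int(e)) for c, s, e, _ in truth["inversions"]]
    samples = pd.read_csv(data_dir / "samples.tsv", sep="\t")
    a_samples = samples.loc[samples.species == "A", "sample"].tolist()
    b_samples = samples.loc[samples.species == "B", "sample"].tolist()
    pairs = list(islice(product(a_samples, b_samples), max_pairs))

    snps = decompose_and_filter(data_dir / "synthetic.vcf", policy)
    intergenic = read_bed(data_dir / "intergenic.bed")
    repeats = read_bed(data_dir / "repeats.bed")
    mask = {c: subtract(iv, repeats.get(c, [])) for c, iv in intergenic.items()}
    partitions = partition_genome(inversions, chrom_class, lengths)

    spec = BlockSpec(block_length=block_length)
    missing = {s: snps.missing_positions(s) for s in {x for p in pairs for x in p}}
    out = {}
    for part in partitions:
        per_pair = []
        for sa, sb in pairs:
            callable_ = pair_callable_intervals(
                {c: intersect(mask.get(c, []), iv) for c, iv in part.intervals.items()},
                missing[sa],
                missing[sb],
            )
            vchrom, vpos, vcls = snps.pair_variant_sites(sa, sb)
            for chrom, iv in callable_.items():
                if not iv:
                    continue
                blk = cut_blocks(iv, spec, chrom)
                if blk.n_blocks == 0:
                    continue
                sel = vchrom == chrom
                per_pair.append(block_count_matrix(blk, vpos[sel], vcls[sel]))
        bc = (
            np.concatenate(per_pair)
            if per_pair
            else np.empty((0, 4), dtype=np.int64)
        )
        if len(bc) == 0:
            continue
        out[part.name] = (tally_from_block_counts(bc, kmax, block_length), bc)
    return out
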