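"""Block cutting and blockwise-SFS tallies.

Callable sequence for a heterospecific sample pair is packed left-to-right
into blocks of exactly ``block_length`` *callable* sites (not consecutive
bp); a candidate block whose genomic span exceeds ``max_span`` is skipped
and packing restarts at the next callable site.  Each block is scored by
the four folded mutation-type counts (hetA, hetB, hetAB, fixed) and the
blockwise SFS (bSFS) is the histogram of these configurations, truncated
at ``kmax`` per type with an explicit residual class so the total block
count is conserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BlockSpec",
    "Blocks",
    "BSFSTally",
    "cut_blocks",
    "classify_site",
    "tally_bsfs",
    "tally_from_block_counts",
]

MONO, HETA, HETB, HETAB, FIXED, MISSING = "mono", "hetA", "hetB", "hetAB", "fixed", "missing"
_TYPE_INDEX = {HETA: 0, HETB: 1, HETAB: 2, FIXED: 3}


@dataclass(frozen=True)
class BlockSpec:
    """Block construction parameters (64 and 128 bp are the standard lengths)."""

    block_length: int = 64
    max_span: int | None = None  # default 2 * block_length

    def __post_init__(self):
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if self.max_span is not None and self.max_span < self.block_length:
            raise ValueError("max_span must be >= block_length")

    @property
    def span(self) -> int:
        return self.max_span if self.max_span is not None else 2 * self.block_length


@dataclass
class Blocks:
    """Blocks for one chromosome/pair: ``positions`` are the callable sites
    in order; block ``i`` covers ``positions[starts[i] : starts[i] + ell]``."""

    chrom: str
    positions: np.ndarray
    starts: np.ndarray
    block_length: int

    @property
    def n_blocks(self) -> int:
        return len(self.starts)

    def block_sites(self, i: int) -> np.ndarray:
        s = self.starts[i]
        return self.positions[s : s + self.block_length]

    def block_bounds(self, i: int) -> tuple[int, int]:
        """Genomic interval [start, end) spanned by block i."""
        s = self.block_sites(i)
        return int(s[0]), int(s[-1]) + 1

    def midpoints(self) -> np.ndarray:
        first = self.positions[self.starts]
        last = self.positions[self.starts + self.block_length - 1]
        return (first + last + 1) / 2.0


def cut_blocks(intervals, spec: BlockSpec, chrom: str = "") -> Blocks:
    """Greedy left-to-right packing of callable sites into fixed-size blocks.

    ``intervals`` is a sorted, disjoint list of half-open [start, end)
    callable intervals.  Trailing sites that cannot fill a block are
    discarded.
    """
    arrs = [np.arange(s, e, dtype=np.int64) for s, e in intervals if e > s]
    positions = np.concatenate(arrs) if arrs else np.empty(0, dtype=np.int64)
    ell = spec.block_length
    span = spec.span
    starts = []
    i = 0
    n = len(positions)
    while i + ell <= n:
        if positions[i + ell - 1] - positions[i] + 1 <= span:
            starts.append(i)
            i += ell
        else:
            i += 1
    return Blocks(chrom, positions, np.asarray(starts, dtype=np.int64), ell)


def classify_site(gt_a, gt_b) -> str:
    """Folded mutation type of one biallelic site for a heterospecific pair.

    Genotypes are length-2 sequences of allele indices; ``None``/negative
    alleles mean missing.  Classes: mono, hetA, hetB, hetAB, fixed, missing.
    """
    alleles = list(gt_a) + list(gt_b)
    if any(a is None or a < 0 for a in alleles):
        return MISSING
    if len(set(alleles)) > 2:
        raise ValueError(f"more than two alleles across the pair: {gt_a}, {gt_b}")
    het_a = gt_a[0] != gt_a[1]
    het_b = gt_b[0] != gt_b[1]
    if het_a and het_b:
        return HETAB
    if het_a:
        return HETA
    if het_b:
        return HETB
    if gt_a[0] != gt_b[0]:
        return FIXED
    return MONO


@dataclass
class BSFSTally:
    """Histogram over truncated mutation configurations.

    ``counts`` has shape ``(kmax+2,)*4`` indexed (hetA, hetB, hetAB, fixed);
    index ``kmax+1`` is the residual (> kmax) class per type.
    """

    counts: np.ndarray
    kmax: int
    block_length: int
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        K = self.kmax + 2
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (K, K, K, K):
            raise ValueError("counts shape does not match kmax")

    @property
    def n_blocks(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "BSFSTally") -> "BSFSTally":
        if (self.kmax, self.block_length) != (other.kmax, other.block_length):
            raise ValueError("tallies have incompatible kmax/block length")
        return BSFSTally(
            self.counts + other.counts,
            self.kmax,
            self.block_length,
            self.n_dropped + other.n_dropped,
        )

    def to_tsv(self, path):
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("hetA\thetB\thetAB\tfixed\tn_blocks\n")
            K = self.kmax + 2
            for idx in np.ndindex(self.counts.shape):
                c = self.counts[idx]
                if c:
                    lab = ["R" if v == K - 1 else str(v) for v in idx]
                    fh.write("\t".join(lab) + f"\t{c}\n")
        meta = {
            "kmax": self.kmax,
            "block_length": self.block_length,
            "n_dropped": self.n_dropped,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path):
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        kmax = meta.pop("kmax")
        ell = meta.pop("block_length")
        dropped = meta.pop("n_dropped", 0)
        K = kmax + 2
        counts = np.zeros((K, K, K, K), dtype=np.int64)
        with open(path) as fh:
            next(fh)
            for line in fh:
                *lab, c = line.split()
                idx = tuple(K - 1 if v == "R" else int(v) for v in lab)
                counts[idx] = int(c)
        return cls(counts, kmax, ell, dropped, meta)


def tally_from_block_counts(block_counts, kmax: int, block_length: int) -> BSFSTally:
    """Histogram an (n_blocks, 4) matrix of per-block mutation-type counts,
    pooling counts above ``kmax`` into the residual class."""
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    bc = np.asarray(block_counts, dtype=np.int64)
    if bc.ndim != 2 or bc.shape[1] != 4:
        raise ValueError("block_counts must be (n, 4)")
    K = kmax + 2
    trunc = np.minimum(bc, kmax + 1)
    flat = np.ravel_multi_index(tuple(trunc.T), (K, K, K, K))
    counts = np.bincount(flat, minlength=K**4).reshape(K, K, K, K)
    return BSFSTally(counts, kmax, block_length)


def block_count_matrix(blocks: Blocks, variant_positions, variant_classes) -> np.ndarray:
    """Per-block mutation-type counts from site classifications.

    ``variant_positions`` / ``variant_classes`` give the positions and type
    labels (hetA/hetB/hetAB/fixed; mono and missing-free by construction)
    of this pair's variant sites; unlisted callable sites are monomorphic.
    Blocks containing a site labelled ``missing`` are dropped by the caller
    (pair-callable intervals already exclude missing genotypes).
    """
    vpos = np.asarray(variant_positions, dtype=np.int64)
    order = np.argsort(vpos)
    vpos = vpos[order]
    vcls = np.asarray([_TYPE_INDEX[c] for c in np.asarray(variant_classes)[order]])
    ell = blocks.block_length
    out = np.zeros((blocks.n_blocks, 4), dtype=np.int64)
    if blocks.n_blocks == 0 or len(vpos) == 0:
        return out
    # map variant positions to their index in the callable-site array
    site_idx = np.searchsorted(blocks.positions, vpos)
    ok = (site_idx < len(blocks.positions)) & (blocks.positions[np.minimum(site_idx, len(blocks.positions) - 1)] == vpos)
    site_idx, vcls = site_idx[ok], vcls[ok]
    # block id of each callable-site index (or -1 outside any block)
    block_of = np.full(len(blocks.positions), -1, dtype=np.int64)
    for b, s in enumerate(blocks.starts):
        block_of[s : s + ell] = b
    bid = block_of[site_idx]
    keep = bid >= 0
    np.add.at(out, (bid[keep], vcls[keep]), 1)
    return out


def tally_bsfs(blocks: Blocks, variant_positions, variant_classes, kmax: int = 2) -> BSFSTally:
    """Tally one pair's blocks into a truncated bSFS."""
    bc = block_count_matrix(blocks, variant_positions, variant_classes)
    return tally_from_block_counts(bc, kmax, blocks.block_length)
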