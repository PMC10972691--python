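"""Variant QC, site-class masking and genome partitioning.

Mirrors the preprocessing applied to short-read genotype calls before
blockwise-SFS construction: non-SNP variants are decomposed into allelic
primitives, remaining non-SNPs removed together with any SNP within
``snp_exclusion_radius`` (2 bp) of one, and genotype calls are set missing
when depth or read-placement balance thresholds are violated (FMT/DP
between 8 and 2 SD above the per-sample mean coverage; RPL, RPR, SAF,
SAR >= 1).  Masks and partitions use 0-based half-open coordinates.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .intervals import merge, subtract, subtract_positions, validate

__all__ = [
    "GenotypeFilterPolicy",
    "SnpSet",
    "GenomicPartition",
    "decompose_and_filter",
    "build_site_class_mask",
    "partition_genome",
    "pair_callable_intervals",
]

FORMAT_FIELDS = ("DP", "RPL", "RPR", "SAF", "SAR")


@dataclass(frozen=True)
class GenotypeFilterPolicy:
    """Genotype-level filter thresholds.

    The depth ceiling is computed from the data per sample (mean + k*SD of
    FMT/DP over called sites), never fixed.  ``two_sided_depth`` switches to
    the alternative reading DP in [max(min_depth, mean-k*SD), mean+k*SD].
    """

    min_depth: int = 8
    depth_sd_k: float = 2.0
    min_rpl: int = 1
    min_rpr: int = 1
    min_saf: int = 1
    min_sar: int = 1
    snp_exclusion_radius: int = 2
    two_sided_depth: bool = False
    strict_formats: bool = False

    def __post_init__(self):
        if min(self.min_depth, self.min_rpl, self.min_rpr, self.min_saf, self.min_sar) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.snp_exclusion_radius < 0:
            raise ValueError("snp_exclusion_radius must be >= 0")


@dataclass
class SnpSet:
    """Filtered biallelic SNP primitives with per-sample diploid genotypes.

    ``pos`` is 0-based; ``gt`` has shape (n_sites, n_samples, 2) with allele
    codes 0 (REF-like) / 1 (ALT-like) and -1 for missing.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    samples: list[str]
    n_multiallelic_dropped: int = 0
    n_near_nonsnp_dropped: int = 0
    coverage_stats: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def missing_positions(self, sample: str):
        """Per-chromosome positions where this sample's genotype is missing."""
        si = self.samples.index(sample)
        miss = np.any(self.gt[:, si, :] < 0, axis=1)
        out = {}
        for c in np.unique(self.chrom):
            sel = (self.chrom == c) & miss
            out[str(c)] = self.pos[sel]
        return out

    def pair_variant_sites(self, sample_a: str, sample_b: str):
        """(chrom, pos, class) for sites variable within the pair.

        Class labels follow :func:`invcoal.blocks.classify_site`; missing
        sites are excluded (they are holes in the callable intervals).
        """
        from .blocks import classify_site

        ia, ib = self.samples.index(sample_a), self.samples.index(sample_b)
        ga, gb = self.gt[:, ia, :], self.gt[:, ib, :]
        ok = np.all(ga >= 0, axis=1) & np.all(gb >= 0, axis=1)
        chroms, poss, classes = [], [], []
        for i in np.nonzero(ok)[0]:
            cls = classify_site(tuple(ga[i]), tuple(gb[i]))
            if cls not in ("mono",):
                chroms.append(self.chrom[i])
                poss.append(self.pos[i])
                classes.append(cls)
        return np.asarray(chroms), np.asarray(poss, dtype=np.int64), np.asarray(classes)


def _decompose_record(pos0, ref, alts):
    """Split a VCF record into SNP primitives and non-SNP footprints.

    Returns (snp_sites, nonsnp_intervals, multiallelic): ``snp_sites`` maps
    offset -> list of per-input-allele output codes (0 REF-like / 1
    ALT-like), used to translate genotypes.
    """
    snps = {}
    nonsnp = []
    multi = 0
    if any(len(a) != len(ref) for a in alts):
        span = max(len(ref), *(len(a) for a in alts))
        nonsnp.append((pos0, pos0 + span))
        return snps, nonsnp, multi
    for off in range(len(ref)):
        bases = [ref[off]] + [a[off] for a in alts]
        if all(b == bases[0] for b in bases[1:]):
            continue
        if len(set(bases)) > 2:
            multi += 1
            continue
        codes = [0 if b == bases[0] else 1 for b in bases]
        snps[off] = codes
    return snps, nonsnp, multi


def _coverage_stats(vcf_path, samples):
    from cyvcf2 import VCF

    tot = np.zeros(len(samples))
    tot2 = np.zeros(len(samples))
    n = np.zeros(len(samples))
    for v in VCF(str(vcf_path)):
        dp = v.format("DP")
        if dp is None:
            continue
        dp = dp[:, 0].astype(float)
        ok = dp >= 0
        tot[ok] += dp[ok]
        tot2[ok] += dp[ok] ** 2
        n[ok] += 1
    mean = np.divide(tot, n, out=np.zeros_like(tot), where=n > 0)
    var = np.divide(tot2, n, out=np.zeros_like(tot), where=n > 0) - mean**2
    return {s: (float(mean[i]), float(np.sqrt(max(var[i], 0.0)))) for i, s in enumerate(samples)}


def decompose_and_filter(
    vcf_path,
    policy: GenotypeFilterPolicy | None = None,
    coverage_stats: dict | None = None,
) -> SnpSet:
    """Decompose variants to allelic primitives and apply genotype filters.

    Returns the clean biallelic SNP set; genotypes violating any threshold
    are set to missing (-1).  SNPs within ``snp_exclusion_radius`` of a
    non-SNP footprint are dropped, as are multiallelic primitives.
    Records lacking a FORMAT field skip that filter with a warning unless
    ``policy.strict_formats``.
    """
    from cyvcf2 import VCF

    policy = policy or GenotypeFilterPolicy()
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if coverage_stats is None:
        coverage_stats = _coverage_stats(vcf_path, samples)
    dp_hi = {}
    dp_lo = {}
    for s in samples:
        mean, sd = coverage_stats[s]
        dp_hi[s] = mean + policy.depth_sd_k * sd
        dp_lo[s] = (
            max(policy.min_depth, mean - policy.depth_sd_k * sd)
            if policy.two_sided_depth
            else policy.min_depth
        )
    lo = np.array([dp_lo[s] for s in samples])
    hi = np.array([dp_hi[s] for s in samples])

    chroms, poss, refs, alts_, gts = [], [], [], [], []
    nonsnp = defaultdict(list)
    n_multi = 0
    warned = set()

    for v in vcf:
        pos0 = v.POS - 1
        alts = v.ALT or []
        if not alts:
            continue
        snps, ns, multi = _decompose_record(pos0, v.REF, alts)
        n_multi += multi
        for iv in ns:
            nonsnp[v.CHROM].append(iv)
        if not snps:
            continue

        garr = np.array(v.genotypes, dtype=np.int64)[:, :2]  # (S, 2), -1 missing
        bad = np.zeros(len(samples), dtype=bool)
        for name, lo_thr in (
            ("RPL", policy.min_rpl),
            ("RPR", policy.min_rpr),
            ("SAF", policy.min_saf),
            ("SAR", policy.min_sar),
        ):
            arr = v.format(name)
            if arr is None:
                if policy.strict_formats:
                    raise ValueError(f"missing FORMAT/{name} at {v.CHROM}:{v.POS}")
                if name not in warned:
                    warnings.warn(f"FORMAT/{name} absent; skipping that filter")
                    warned.add(name)
                continue
            bad |= arr[:, 0].astype(float) < lo_thr
        dp = v.format("DP")
        if dp is None:
            if policy.strict_formats:
                raise ValueError(f"missing FORMAT/DP at {v.CHROM}:{v.POS}")
            if "DP" not in warned:
                warnings.warn("FORMAT/DP absent; skipping the depth filter")
                warned.add("DP")
        else:
            d = dp[:, 0].astype(float)
            bad |= (d < lo) | (d > hi)

        for off, codes in sorted(snps.items()):
            g = garr.copy()
            ok = g >= 0
            g[ok] = np.take(codes, g[ok])
            g[~ok] = -1
            g[bad, :] = -1
            chroms.append(v.CHROM)
            poss.append(pos0 + off)
            refs.append(v.REF[off])
            aset = {a[off] for a in alts if a[off] != v.REF[off]}
            alts_.append(sorted(aset)[0])
            gts.append(g)

    chrom = np.asarray(chroms, dtype=object)
    pos = np.asarray(poss, dtype=np.int64)
    gt = (
        np.stack(gts).astype(np.int8)
        if gts
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    ref = np.asarray(refs, dtype=object)
    alt = np.asarray(alts_, dtype=object)

    # drop SNPs within the exclusion radius of any non-SNP footprint
    r = policy.snp_exclusion_radius
    keep = np.ones(len(pos), dtype=bool)
    n_near = 0
    for c, ivs in nonsnp.items():
        expanded = merge([(max(s - r, 0), e + r) for s, e in ivs])
        sel = chrom == c
        if not sel.any():
            continue
        p = pos[sel]
        inside = np.zeros(len(p), dtype=bool)
        for s, e in expanded:
            inside |= (p >= s) & (p < e)
        idx = np.nonzero(sel)[0][inside]
        n_near += len(idx)
        keep[idx] = False

    # collapse duplicate positions (multiallelic after decomposition)
    key = [(c, p) for c, p in zip(chrom[keep], pos[keep])]
    seen, dup = set(), set()
    for k in key:
        (dup if k in seen else seen).add(k)
    if dup:
        kidx = np.nonzero(keep)[0]
        for i, k in zip(kidx, key):
            if k in dup:
                keep[i] = False
                n_multi += 1

    order = np.lexsort((pos[keep], chrom[keep].astype(str)))
    sel = np.nonzero(keep)[0][order]
    return SnpSet(
        chrom=chrom[sel],
        pos=pos[sel],
        ref=ref[sel],
        alt=alt[sel],
        gt=gt[sel],
        samples=samples,
        n_multiallelic_dropped=n_multi,
        n_near_nonsnp_dropped=n_near,
        coverage_stats=coverage_stats,
    )


def build_site_class_mask(annotation: dict, repeats: dict, chrom_lengths: dict, site_class: str = "intergenic") -> dict:
    """Requested site class minus repeats, per chromosome (exact set algebra)."""
    if site_class not in annotation:
        raise KeyError(f"site class {site_class!r} not in annotation")
    out = {}
    for chrom, iv in annotation[site_class].items():
        if chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        validate(iv, chrom_lengths[chrom])
        rep = repeats.get(chrom, [])
        validate(rep, chrom_lengths[chrom])
        out[chrom] = subtract(iv, rep)
    return out


@dataclass
class GenomicPartition:
    """Named interval set with an evolutionary-history class label."""

    name: str
    kind: str  # autosome_colinear | autosome_inversion | X_colinear | X_inversion
    intervals: dict  # chrom -> [(start, end), ...]

    def length(self) -> int:
        return sum(e - s for iv in self.intervals.values() for s, e in iv)


def partition_genome(inversions, chrom_class: dict, chrom_lengths: dict) -> list[GenomicPartition]:
    """Partition the genome the way the inversion-dating analysis requires.

    Autosomal colinear regions (ending at inversion breakpoints) are pooled
    across autosomes into one partition; each autosomal inversion is its own
    partition; the X colinear region is separate; overlapping X inversions
    are merged (interval union) into a single partition.
    """
    inv_by_chrom = defaultdict(list)
    for chrom, s, e in inversions:
        if chrom not in chrom_class:
            raise ValueError(f"inversion on unknown chromosome {chrom!r}")
        validate([(s, e)], chrom_lengths[chrom])
        inv_by_chrom[chrom].append((s, e))

    parts = []
    auto_col = {}
    x_col = {}
    x_inv = {}
    for chrom, length in chrom_lengths.items():
        cls = chrom_class[chrom]
        invs = sorted(inv_by_chrom.get(chrom, []))
        if cls == "autosome":
            for (s1, e1), (s2, e2) in zip(invs, invs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping autosomal inversions on {chrom}")
            for s, e in invs:
                parts.append(
                    GenomicPartition(f"{chrom}_inv_{s}", "autosome_inversion", {chrom: [(s, e)]})
                )
            col = subtract([(0, length)], invs)
            if col:
                auto_col[chrom] = col
        elif cls == "X":
            merged = merge(invs)
            if merged:
                x_inv[chrom] = merged
            col = subtract([(0, length)], merged)
            if col:
                x_col[chrom] = col
        else:
            raise ValueError(f"unknown chromosome class {cls!r} for {chrom}")

    out = []
    if auto_col:
        out.append(GenomicPartition("autosome_colinear", "autosome_colinear", auto_col))
    out.extend(parts)
    if x_col:
        out.append(GenomicPartition("X_colinear", "X_colinear", x_col))
    if x_inv:
        out.append(GenomicPartition("X_inv", "X_inversion", x_inv))
    return out


def pair_callable_intervals(mask: dict, missing_a: dict, missing_b: dict) -> dict:
    """Callable intervals for a sample pair: the site-class mask minus 1-bp
    holes at positions where either sample's genotype is missing."""
    out = {}
    for chrom, iv in mask.items():
        holes = np.concatenate(
            [
                np.asarray(missing_a.get(chrom, []), dtype=np.int64),
                np.asarray(missing_b.get(chrom, []), dtype=np.int64),
            ]
        )
        out[chrom] = subtract_positions(iv, holes)
    return out
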