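"""Synthetic truth scenarios and the files every downstream stage consumes.

The generator emulates the study design this pipeline targets: two diploid
species samples (default 12 + 9 females), a genome of five chromosome arms
plus an X carrying five large (>0.5 Mb) alternatively fixed inversions
(three overlapping on the X, one each on autosomes 4 and 5), and an
isolation-with-migration history in which inversion partitions are older
and exchange fewer migrants than the colinear background.  Genotypes are
drawn per partition from the structured coalescent with that partition's
parameters; masks are written so that downstream intergenic filtering
retains a known fraction of sites; caller-style structural-variant tables
are derived from the truth inversions with configurable noise.

Everything is reproducible: a scenario plus its seed regenerates the same
dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from . import msp
from .intervals import intersect, merge, total_length, validate
from .likelihood import DemographicParams, MU_DEFAULT, GENERATION_TIME_DEFAULT
from .preprocess import GenomicPartition, partition_genome

__all__ = [
    "TruthScenario",
    "SyntheticDataset",
    "SVCallNoise",
    "generate_truth_scenario",
    "generate_dataset",
    "generate_sv_calls",
    "DEFAULT_CONFIG",
]

_BASES = np.array(list("ACGT"))

# Study-like default truth: chromosome-arm lengths, five fixed inversions
# (carrier = species with the derived arrangement) and per-partition
# demographies in which inversions are older and leakier-proof (smaller m)
# than the colinear background.  M values are converted to per-generation
# m via m = M / (2 * Ne_recipient).
DEFAULT_CONFIG = {
    "chromosomes": [
        ("X", 29_100_000),
        ("2L", 20_200_000),
        ("2R", 11_000_000),
        ("3", 26_000_000),
        ("4", 32_500_000),
        ("5", 26_500_000),
    ],
    "x_chromosomes": ["X"],
    "inversions": [
        ("X", 6_000_000, 17_000_000, "B"),   # 11.0 Mb
        ("X", 9_000_000, 16_200_000, "A"),   # 7.2 Mb, overlaps both B inversions
        ("X", 16_000_000, 19_100_000, "B"),  # 3.1 Mb
        ("4", 8_000_000, 23_900_000, "B"),   # 15.9 Mb
        ("5", 9_000_000, 18_200_000, "B"),   # 9.2 Mb
    ],
    "n_a": 12,
    "n_b": 9,
    "mu": MU_DEFAULT,
    "generation_time": GENERATION_TIME_DEFAULT,
    # (ne_a, ne_b, ne_anc, t, M) per partition kind
    "demography": {
        "autosome_colinear": (735_000, 377_000, 1_388_000, 2_526_000, 0.0097),
        "4_inv": (865_000, 470_000, 1_603_000, 2_988_000, 0.0067),
        "5_inv": (752_000, 392_000, 1_321_000, 2_823_000, 0.0076),
        "X_colinear": (493_000, 219_000, 1_592_000, 2_769_000, 0.0088),
        "X_inv": (607_000, 365_000, 1_591_000, 3_321_000, 0.0078),
    },
}


@dataclass
class TruthScenario:
    chromosomes: list
    chrom_class: dict
    inversions: list  # (chrom, start, end, carrier_species)
    partitions: list
    params: dict  # partition name -> DemographicParams
    n_a: int
    n_b: int
    mu: float
    generation_time: float
    seed: int

    @property
    def chrom_lengths(self) -> dict:
        return dict(self.chromosomes)

    @property
    def samples(self) -> dict:
        return {
            "A": [f"A{i:02d}" for i in range(1, self.n_a + 1)],
            "B": [f"B{i:02d}" for i in range(1, self.n_b + 1)],
        }

    def provenance(self) -> dict:
        return {
            "chromosomes": self.chromosomes,
            "chrom_class": self.chrom_class,
            "inversions": self.inversions,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mu": self.mu,
            "generation_time": self.generation_time,
            "seed": self.seed,
            "params": {
                k: {f: getattr(p, f) for f in ("ne_a", "ne_b", "ne_anc", "t", "m", "model")}
                for k, p in self.params.items()
            },
        }


def _partition_key(part: GenomicPartition) -> str:
    if part.kind == "autosome_inversion":
        chrom = next(iter(part.intervals))
        return f"{chrom}_inv"
    return part.name


def generate_truth_scenario(config: dict | None = None, seed: int = 0) -> TruthScenario:
    """Build and validate a truth scenario (defaults mimic the study design)."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    chromosomes = [(str(c), int(l)) for c, l in cfg["chromosomes"]]
    for name, length in chromosomes:
        if length <= 0:
            raise ValueError(f"zero-length chromosome {name!r}")
    lengths = dict(chromosomes)
    xset = set(cfg["x_chromosomes"])
    chrom_class = {c: ("X" if c in xset else "autosome") for c, _ in chromosomes}
    inversions = [tuple(i) for i in cfg["inversions"]]
    for chrom, s, e, carrier in inversions:
        if chrom not in lengths:
            raise ValueError(f"inversion on unknown chromosome {chrom!r}")
        validate([(s, e)], lengths[chrom])
        if carrier not in ("A", "B"):
            raise ValueError(f"carrier must be A or B, got {carrier!r}")
    if cfg["n_a"] < 1 or cfg["n_b"] < 1:
        raise ValueError("need at least one sample per species")

    parts = partition_genome(
        [(c, s, e) for c, s, e, _ in inversions], chrom_class, lengths
    )
    params = {}
    demo = cfg["demography"]
    for part in parts:
        key = _partition_key(part)
        if key not in demo:
            raise ValueError(f"no demography for partition {part.name} (key {key})")
        ne_a, ne_b, ne_anc, t, M = demo[key]
        m = M / (2.0 * ne_b)
        model = "IM_AB" if m > 0 else "DIV"
        params[part.name] = DemographicParams(ne_a, ne_b, ne_anc, t, m, model)
    return TruthScenario(
        chromosomes=chromosomes,
        chrom_class=chrom_class,
        inversions=inversions,
        partitions=parts,
        params=params,
        n_a=int(cfg["n_a"]),
        n_b=int(cfg["n_b"]),
        mu=float(cfg["mu"]),
        generation_time=float(cfg["generation_time"]),
        seed=int(seed),
    )


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset; ``write`` emits the standard file set."""

    scenario: TruthScenario
    variants: pd.DataFrame  # chrom, pos (0-based), ref, alt
    gt: np.ndarray  # (n_sites, n_samples, 2)
    sample_names: list
    sample_species: list
    intergenic: dict  # chrom -> intervals
    repeats: dict
    simulated_spans: dict  # partition name -> {chrom: intervals}
    depth_mean: float = 30.0

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    def inversion_bed(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, s, e, carrier) for c, s, e, carrier in self.scenario.inversions],
            columns=["chrom", "start", "end", "carrier"],
        )

    def pairwise_dxy(self, sample_a: str, sample_b: str) -> float:
        """Mean per-site divergence for one heterospecific pair over the
        simulated spans (all simulated sites treated as callable)."""
        ia = self.sample_names.index(sample_a)
        ib = self.sample_names.index(sample_b)
        L = sum(
            total_length(iv)
            for spans in self.simulated_spans.values()
            for iv in spans.values()
        )
        ga, gb = self.gt[:, ia, :], self.gt[:, ib, :]
        diffs = (ga[:, :, None] != gb[:, None, :]).mean(axis=(1, 2)).sum()
        return float(diffs) / L

    def write(self, out_dir, rng_seed: int | None = None):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self._write_vcf(out / "synthetic.vcf")
        _write_bed(out / "intergenic.bed", self.intergenic)
        _write_bed(out / "repeats.bed", self.repeats)
        with open(out / "inversions.bed", "w") as fh:
            for c, s, e, carrier in self.scenario.inversions:
                fh.write(f"{c}\t{s}\t{e}\tinv_{carrier}\n")
        with open(out / "samples.tsv", "w") as fh:
            fh.write("sample\tspecies\n")
            for n, sp in zip(self.sample_names, self.sample_species):
                fh.write(f"{n}\t{sp}\n")
        (out / "truth.json").write_text(json.dumps(self.scenario.provenance(), indent=1))
        return out

    def _write_vcf(self, path):
        rng = np.random.default_rng(np.random.SeedSequence([self.scenario.seed, 977]))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=invcoal-synthetic\n")
            for c, l in self.scenario.chromosomes:
                fh.write(f"##contig=<ID={c},length={l}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            for f in ("RPL", "RPR", "SAF", "SAR"):
                fh.write(f'##FORMAT=<ID={f},Number=1,Type=Integer,Description="Read placement/strand count">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_names)
                + "\n"
            )
            n_samp = len(self.sample_names)
            for i, row in enumerate(self.variants.itertuples(index=False)):
                dp = rng.poisson(self.depth_mean, n_samp)
                rpl = rng.binomial(dp, 0.5)
                saf = rng.binomial(dp, 0.5)
                cols = []
                for s in range(n_samp):
                    g = self.gt[i, s]
                    cols.append(
                        f"{g[0]}/{g[1]}:{dp[s]}:{rpl[s]}:{dp[s]-rpl[s]}:{saf[s]}:{dp[s]-saf[s]}"
                    )
                fh.write(
                    f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t60\tPASS\t.\t"
                    "GT:DP:RPL:RPR:SAF:SAR\t" + "\t".join(cols) + "\n"
                )


def _write_bed(path, ivd):
    with open(path, "w") as fh:
        for chrom in sorted(ivd):
            for s, e in ivd[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def _allocate_spans(part: GenomicPartition, max_len: int) -> dict:
    """Deterministically allocate up to ``max_len`` bp of simulated sequence
    at the start of a partition's intervals."""
    left = max_len
    out = {}
    for chrom in sorted(part.intervals):
        for s, e in part.intervals[chrom]:
            if left <= 0:
                break
            take = min(e - s, left)
            out.setdefault(chrom, []).append((s, s + take))
            left -= take
    return out


def _mask_pattern(spans: dict, period=10_000, intergenic_frac=0.7):
    """Deterministic intergenic/genic tiling inside simulated spans: the
    first ``intergenic_frac`` of every ``period`` is intergenic."""
    inter = {}
    cut = int(period * intergenic_frac)
    for chrom, ivs in spans.items():
        pieces = []
        for s, e in ivs:
            p = s - s % period
            while p < e:
                pieces.append((p, p + cut))
                p += period
        inter[chrom] = intersect(ivs, merge(pieces))
    return inter


def generate_dataset(
    scenario: TruthScenario,
    max_sim_length: int = 200_000,
    recombination_rate: float = 8.9e-9,
    repeat_fraction: float = 0.1,
) -> SyntheticDataset:
    """Simulate genotypes per partition and assemble the dataset.

    Each partition contributes up to ``max_sim_length`` bp of simulated
    sequence (placed at the start of its intervals; the remainder is left
    outside the intergenic mask), drawn from the structured coalescent with
    the partition's parameters via msprime and overlaid with mutations at
    the scenario's mu.
    """
    for name, length in scenario.chromosomes:
        if length <= 0:
            raise ValueError(f"zero-length chromosome {name!r}")
    samples = scenario.samples
    names = samples["A"] + samples["B"]
    species = ["A"] * scenario.n_a + ["B"] * scenario.n_b
    ss = np.random.SeedSequence([scenario.seed, 101])
    rows = []
    gts = []
    spans_by_part = {}
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 55]))
    for part in scenario.partitions:
        params = scenario.params[part.name]
        spans = _allocate_spans(part, max_sim_length)
        spans_by_part[part.name] = spans
        for chrom in sorted(spans):
            for s, e in spans[chrom]:
                child = ss.spawn(1)[0]
                seed1, seed2 = child.generate_state(2) % (2**31 - 2) + 1
                if scenario.mu > 0:
                    ts = msp.sim_pair_ancestry(
                        params,
                        e - s,
                        seed=int(seed1),
                        n_a=scenario.n_a,
                        n_b=scenario.n_b,
                        recombination_rate=recombination_rate,
                    )
                    mts = msprime.sim_mutations(ts, rate=scenario.mu, random_seed=int(seed2))
                else:
                    mts = None
                if mts is None or mts.num_sites == 0:
                    continue
                G = mts.genotype_matrix()  # sites x haplotypes
                pos = mts.tables.sites.position.astype(np.int64)
                # biallelic only; collapse allele codes to 0/1
                nall = G.max(axis=1)
                keep = nall == 1
                G, pos = G[keep], pos[keep]
                # unique discrete positions only
                _, uidx = np.unique(pos, return_index=True)
                G, pos = G[uidx], pos[uidx]
                ref_idx = rng.integers(0, 4, size=len(pos))
                alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
                for i, p in enumerate(pos):
                    rows.append((chrom, int(s + p), _BASES[ref_idx[i]], _BASES[alt_idx[i]]))
                gts.append(G.reshape(len(pos), -1, 2))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gt = (
        np.concatenate(gts, axis=0)
        if gts
        else np.empty((0, len(names), 2), dtype=np.int8)
    )
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy(dtype=object).astype(str))) if len(variants) else []
    variants = variants.iloc[order].reset_index(drop=True) if len(variants) else variants
    gt = gt[order] if len(variants) else gt

    all_spans = {}
    for spans in spans_by_part.values():
        for chrom, ivs in spans.items():
            all_spans.setdefault(chrom, []).extend(ivs)
    all_spans = {c: merge(iv) for c, iv in all_spans.items()}
    intergenic = _mask_pattern(all_spans)
    repeats = {}
    for chrom in sorted(all_spans):
        reps = []
        for s, e in all_spans[chrom]:
            p = s
            while p < e:
                gap = int(rng.exponential(10_000 / max(repeat_fraction, 1e-9) * 0.1 / 0.1))
                gap = max(gap, 500)
                rep_len = int(rng.integers(500, 3000))
                p += gap
                if p + rep_len <= e and rng.random() < repeat_fraction * 10_000 / (gap + rep_len):
                    reps.append((p, p + rep_len))
                    p += rep_len
        repeats[chrom] = merge(reps)

    return SyntheticDataset(
        scenario=scenario,
        variants=variants,
        gt=gt,
        sample_names=names,
        sample_species=species,
        intergenic=intergenic,
        repeats=repeats,
        simulated_spans=spans_by_part,
    )


@dataclass(frozen=True)
class SVCallNoise:
    """Caller-noise model for synthetic SV tables."""

    jitter_sd: float = 0.0  # bp, Gaussian breakpoint jitter
    fn_rate: float = 0.0  # per carrier sample per caller
    fp_rate: float = 0.0  # expected false calls per sample per caller

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not (0 <= self.fn_rate <= 1):
            raise ValueError("fn_rate must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


def generate_sv_calls(
    scenario: TruthScenario,
    noise: SVCallNoise | None = None,
    seed: int = 0,
    callers=("caller1", "caller2"),
):
    """Two caller-style inversion-call tables derived from the truth set.

    Every true fixed inversion is reported by each caller for each sample of
    the carrier species unless dropped at the false-negative rate;
    breakpoints are jittered with Gaussian noise; false positives are random
    intervals.  Returns one DataFrame per caller.
    """
    noise = noise or SVCallNoise()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 313]))
    lengths = scenario.chrom_lengths
    samples = scenario.samples
    tables = []
    for caller in callers:
        rows = []
        for chrom, s, e, carrier in scenario.inversions:
            for sample in samples[carrier]:
                if rng.random() < noise.fn_rate:
                    continue
                js = int(round(rng.normal(0, noise.jitter_sd))) if noise.jitter_sd else 0
                je = int(round(rng.normal(0, noise.jitter_sd))) if noise.jitter_sd else 0
                cs = max(0, s + js)
                ce = min(lengths[chrom], e + je)
                if ce <= cs:
                    ce = cs + 1
                rows.append((chrom, cs, ce, "INV", sample, carrier, caller))
        if noise.fp_rate > 0:
            for sp in ("A", "B"):
                for sample in samples[sp]:
                    for _ in range(rng.poisson(noise.fp_rate)):
                        chrom = scenario.chromosomes[rng.integers(len(scenario.chromosomes))][0]
                        L = lengths[chrom]
                        size = int(min(np.exp(rng.normal(11.5, 1.0)), L / 2))
                        start = int(rng.integers(0, max(L - size, 1)))
                        rows.append((chrom, start, start + size, "INV", sample, sp, caller))
        tables.append(
            pd.DataFrame(
                rows,
                columns=["chrom", "start", "end", "svtype", "sample", "species", "caller"],
            )
        )
    return tuple(tables)
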