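"""Variant decomposition, genotype filters, masks and genome partitioning."""

import numpy as np
import pytest

from conftest import write_vcf
from invcoal.preprocess import (
    GenotypeFilterPolicy,
    build_site_class_mask,
    decompose_and_filter,
    pair_callable_intervals,
    partition_genome,
)

S2 = ["s1", "s2"]


def _col(gt="0/1", dp=30, rpl=None, saf=None):
    rpl = dp // 2 if rpl is None else rpl
    saf = dp // 2 if saf is None else saf
    return f"{gt}:{dp}:{rpl}:{dp - rpl}:{saf}:{dp - saf}"


class TestDecompose:
    def test_mnp_becomes_two_snp_primitives(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [("chr1", 100, "AT", "GC", [_col(), _col("0/0")])],
            S2,
        )
        snps = decompose_and_filter(vcf)
        assert snps.n_sites == 2
        assert list(snps.pos) == [99, 100]  # 0-based
        assert list(snps.ref) == ["A", "T"] and list(snps.alt) == ["G", "C"]

    def test_mnp_keeps_only_differing_offsets(self, tmp_path):
        vcf = write_vcf(tmp_path / "a.vcf", [("chr1", 100, "ATG", "ATC", [_col(), _col()])], S2)
        snps = decompose_and_filter(vcf)
        assert snps.n_sites == 1 and snps.pos[0] == 101

    def test_snp_near_deletion_dropped(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [
                ("chr1", 100, "ATT", "A", [_col(), _col()]),  # deletion footprint [99,102)
                ("chr1", 104, "C", "T", [_col(), _col()]),  # 2 bp from footprint end
                ("chr1", 107, "G", "A", [_col(), _col()]),  # outside the radius
            ],
            S2,
        )
        snps = decompose_and_filter(vcf)
        assert list(snps.pos) == [106]
        assert snps.n_near_nonsnp_dropped == 1

    def test_multiallelic_snp_dropped_and_counted(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf", [("chr1", 50, "A", "C,G", [_col("1/2"), _col("0/0")])], S2
        )
        snps = decompose_and_filter(vcf)
        assert snps.n_sites == 0
        assert snps.n_multiallelic_dropped == 1


class TestGenotypeFilters:
    def test_low_depth_set_missing(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [
                ("chr1", p, "A", "C", [_col(dp=30), _col(dp=30)])
                for p in range(100, 140)
            ]
            + [("chr1", 200, "A", "C", [_col(dp=7), _col(dp=30)])],
            S2,
        )
        snps = decompose_and_filter(vcf)
        i = list(snps.pos).index(199)
        assert (snps.gt[i, 0] == -1).all()  # s1 missing (DP = 7 < 8)
        assert (snps.gt[i, 1] >= 0).all()

    def test_high_depth_outlier_set_missing(self, tmp_path):
        recs = [("chr1", p, "A", "C", [_col(dp=30), _col(dp=30)]) for p in range(100, 160)]
        recs.append(("chr1", 300, "A", "C", [_col(dp=300), _col(dp=30)]))
        snps = decompose_and_filter(write_vcf(tmp_path / "a.vcf", recs, S2))
        i = list(snps.pos).index(299)
        assert (snps.gt[i, 0] == -1).all()  # far above mean + 2 SD

    def test_strand_balance_filter(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [("chr1", 100, "A", "C", [_col(saf=0), _col()])],
            S2,
        )
        snps = decompose_and_filter(vcf)
        assert (snps.gt[0, 0] == -1).all() and (snps.gt[0, 1] >= 0).all()

    def test_monotone_in_min_depth(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = [
            ("chr1", p, "A", "C", [_col(dp=int(d1)), _col(dp=int(d2))])
            for p, d1, d2 in zip(
                range(100, 200), rng.integers(5, 40, 100), rng.integers(5, 40, 100)
            )
        ]
        vcf = write_vcf(tmp_path / "a.vcf", recs, S2)
        called = []
        for md in (5, 8, 15, 25):
            snps = decompose_and_filter(vcf, GenotypeFilterPolicy(min_depth=md))
            called.append(int((snps.gt >= 0).sum()))
        assert called == sorted(called, reverse=True)

    def test_missing_format_pass_through_and_idempotence(self, tmp_path):
        """A GT-only VCF passes through with a warning; refiltering the
        filtered output changes nothing (idempotence)."""
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [("chr1", 100, "A", "C", ["0/1", "1/1"]), ("chr1", 120, "G", "T", ["0/0", "0/1"])],
            S2,
            fmt="GT",
        )
        with pytest.warns(UserWarning):
            once = decompose_and_filter(vcf)
        with pytest.warns(UserWarning):
            twice = decompose_and_filter(vcf)
        assert (once.gt == twice.gt).all() and (once.pos == twice.pos).all()
        assert once.n_sites == 2

    def test_strict_mode_errors_on_missing_format(self, tmp_path):
        vcf = write_vcf(tmp_path / "a.vcf", [("chr1", 100, "A", "C", ["0/1", "1/1"])], S2, fmt="GT")
        with pytest.raises(ValueError):
            decompose_and_filter(vcf, GenotypeFilterPolicy(strict_formats=True))


class TestMasks:
    def test_class_minus_repeats(self):
        out = build_site_class_mask(
            {"intergenic": {"chr1": [(0, 100)]}},
            {"chr1": [(50, 60)]},
            {"chr1": 1000},
        )
        assert out["chr1"] == [(0, 50), (60, 100)]

    def test_repeat_covering_class_gives_empty(self):
        out = build_site_class_mask(
            {"intergenic": {"chr1": [(10, 20)]}}, {"chr1": [(0, 100)]}, {"chr1": 1000}
        )
        assert out["chr1"] == []

    def test_interval_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValueError):
            build_site_class_mask(
                {"intergenic": {"chr1": [(0, 2000)]}}, {}, {"chr1": 1000}
            )

    def test_pair_callable_punches_missing_holes(self):
        out = pair_callable_intervals(
            {"chr1": [(0, 100)]}, {"chr1": [10]}, {"chr1": [10, 50]}
        )
        assert out["chr1"] == [(0, 10), (11, 50), (51, 100)]


class TestPartitionGenome:
    LENGTHS = {"X": 30_000_000, "4": 33_000_000, "5": 27_000_000}
    CLASSES = {"X": "X", "4": "autosome", "5": "autosome"}

    def test_study_layout_gives_five_partitions(self):
        inversions = [
            ("4", 8_000_000, 23_900_000),
            ("5", 9_000_000, 18_200_000),
            ("X", 6_000_000, 17_000_000),
            ("X", 9_000_000, 16_200_000),
            ("X", 16_000_000, 19_100_000),
        ]
        parts = partition_genome(inversions, self.CLASSES, self.LENGTHS)
        kinds = sorted(p.kind for p in parts)
        assert len(parts) == 5
        assert kinds == [
            "X_colinear",
            "X_inversion",
            "autosome_colinear",
            "autosome_inversion",
            "autosome_inversion",
        ]
        xinv = next(p for p in parts if p.kind == "X_inversion")
        assert xinv.intervals["X"] == [(6_000_000, 19_100_000)]  # union of overlaps

    def test_no_inversions(self):
        parts = partition_genome([], self.CLASSES, self.LENGTHS)
        assert sorted(p.kind for p in parts) == ["X_colinear", "autosome_colinear"]

    def test_abutting_x_inversions_merge_to_union(self):
        parts = partition_genome(
            [("X", 1_000_000, 2_000_000), ("X", 2_000_000, 3_000_000)],
            self.CLASSES,
            self.LENGTHS,
        )
        xinv = next(p for p in parts if p.kind == "X_inversion")
        assert xinv.intervals["X"] == [(1_000_000, 3_000_000)]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            partition_genome([("7", 0, 100)], self.CLASSES, self.LENGTHS)

    def test_overlapping_autosomal_inversions_rejected(self):
        with pytest.raises(ValueError):
            partition_genome(
                [("4", 0, 2_000_000), ("4", 1_000_000, 3_000_000)],
                self.CLASSES,
                self.LENGTHS,
            )

    def test_partitions_tile_the_genome(self):
        """Union of partitions equals the full genome, with no overlap."""
        inversions = [("4", 8_000_000, 23_900_000), ("X", 6_000_000, 17_000_000)]
        parts = partition_genome(inversions, self.CLASSES, self.LENGTHS)
        per_chrom = {c: [] for c in self.LENGTHS}
        for p in parts:
            for c, ivs in p.intervals.items():
                per_chrom[c].extend(ivs)
        from invcoal.intervals import merge, total_length

        for c, L in self.LENGTHS.items():
            assert merge(per_chrom[c]) == [(0, L)]
            assert sum(e - s for s, e in per_chrom[c]) == total_length(per_chrom[c])
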