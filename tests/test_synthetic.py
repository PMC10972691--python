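"""Truth scenarios, dataset generation, and caller-style SV tables."""

import filecmp

import numpy as np
import pytest

from invcoal import mc
from invcoal.likelihood import DemographicParams
from invcoal.synthetic import (
    DEFAULT_CONFIG,
    SVCallNoise,
    generate_dataset,
    generate_sv_calls,
    generate_truth_scenario,
)

MU = 2.8e-9


class TestScenario:
    def test_default_mimics_study_layout(self):
        scen = generate_truth_scenario(seed=1)
        assert len(scen.inversions) == 5
        kinds = sorted(p.kind for p in scen.partitions)
        assert kinds == [
            "X_colinear",
            "X_inversion",
            "autosome_colinear",
            "autosome_inversion",
            "autosome_inversion",
        ]
        assert scen.n_a == 12 and scen.n_b == 9
        # all inversions exceed the consensus filter's 0.5 Mb floor
        assert all(e - s > 500_000 for _, s, e, _ in scen.inversions)

    def test_inversions_older_with_less_migration_than_background(self):
        scen = generate_truth_scenario(seed=1)
        by_kind = {p.kind: scen.params[p.name] for p in scen.partitions}
        col = by_kind["autosome_colinear"]
        for p in scen.partitions:
            if p.kind == "autosome_inversion":
                assert scen.params[p.name].t > col.t
                assert scen.params[p.name].m < col.m
        assert by_kind["X_inversion"].t > by_kind["X_colinear"].t
        assert by_kind["X_inversion"].m < by_kind["X_colinear"].m

    def test_zero_inversions_degenerate_case(self):
        cfg = {**DEFAULT_CONFIG, "inversions": []}
        scen = generate_truth_scenario(cfg, seed=0)
        assert sorted(p.kind for p in scen.partitions) == ["X_colinear", "autosome_colinear"]

    def test_determinism(self):
        a = generate_truth_scenario(seed=3)
        b = generate_truth_scenario(seed=3)
        assert a.provenance() == b.provenance()

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            generate_truth_scenario({**DEFAULT_CONFIG, "chromosomes": [("X", 0)]})
        with pytest.raises(ValueError):
            generate_truth_scenario({**DEFAULT_CONFIG, "n_a": 0})
        bad = {**DEFAULT_CONFIG, "inversions": [("nope", 0, 1000, "A")]}
        with pytest.raises(ValueError):
            generate_truth_scenario(bad)


ONE_CHROM_DIV = {
    "chromosomes": [("2L", 60_000)],
    "x_chromosomes": [],
    "inversions": [],
    "n_a": 1,
    "n_b": 1,
    "demography": {"autosome_colinear": (100_000, 100_000, 200_000, 400_000, 0.0)},
}


class TestDataset:
    def test_byte_identical_regeneration(self, tiny_scenario, tmp_path):
        d1 = generate_dataset(tiny_scenario, max_sim_length=30_000)
        d2 = generate_dataset(tiny_scenario, max_sim_length=30_000)
        p1 = d1.write(tmp_path / "a")
        p2 = d2.write(tmp_path / "b")
        for f in ("synthetic.vcf", "intergenic.bed", "repeats.bed", "truth.json", "samples.tsv"):
            assert filecmp.cmp(p1 / f, p2 / f, shallow=False), f

    def test_zero_mutation_rate_gives_empty_vcf(self):
        cfg = {**ONE_CHROM_DIV, "mu": 0.0}
        scen = generate_truth_scenario(cfg, seed=2)
        ds = generate_dataset(scen, max_sim_length=20_000)
        assert ds.n_sites == 0

    def test_variants_inside_chromosomes_and_diploid(self, tiny_dataset):
        lengths = tiny_dataset.scenario.chrom_lengths
        for row in tiny_dataset.variants.itertuples(index=False):
            assert 0 <= row.pos < lengths[row.chrom]
        assert tiny_dataset.gt.shape[1:] == (5, 2)
        assert (tiny_dataset.gt >= 0).all()  # raw simulated genotypes are called

    def test_divergence_matches_closed_form_under_strict_isolation(self):
        """Under DIV with one diploid per species, mean per-site d_xy over
        replicates approaches 2*mu*(t + 2*Ne_anc) (the analytic expectation
        of cross-species divergence)."""
        expected = 2 * MU * (400_000 + 2 * 200_000)
        vals = []
        for seed in range(40):
            scen = generate_truth_scenario(ONE_CHROM_DIV, seed=seed)
            ds = generate_dataset(scen, max_sim_length=60_000)
            vals.append(ds.pairwise_dxy("A01", "B01"))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se

    def test_within_species_diversity_matches_coalescent_expectation(self):
        """Mean per-site heterozygosity of each species matches
        2*mu*E[pairwise coalescence time] at >= 1e4 blocks (3 MC SE)."""
        params = DemographicParams(300_000, 150_000, 600_000, 1_000_000, 0.0, "DIV")
        counts = mc.sample_block_counts(params, 10_000, 64, MU, seed=17)
        for ne, cols in ((params.ne_a, (0, 2)), (params.ne_b, (1, 2))):
            lam = 1.0 / (2 * ne)
            e_t = 2 * ne + (2 * params.ne_anc - 2 * ne) * np.exp(-lam * params.t)
            expected = 2 * MU * e_t * 64  # per-block het count
            per_block = counts[:, cols[0]] + counts[:, cols[1]]
            se = per_block.std(ddof=1) / np.sqrt(len(per_block))
            assert abs(per_block.mean() - expected) < 3 * se

    def test_older_inversions_show_higher_dxy(self):
        """Partitions simulated with older T yield higher mean d_xy than the
        colinear background (checked over 20 replicate datasets)."""
        cfg = {
            "chromosomes": [("4", 100_000)],
            "x_chromosomes": [],
            "inversions": [("4", 40_000, 90_000, "B")],
            "n_a": 1,
            "n_b": 1,
            "demography": {
                "autosome_colinear": (150_000, 150_000, 300_000, 300_000, 0.0),
                "4_inv": (150_000, 150_000, 300_000, 1_200_000, 0.0),
            },
        }
        col, inv = [], []
        for seed in range(20):
            scen = generate_truth_scenario(cfg, seed=seed)
            ds = generate_dataset(scen, max_sim_length=30_000)
            is_inv = (ds.variants.pos >= 40_000) & (ds.variants.pos < 90_000)
            gt = ds.gt
            for sel, acc in ((~is_inv, col), (is_inv, inv)):
                ga, gb = gt[sel.to_numpy(), 0, :], gt[sel.to_numpy(), 1, :]
                diffs = (ga[:, :, None] != gb[:, None, :]).mean(axis=(1, 2)).sum()
                acc.append(diffs / 30_000)
        assert np.mean(inv) > np.mean(col)


class TestSVCalls:
    def test_noise_free_tables_contain_exact_truth(self, tiny_scenario):
        t1, t2 = generate_sv_calls(tiny_scenario, SVCallNoise(), seed=0)
        for tab in (t1, t2):
            for chrom, s, e, carrier in tiny_scenario.inversions:
                sub = tab[(tab.chrom == chrom) & (tab.start == s) & (tab.end == e)]
                assert set(sub["sample"]) == set(tiny_scenario.samples[carrier])
            n_expected = sum(
                len(tiny_scenario.samples[c]) for _, _, _, c in tiny_scenario.inversions
            )
            assert len(tab) == n_expected

    def test_total_false_negative_rate_empties_tables(self, tiny_scenario):
        t1, t2 = generate_sv_calls(tiny_scenario, SVCallNoise(fn_rate=1.0), seed=0)
        assert t1.empty and t2.empty

    def test_jitter_bounded_and_reproducible(self, tiny_scenario):
        noise = SVCallNoise(jitter_sd=200.0)
        t1a, _ = generate_sv_calls(tiny_scenario, noise, seed=4)
        t1b, _ = generate_sv_calls(tiny_scenario, noise, seed=4)
        assert t1a.equals(t1b)
        devs = []
        for row in t1a.itertuples(index=False):
            cands = [
                (abs(row.start - s), abs(row.end - e))
                for c, s, e, _ in tiny_scenario.inversions
                if c == row.chrom
            ]
            devs.append(min(max(ds, de) for ds, de in cands))
        assert max(devs) < 4 * 200.0  # Gaussian jitter stays within a few SD
        assert np.std([d for d in devs]) > 0  # jitter actually applied

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            SVCallNoise(fn_rate=1.5)
        with pytest.raises(ValueError):
            SVCallNoise(jitter_sd=-1)


class TestPipelineIntegration:
    def test_dataset_directory_tallies_every_partition(self, tiny_dataset_dir):
        from invcoal.pipeline import tally_dataset_directory

        res = tally_dataset_directory(tiny_dataset_dir, max_pairs=2)
        kinds = set(res)
        assert "autosome_colinear" in kinds and "X_inv" in kinds and "X_colinear" in kinds
        for name, (tally, bc) in res.items():
            assert tally.n_blocks == len(bc) > 0
            assert tally.block_length == 64
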