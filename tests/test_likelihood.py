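"""The DIV/IM likelihood core: probability tables, conversions, fitting."""

import numpy as np
import pytest

from invcoal.blocks import tally_from_block_counts
from invcoal.likelihood import (
    DemographicParams,
    bsfs_probabilities,
    bsfs_probabilities_mc,
    composite_loglik,
    compare_models,
    fit_model,
    gc_initiation_rate,
    migrant_fraction,
    ne_from_theta,
    to_absolute,
    to_scaled,
)
from invcoal import mc

SYM_IM = DemographicParams(735e3, 377e3, 1388e3, 2526e3, 1.29e-8, "IM_AB")
INTRA_DIV = DemographicParams(1087e3, 1560e3, 858e3, 210e3, 0.0, "DIV")


class TestParams:
    def test_div_requires_zero_migration(self):
        with pytest.raises(ValueError):
            DemographicParams(1e5, 1e5, 1e5, 1e5, 1e-8, "DIV")

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            DemographicParams(0, 1e5, 1e5, 1e5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            DemographicParams(np.nan, 1e5, 1e5, 1e5)


class TestConversions:
    def test_absolute_time_from_scaled(self):
        # T = 3.3501 coalescent units of 2*Ne with Ne = 377,000 -> ~2.526 My
        assert to_absolute(3.3501, 377_000, 1.0) == pytest.approx(2_525_975, rel=1e-6)
        assert to_absolute(0.0, 377_000) == 0.0

    def test_round_trip(self):
        s = to_scaled(SYM_IM)
        assert to_absolute(s["T"], s["ne_ref"]) == pytest.approx(SYM_IM.t)

    def test_ne_from_theta(self):
        assert ne_from_theta(4 * 2.8e-9 * 377_000) == pytest.approx(377_000)

    def test_scaled_migration_rate(self):
        assert to_scaled(SYM_IM)["M"] == pytest.approx(2 * 377e3 * 1.29e-8)

    def test_migrant_fraction(self):
        T = 2_526_000 / (2 * 377_000)
        assert migrant_fraction(T, 0.0097) == pytest.approx(0.032, abs=5e-4)
        assert migrant_fraction(5.0, 0.0) == 0.0
        assert migrant_fraction(1.0, np.log(2)) == pytest.approx(0.5)

    def test_gc_initiation_rate(self):
        assert gc_initiation_rate(1.4e-5, 390) == pytest.approx(3.59e-8, rel=5e-3)
        assert gc_initiation_rate(0.123, 1) == 0.123
        assert gc_initiation_rate(0.0, 390) == 0.0


GRID_QUICK = [
    SYM_IM,
    INTRA_DIV,
    DemographicParams(5e5, 2e5, 1e6, 2e6, 2e-6, "IM_BA"),
]


class TestProbabilityTable:
    @pytest.mark.parametrize("params", GRID_QUICK)
    def test_normalization(self, params):
        tab = bsfs_probabilities(params, kmax=2)
        assert tab.total() == pytest.approx(1.0, abs=1e-8)
        assert (tab.probs >= -1e-12).all()

    def test_zero_mutation_rate_limit(self):
        tab = bsfs_probabilities(INTRA_DIV, kmax=2, mu=0.0)
        assert tab.probs[0, 0, 0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_zero_split_time(self):
        tab = bsfs_probabilities(DemographicParams(2e5, 2e5, 2e5, 0.0), kmax=1)
        assert tab.total() == pytest.approx(1.0, abs=1e-8)

    def test_matches_mc_oracle(self):
        """Exact table vs the independent Gillespie sampler (quick version;
        the full 12-point grid runs in the acceptance suite)."""
        for i, params in enumerate((INTRA_DIV, SYM_IM)):
            exact = bsfs_probabilities(params, kmax=2)
            est, se = bsfs_probabilities_mc(
                params, kmax=2, n_genealogies=100_000, seed=11 + i, return_se=True
            )
            sel = se > 1e-12
            z = np.abs(est.probs[sel] - exact.probs[sel]) / se[sel]
            assert z.max() < 4.0

    def test_fixed_count_monotone_in_split_time(self):
        """At m = 0 the expected fixed-difference count per block grows with T."""
        vals = np.arange(7.0)
        expectations = []
        for t in (1e5, 5e5, 2e6, 8e6):
            tab = bsfs_probabilities(DemographicParams(3e5, 3e5, 3e5, t), kmax=5)
            expectations.append(float(np.einsum("abcd,d->", tab.probs, vals)))
        assert all(b > a for a, b in zip(expectations, expectations[1:]))

    def test_label_swap_symmetry(self):
        """Swapping population labels and the migration direction mirrors the
        table in its hetA/hetB axes."""
        p1 = DemographicParams(6e5, 25e4, 9e5, 1.5e6, 4e-8, "IM_AB")
        p2 = DemographicParams(25e4, 6e5, 9e5, 1.5e6, 4e-8, "IM_BA")
        t1 = bsfs_probabilities(p1, kmax=2)
        t2 = bsfs_probabilities(p2, kmax=2)
        assert np.allclose(t1.probs, t2.probs.transpose(1, 0, 2, 3), atol=1e-10)


class _FloatTally:
    """Duck-typed tally carrying expected (fractional) counts."""

    def __init__(self, counts, kmax, block_length):
        self.counts = counts
        self.kmax = kmax
        self.block_length = block_length
        self.n_blocks = float(np.sum(counts))


class TestCompositeLikelihood:
    def test_single_block(self):
        tab = bsfs_probabilities(INTRA_DIV, kmax=2)
        counts = np.zeros_like(tab.probs)
        counts[0, 0, 0, 1] = 1
        t = _FloatTally(counts, 2, 64)
        assert composite_loglik(t, tab) == pytest.approx(np.log(tab.probs[0, 0, 0, 1]))

    def test_linearity(self):
        tab = bsfs_probabilities(INTRA_DIV, kmax=2)
        counts = np.round(tab.probs * 1000)
        a = composite_loglik(_FloatTally(counts, 2, 64), tab)
        b = composite_loglik(_FloatTally(2 * counts, 2, 64), tab)
        assert b == pytest.approx(2 * a)

    def test_zero_probability_config_gives_minus_inf(self):
        tab = bsfs_probabilities(INTRA_DIV, kmax=1, mu=0.0)
        counts = np.zeros((3, 3, 3, 3))
        counts[2, 2, 2, 2] = 1
        assert composite_loglik(_FloatTally(counts, 1, 64), tab) == -np.inf

    def test_profile_fit_recovers_generating_time_from_expected_counts(self):
        """Maximising lnCL on a tally of exact expected counts returns the
        generating parameter (self-consistency of the likelihood)."""
        truth = INTRA_DIV
        tab = bsfs_probabilities(truth, kmax=2)
        tally = _FloatTally(tab.probs * 1e5, 2, 64)
        fit = fit_model(
            tally,
            "DIV",
            fixed={"ne_a": truth.ne_a, "ne_b": truth.ne_b, "ne_anc": truth.ne_anc},
            start_params=DemographicParams(truth.ne_a, truth.ne_b, truth.ne_anc, 4e5),
            n_starts=1,
        )
        assert fit.params.t == pytest.approx(truth.t, rel=5e-3)


@pytest.fixture(scope="module")
def small_tally():
    counts = mc.sample_block_counts(SYM_IM, 3000, 64, 2.8e-9, seed=21)
    return tally_from_block_counts(counts, 2, 64)


class TestFitting:
    def test_im_nests_div(self, small_tally):
        f_div = fit_model(small_tally, "DIV", n_starts=1, maxfev=600, fatol=1e-3)
        start_im = DemographicParams(
            f_div.params.ne_a,
            f_div.params.ne_b,
            f_div.params.ne_anc,
            f_div.params.t,
            1e-10,
            "IM_AB",
        )
        f_im = fit_model(
            small_tally, "IM_AB", n_starts=1, maxfev=800, fatol=1e-3, start_params=start_im
        )
        assert f_im.lnCL >= f_div.lnCL - 0.1
        cmp = compare_models(f_im, f_div)
        assert cmp["delta_lnCL"] >= -0.1

    def test_compare_models_identical_fits(self, small_tally):
        f = fit_model(small_tally, "DIV", n_starts=1, maxfev=300, fatol=1e-2)
        assert compare_models(f, f)["delta_lnCL"] == 0.0

    def test_empty_tally_rejected(self):
        empty = tally_from_block_counts(np.empty((0, 4), dtype=int), 2, 64)
        with pytest.raises(ValueError):
            fit_model(empty, "DIV")

    def test_seed_reproducibility(self, small_tally):
        f1 = fit_model(small_tally, "DIV", n_starts=2, seed=3, maxfev=300, fatol=1e-2)
        f2 = fit_model(small_tally, "DIV", n_starts=2, seed=3, maxfev=300, fatol=1e-2)
        assert f1.params == f2.params and f1.lnCL == f2.lnCL


class TestMCSampler:
    def test_deterministic_given_seed(self):
        a = mc.sample_class_lengths(SYM_IM, 100, seed=5)
        b = mc.sample_class_lengths(SYM_IM, 100, seed=5)
        assert (a == b).all()

    def test_lengths_positive_and_finite(self):
        L = mc.sample_class_lengths(INTRA_DIV, 500, seed=1)
        assert np.isfinite(L).all() and (L >= 0).all()
        # a fixed difference requires the (2,0)/(0,2) class to have length
        assert L[:, 3].mean() > 0
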