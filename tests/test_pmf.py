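"""Boltzmann inversion, pooling, WHAM joining, barriers, block errors."""

import numpy as np
import pytest

from loopstate.pmf import (
    FreeEnergyProfile,
    Histogram1D,
    ThermoConstants,
    UmbrellaWindow,
    barrier_height,
    bias_energy,
    block_errors,
    histogram_rc,
    pmf_from_density,
    pool_pmf,
    wham_join,
)
from loopstate.synthetic import double_well, gen_umbrella_samples, sample_rc

RT = ThermoConstants().rt  # 0.59250... kcal/mol at 298.16 K


class TestHistogram:
    def test_single_bin_density(self):
        """100 identical samples in a 0.2 Å bin give density 5 /Å."""
        h = histogram_rc([1.0] * 100, 0.2, (0.0, 2.0))
        assert h.density.max() == pytest.approx(5.0)
        assert h.density.sum() * h.width == pytest.approx(1.0)

    def test_uniform_samples(self):
        rng = np.random.default_rng(0)
        h = histogram_rc(rng.uniform(0, 1, 100_000), 0.1, (0.0, 1.0))
        assert np.allclose(h.density, 1.0, atol=0.05)  # ~3 binomial sigmas

    def test_bad_width(self):
        with pytest.raises(ValueError):
            histogram_rc([1.0], 0.0)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            histogram_rc([])


class TestPmfFromDensity:
    def test_flat_density_flat_profile(self):
        h = Histogram1D(np.arange(0, 1.05, 0.1), np.full(10, 7.0))
        prof = pmf_from_density(h)
        assert np.allclose(prof.w, 0.0)

    def test_two_bin_ratio_gives_rt_ln2(self):
        """Density ratio 2 at 298.16 K -> dW = RT ln 2 = 0.4107 kcal/mol."""
        h = Histogram1D(np.array([0.0, 0.2, 0.4]), np.array([200.0, 100.0]))
        prof = pmf_from_density(h)
        dw = prof.w[1] - prof.w[0]
        assert dw == pytest.approx(RT * np.log(2), abs=1e-12)
        assert dw == pytest.approx(0.4107, abs=5e-5)

    def test_single_bin_masked_elsewhere(self):
        h = Histogram1D(np.arange(0, 1.05, 0.1), np.eye(1, 10, 4).ravel() * 9)
        prof = pmf_from_density(h)
        assert prof.w[prof.mask] == pytest.approx(0.0)
        assert np.isnan(prof.w[~prof.mask]).all()

    def test_reference_is_min_zero(self):
        rng = np.random.default_rng(3)
        prof = pmf_from_density(histogram_rc(rng.normal(2, 0.5, 10000), 0.2))
        assert np.nanmin(prof.w[prof.mask]) == pytest.approx(0.0)


class TestPoolPmf:
    def test_three_copies_same_profile(self):
        s = np.random.default_rng(1).normal(3, 0.7, 5000)
        one = pool_pmf([s], bin_width=0.2)
        three = pool_pmf([s, s, s], bin_width=0.2)
        np.testing.assert_allclose(one.w[one.mask], three.w[three.mask])

    def test_pooled_equals_concatenated(self):
        rng = np.random.default_rng(2)
        a, b, c = (rng.normal(m, 0.5, 3000) for m in (0.0, 2.0, 5.0))
        pooled = pool_pmf([a, b, c], bin_width=0.2, rc_range=(-4, 9))
        concat = pmf_from_density(
            histogram_rc(np.concatenate([a, b, c]), 0.2, (-4, 9))
        )
        np.testing.assert_array_equal(pooled.w[pooled.mask], concat.w[concat.mask])

    def test_disjoint_supports_union(self):
        prof = pool_pmf(
            [np.full(10, 0.5), np.full(10, 6.5)], bin_width=0.2, rc_range=(0, 7)
        )
        c = prof.centers[prof.mask]
        assert (c < 1).any() and (c > 6).any()

    def test_empty_union(self):
        with pytest.raises(ValueError):
            pool_pmf([[], []])


class TestBiasEnergy:
    def test_zero_at_center(self):
        w = UmbrellaWindow(1.5, 10.0, [])
        assert bias_energy(1.5, w) == 0.0

    def test_half_k_convention(self):
        """k = 10, displacement 0.2 Å -> 1/2 * 10 * 0.04 = 0.2 kcal/mol."""
        w = UmbrellaWindow(0.0, 10.0, [])
        assert bias_energy(0.2, w) == pytest.approx(0.2)

    def test_full_k_convention_switch(self):
        w = UmbrellaWindow(0.0, 10.0, [], half_k_convention=False)
        assert bias_energy(0.2, w) == pytest.approx(0.4)

    def test_zero_k(self):
        w = UmbrellaWindow(0.0, 0.0, [])
        assert np.all(bias_energy(np.linspace(-5, 5, 11), w) == 0.0)


class TestWhamJoin:
    def test_single_unbiased_window_reduces_to_inversion(self):
        s = sample_rc(double_well(barrier=1.6), n=50_000, seed=5)
        prof = wham_join([UmbrellaWindow(0.0, 0.0, s)], bin_width=0.2,
                         rc_range=(-3.0, 8.0))
        direct = pmf_from_density(histogram_rc(s, 0.2, (-3.0, 8.0)))
        np.testing.assert_allclose(
            prof.w[prof.mask], direct.w[direct.mask], atol=1e-9
        )

    def test_two_identical_unbiased_windows(self):
        s = sample_rc(double_well(barrier=1.6), n=20_000, seed=6)
        one = wham_join([UmbrellaWindow(0.0, 0.0, s)], rc_range=(-3, 8))
        two = wham_join(
            [UmbrellaWindow(0.0, 0.0, s), UmbrellaWindow(1.0, 0.0, s)],
            rc_range=(-3, 8),
        )
        np.testing.assert_allclose(one.w[one.mask], two.w[two.mask], atol=1e-9)

    def test_all_unbiased_equals_pooling_exactly(self):
        rng = np.random.default_rng(7)
        sets = [rng.normal(m, 0.8, 10_000) for m in (1.0, 3.0, 5.0)]
        wham = wham_join(
            [UmbrellaWindow(0.0, 0.0, s) for s in sets],
            bin_width=0.2, rc_range=(-4, 9),
        )
        pooled = pool_pmf(sets, bin_width=0.2, rc_range=(-4, 9))
        np.testing.assert_allclose(
            wham.w[wham.mask], pooled.w[pooled.mask], atol=1e-9
        )

    def test_umbrella_recovery_within_tolerance(self):
        """k = 10 kcal/(mol Å²) windows at 0.2 Å spacing recover the true
        double-well within 0.15 kcal/mol over the scanned interval."""
        spec = double_well(barrier=3.2)
        centers = np.arange(-2.8, 7.8 + 1e-9, 0.2)
        wins = gen_umbrella_samples(spec, centers, k=10.0,
                                    n_per_window=3000, seed=11)
        prof = wham_join(wins, bin_width=0.2, rc_range=(-3.0, 8.0))
        c, w = prof.sampled()
        inside = (c >= centers[0]) & (c <= centers[-1])
        wt = spec(c[inside])
        wt -= wt.min()
        assert np.abs(w[inside] - wt).max() <= 0.15

    def test_window_order_invariance(self):
        spec = double_well(barrier=1.6)
        wins = gen_umbrella_samples(spec, [2.0, 2.4, 2.8], k=10.0,
                                    n_per_window=2000, seed=9)
        a = wham_join(wins, rc_range=(-3, 8))
        b = wham_join(wins[::-1], rc_range=(-3, 8))
        np.testing.assert_allclose(a.w[a.mask], b.w[b.mask], atol=1e-6)

    def test_non_overlapping_windows_error(self):
        w1 = UmbrellaWindow(0.0, 10.0, np.random.default_rng(0).normal(0, 0.1, 500))
        w2 = UmbrellaWindow(6.0, 10.0, np.random.default_rng(1).normal(6, 0.1, 500))
        with pytest.raises(ValueError, match="no\\s+sampled bins|share no"):
            wham_join([w1, w2], bin_width=0.2)

    def test_convergence_metadata(self):
        s = sample_rc(double_well(), n=1000, seed=1)
        prof = wham_join([UmbrellaWindow(0.0, 0.0, s)])
        assert prof.meta["iterations"] >= 1
        assert prof.meta["residual"] < 1e-7


class TestBarrierHeight:
    def _profile(self, w_values, centers=None):
        w = np.asarray(w_values, dtype=float)
        c = centers if centers is not None else np.arange(len(w), dtype=float)
        return FreeEnergyProfile(c, w, np.ones(len(w), dtype=bool))

    def test_flat_profile_zero_barrier(self):
        prof = self._profile(np.zeros(10))
        out = barrier_height(prof, (0, 2), (7, 9))
        assert out["barrier"] == pytest.approx(0.0)

    def test_asymmetric_wells_measured_from_shallower(self):
        """Wells at 0 and 1 kcal/mol, top at 3: barrier = 3 - 1 = 2."""
        prof = self._profile([0.0, 1.5, 3.0, 1.8, 1.0])
        out = barrier_height(prof, (0, 0.5), (3.5, 4.5))
        assert out["barrier"] == pytest.approx(2.0)
        assert out["wells"]["a"] == (0.0, 0.0)
        assert out["wells"]["b"] == (4.0, 1.0)

    def test_synthetic_double_well_ground_truth(self):
        """Recovered barrier matches the generator setting within binning
        error for a deterministic (noise-free) tabulated profile."""
        for b in (1.6, 3.2):
            spec = double_well(barrier=b)
            w = spec(np.arange(-2.9, 7.9, 0.2))
            prof = self._profile(w, np.arange(-2.9, 7.9, 0.2))
            out = barrier_height(prof, (-1.5, 1.0), (5.0, 7.0))
            assert out["barrier"] == pytest.approx(b, abs=RT * 0.2)

    def test_overlapping_wells_error(self):
        prof = self._profile(np.zeros(10))
        with pytest.raises(ValueError):
            barrier_height(prof, (0, 5), (4, 9))

    def test_no_bins_in_well_error(self):
        prof = self._profile(np.zeros(5))
        with pytest.raises(ValueError):
            barrier_height(prof, (100, 101), (0, 1))


class TestBlockErrors:
    def test_identical_blocks_zero_error(self):
        s = np.tile(np.repeat([1.1, 2.1], 50), 3)
        prof = block_errors(s, n_blocks=3, bin_width=1.0, rc_range=(1, 3))
        assert np.allclose(prof.errors[prof.mask], 0.0)

    def test_two_block_ratio_formula(self):
        """Blocks with density ratio 2 in a bin give error |dW|/2 there."""
        block1 = np.concatenate([np.full(200, 0.5), np.full(100, 1.5)])
        block2 = np.concatenate([np.full(100, 0.5), np.full(200, 1.5)])
        prof = block_errors(
            np.concatenate([block1, block2]), n_blocks=2,
            bin_width=1.0, rc_range=(0, 2),
        )
        # per-bin W difference between the equal-size blocks
        w1 = -RT * np.log(np.array([200, 100]) / 300 / 1.0)
        w2 = -RT * np.log(np.array([100, 200]) / 300 / 1.0)
        expected = np.abs(w2 - w1) / 2.0
        np.testing.assert_allclose(prof.errors[prof.mask], expected, atol=1e-12)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_errors([1.0, 2.0], n_blocks=1)

    def test_fewer_samples_than_blocks(self):
        with pytest.raises(ValueError):
            block_errors([1.0, 2.0], n_blocks=3)
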