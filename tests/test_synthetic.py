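"""Generators: time grids, IRFs, decays, global sets and CD couplets."""

import numpy as np
import pytest

from excispec import synthetic as syn
from excispec.exceptions import ConfigurationError
from excispec.tcspc import DecayCurve

from .oracles import direct_convolution, multiexp


class TestTimeGrid:
    def test_bin_width_4096_50ns(self):
        grid = syn.make_time_grid(4096, 50.0)
        assert grid.size == 4096
        assert np.allclose(np.diff(grid), 50.0 / 4096)

    def test_bin_width_64_6p4ns(self):
        grid = syn.make_time_grid(64, 6.4)
        assert np.allclose(np.diff(grid), 0.1)

    @pytest.mark.parametrize("n,window", [(0, 50.0), (63, 50.0), (4096, 0.0),
                                          (4096, -1.0)])
    def test_invalid_configurations(self, n, window):
        with pytest.raises(ConfigurationError):
            syn.make_time_grid(n, window)

    def test_spans_window(self):
        grid = syn.make_time_grid(128, 12.8)
        assert grid[0] > 0 and grid[-1] < 12.8


class TestIRF:
    def test_peak_position(self):
        grid = syn.make_time_grid(4096, 50.0)
        irf = syn.make_irf(syn.IRFSpec(fwhm=0.080, t0=2.0), grid)
        assert np.argmax(irf.counts) == np.argmin(np.abs(grid - 2.0))

    def test_unit_area(self):
        grid = syn.make_time_grid(1024, 25.0)
        irf = syn.make_irf(syn.IRFSpec(fwhm=0.080, t0=2.0), grid)
        assert irf.counts.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(irf.counts >= 0)

    def test_measured_fwhm_within_one_bin(self):
        # measure half-maximum crossings of the generated histogram
        grid = syn.make_time_grid(4096, 50.0)
        dt = grid[1] - grid[0]
        irf = syn.make_irf(syn.IRFSpec(fwhm=0.200, t0=5.0), grid)
        y = irf.counts
        half = y.max() / 2.0
        above = np.nonzero(y >= half)[0]
        left = np.interp(half, y[above[0] - 1: above[0] + 1],
                         grid[above[0] - 1: above[0] + 1])
        right = np.interp(half, y[above[-1] + 1: above[-1] - 1: -1],
                          grid[above[-1] + 1: above[-1] - 1: -1])
        assert abs((right - left) - 0.200) <= dt

    def test_too_narrow_fwhm_errors(self):
        grid = syn.make_time_grid(128, 50.0)  # ~390 ps bins
        with pytest.raises(ConfigurationError):
            syn.make_irf(syn.IRFSpec(fwhm=0.010, t0=2.0), grid)

    def test_huge_fwhm_warns(self):
        grid = syn.make_time_grid(256, 10.0)
        with pytest.warns(UserWarning):
            syn.make_irf(syn.IRFSpec(fwhm=8.0, t0=5.0), grid)

    def test_t0_outside_window_errors(self):
        grid = syn.make_time_grid(256, 10.0)
        with pytest.raises(ConfigurationError):
            syn.make_irf(syn.IRFSpec(fwhm=0.08, t0=15.0), grid)

    def test_invalid_spec(self):
        with pytest.raises(ConfigurationError):
            syn.IRFSpec(fwhm=-1.0)
        with pytest.raises(ConfigurationError):
            syn.IRFSpec(shape="lorentzian")


class TestDecayComponents:
    def test_amplitudes_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            syn.DecayComponents([1.0, 2.0], [0.5, 0.6])

    def test_lifetimes_must_increase(self):
        with pytest.raises(ConfigurationError):
            syn.DecayComponents([2.0, 1.0], [0.5, 0.5])

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.DecayComponents([1.0, 2.0], [1.2, -0.2])

    def test_presets_valid(self):
        for name, (comps, desc) in syn.PRESETS.items():
            assert comps.n_components == 4, name
            assert desc
            np.testing.assert_allclose(comps.afactors.sum(axis=1), 1.0,
                                       atol=1e-9)

    def test_preset_paper_anchors(self):
        assert syn.PRESETS["duplex"][0].afactors[0][0] == pytest.approx(0.85)
        dflap = syn.PRESETS["double_flap"][0]
        assert dflap.afactors[0][0] == pytest.approx(0.75)
        assert dflap.lifetimes[0] == pytest.approx(0.060)
        y40a = syn.PRESETS["y40a_substrate"][0]
        assert y40a.afactors[0][:3] == pytest.approx([0.58, 0.30, 0.10])
        prod = syn.PRESETS["y40a_product"][0]
        assert prod.afactors[0][3] == pytest.approx(0.40)
        assert prod.lifetimes[3] == pytest.approx(9.0)


class TestSimulateDecay:
    def test_pure_exponential_ratio(self, delta_irf_256, grid_256):
        comps = syn.DecayComponents([10.0], [1.0])
        mu = syn.decay_expectation(comps, delta_irf_256, 1e4)
        dt = grid_256[1] - grid_256[0]
        k = int(round(10.0 / dt))
        ratio = mu[k] / mu[0]
        assert ratio == pytest.approx(np.exp(-k * dt / 10.0), rel=1e-9)

    def test_seed_determinism(self, irf_256, duplex_components):
        a = syn.simulate_decay(duplex_components, irf_256, 1e4, seed=1)
        b = syn.simulate_decay(duplex_components, irf_256, 1e4, seed=1)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = syn.simulate_decay(duplex_components, irf_256, 1e4, seed=2)
        assert not np.array_equal(a.counts, c.counts)

    def test_expectation_matches_direct_convolution(self, irf_256, grid_256):
        comps = syn.DecayComponents([0.2, 1.0, 3.0, 8.0],
                                    [0.4, 0.3, 0.2, 0.1])
        mu = syn.decay_expectation(comps, irf_256, 1e4)
        d = multiexp(grid_256, comps.lifetimes, comps.afactors[0])
        expected = direct_convolution(irf_256.counts / irf_256.counts.sum(), d)
        expected *= 1e4 / expected.max()
        assert np.max(np.abs(mu - expected)) / expected.max() < 1e-10

    def test_peak_counts_scaling(self, irf_256, duplex_components):
        mu = syn.decay_expectation(duplex_components, irf_256, 5000.0)
        assert mu.max() == pytest.approx(5000.0)

    def test_background_added(self, irf_256, duplex_components):
        mu0 = syn.decay_expectation(duplex_components, irf_256, 1e4, 0.0)
        mu5 = syn.decay_expectation(duplex_components, irf_256, 1e4, 5.0)
        np.testing.assert_allclose(mu5 - mu0, 5.0, atol=1e-9)

    def test_poisson_mean_property(self, irf_256, duplex_components):
        mu = syn.decay_expectation(duplex_components, irf_256, 1e4)
        k = int(np.argmax(mu))
        n_seeds = 200
        draws = [syn.simulate_decay(duplex_components, irf_256, 1e4,
                                    seed=s).counts[k]
                 for s in range(n_seeds)]
        assert abs(np.mean(draws) - mu[k]) <= 3 * np.sqrt(mu[k] / n_seeds)

    def test_convolution_linearity(self, irf_256, grid_256):
        two = syn.DecayComponents([0.5, 5.0], [0.3, 0.7])
        basisA = syn.decay_expectation(syn.DecayComponents([0.5], [1.0]),
                                       irf_256, 1e4)
        basisB = syn.decay_expectation(syn.DecayComponents([5.0], [1.0]),
                                       irf_256, 1e4)
        # undo the per-curve peak scaling to compare at identical scaling
        from excispec.tcspc import decay_basis
        cols = decay_basis(grid_256, two.lifetimes, irf_256.counts)
        combined = cols @ two.afactors[0]
        summed = 0.3 * cols[:, 0] + 0.7 * cols[:, 1]
        assert np.max(np.abs(combined - summed)) / combined.max() < 1e-12

    def test_low_peak_counts_rejected(self, irf_256, duplex_components):
        with pytest.raises(ConfigurationError):
            syn.simulate_decay(duplex_components, irf_256, peak_counts=50)

    def test_too_short_lifetime_rejected(self, irf_256):
        dt = irf_256.bin_width
        comps = syn.DecayComponents([dt * 1e-4, 1.0], [0.5, 0.5])
        with pytest.raises(ConfigurationError):
            syn.simulate_decay(comps, irf_256, 1e4)


class TestGlobalSet:
    def test_shared_amplitudes_proportional_expectations(self, irf_256,
                                                         duplex_components):
        mu = syn.decay_expectation(duplex_components, irf_256, 1e4)
        curves = syn.simulate_global_set(duplex_components, irf_256,
                                         [370.0, 380.0, 390.0], 1e4, seed=3)
        assert len(curves) == 3
        # same expectation -> equal within Poisson scatter, grossly
        for c in curves:
            assert abs(c.counts.sum() - mu.sum()) < 6 * np.sqrt(mu.sum())

    def test_per_wavelength_amplitudes_differ_in_shape(self, irf_256):
        comps = syn.DecayComponents(
            [0.2, 5.0], [[0.9, 0.1], [0.1, 0.9]])
        mus = [syn.decay_expectation(comps, irf_256, 1e4, curve_index=j)
               for j in range(2)]
        n1 = mus[0] / mus[0].sum()
        n2 = mus[1] / mus[1].sum()
        assert np.max(np.abs(n1 - n2)) > 1e-4

    def test_different_seeds_same_expectation(self, irf_256,
                                              duplex_components):
        a = syn.simulate_global_set(duplex_components, irf_256, [370.0],
                                    1e4, seed=5)[0]
        b = syn.simulate_global_set(duplex_components, irf_256, [370.0],
                                    1e4, seed=6)[0]
        assert not np.array_equal(a.counts, b.counts)
        mu = syn.decay_expectation(duplex_components, irf_256, 1e4)
        # both are Poisson around the identical expectation
        for c in (a, b):
            assert abs(c.counts.sum() - mu.sum()) < 6 * np.sqrt(mu.sum())

    def test_wavelength_substreams_differ(self, irf_256, duplex_components):
        curves = syn.simulate_global_set(duplex_components, irf_256,
                                         [370.0, 380.0], 1e4, seed=1)
        assert not np.array_equal(curves[0].counts, curves[1].counts)

    def test_empty_wavelengths_error(self, irf_256, duplex_components):
        with pytest.raises(ConfigurationError):
            syn.simulate_global_set(duplex_components, irf_256, [], 1e4)

    def test_mismatched_afactor_lists_error(self, irf_256):
        comps = syn.DecayComponents([0.2, 5.0], [[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ConfigurationError):
            syn.simulate_global_set(comps, irf_256, [370.0, 380.0, 390.0], 1e4)


class TestCDSimulation:
    def test_fully_unpaired_zero_spectrum(self):
        spec = syn.CDCoupletSpec(unpaired_fraction=1.0)
        s = syn.simulate_cd_spectrum(spec)
        np.testing.assert_array_equal(s.values, 0.0)

    def test_mixture_amplitude_ratio_83pct(self):
        paired = syn.simulate_cd_spectrum(syn.CDCoupletSpec(unpaired_fraction=0.0))
        mostly = syn.simulate_cd_spectrum(
            syn.CDCoupletSpec(unpaired_fraction=0.83))
        i330 = np.argmin(np.abs(paired.wavelengths - 330.0))
        assert mostly.values[i330] / paired.values[i330] == pytest.approx(
            0.17, abs=1e-12)

    def test_red_lobe_peak_position(self):
        s = syn.simulate_cd_spectrum(syn.CDCoupletSpec(unpaired_fraction=0.0))
        peak = s.wavelengths[np.argmax(np.abs(s.values))]
        assert abs(peak - 326.0) <= 0.5

    def test_mixture_linearity(self):
        grid = syn.default_cd_grid()
        f = 0.37
        sf = syn.simulate_cd_spectrum(syn.CDCoupletSpec(unpaired_fraction=f), grid)
        s0 = syn.simulate_cd_spectrum(syn.CDCoupletSpec(unpaired_fraction=0.0), grid)
        s1 = syn.simulate_cd_spectrum(syn.CDCoupletSpec(unpaired_fraction=1.0), grid)
        np.testing.assert_allclose(
            sf.values, f * s1.values + (1 - f) * s0.values, atol=1e-14)

    def test_noise_seed_determinism(self):
        spec = syn.CDCoupletSpec(noise_sd=0.1)
        a = syn.simulate_cd_spectrum(spec, seed=9)
        b = syn.simulate_cd_spectrum(spec, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_grid_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            syn.simulate_cd_spectrum(syn.CDCoupletSpec(),
                                     grid=np.arange(250.0, 480.0, 0.5))

    def test_invalid_spec(self):
        with pytest.raises(ConfigurationError):
            syn.CDCoupletSpec(unpaired_fraction=1.5)
        with pytest.raises(ConfigurationError):
            syn.CDCoupletSpec(lobe_amplitudes=(3.0, 4.0))

    def test_mdeg_units_scaling(self):
        de = syn.simulate_cd_spectrum(syn.CDCoupletSpec(), units="delta_epsilon")
        md = syn.simulate_cd_spectrum(syn.CDCoupletSpec(), units="mdeg",
                                      conc_2ap=2e-5, pathlength=1.0)
        np.testing.assert_allclose(md.values, de.values * 32980.0 * 2e-5,
                                   rtol=1e-12)
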