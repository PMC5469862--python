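"""Depth-profile statistics and the flux/current arithmetic."""

import numpy as np
import pytest

from ramanion.profile import (D_NA_CM2_S, FARADAY_C_PER_MOL, DeltaProfile,
                              GradientFit, PlateauNotFoundError, ZProfile,
                              average_profiles, delta_profile,
                              estimate_thickness, fit_gradient,
                              mean_concentration_change, per_depth_ttest,
                              short_circuit_current, sodium_flux)
from ramanion.synthetic import CellScanSpec, make_cell_zscan


def _profile(z, r_cells):
    r_cells = np.atleast_2d(r_cells)
    sd = r_cells.std(axis=0, ddof=1) if r_cells.shape[0] > 1 else np.zeros(z.size)
    return ZProfile(np.asarray(z, float), r_cells.mean(axis=0), sd,
                    r_cells.shape[0], r_cells)


class TestAverageProfiles:
    def test_identical_profiles(self):
        z = np.arange(5.0)
        r = 1.3 + 0.01 * z
        p = average_profiles([(z, r)] * 5)
        assert np.allclose(p.r_mean, r)
        assert np.allclose(p.r_sd, 0.0)
        assert p.n_cells == 5

    def test_two_point_mean_and_sd(self):
        z = np.arange(3.0)
        p = average_profiles([(z, np.full(3, 1.3)), (z, np.full(3, 1.5))])
        assert np.allclose(p.r_mean, 1.4)
        assert np.allclose(p.r_sd, 0.2 / np.sqrt(2), atol=1e-9)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([(np.arange(3.0), np.ones(3)),
                              (np.arange(4.0), np.ones(4))])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([])

    def test_mean_tracks_truth_under_noise(self, rng):
        z = np.arange(31.0)
        truth = 1.363 + 0.05 * np.exp(-z / 4.0)
        sigma = 0.002
        cells = truth + rng.normal(0, sigma, (5, z.size))
        p = average_profiles(list(cells), z=z)
        assert np.all(np.abs(p.r_mean - truth) < 4 * sigma / np.sqrt(5))


class TestThickness:
    def test_recovers_membrane_position_on_generated_scan(self):
        """Noiseless generated scan with t = 15 um and the 1.14 um PSF:
        the plateau onset lands within one grid step of the membrane."""
        _, truth = make_cell_zscan(CellScanSpec(noise_sd=0.0, seed=0))
        p = _profile(truth.z, truth.r_blurred)
        z_star = estimate_thickness(p, 1.363)
        assert abs(z_star - 15.0) <= 1.0

    def test_constant_profile_gives_zero(self):
        z = np.arange(31.0)
        p = _profile(z, np.full(31, 1.363))
        assert estimate_thickness(p, 1.363) == 0.0

    def test_no_plateau_raises(self):
        z = np.arange(31.0)
        p = _profile(z, 1.363 + 0.05 * z)
        with pytest.raises(PlateauNotFoundError):
            estimate_thickness(p, 1.363)


class TestPerDepthTTest:
    def test_identical_groups(self):
        assert per_depth_ttest([1.3, 1.4, 1.5], [1.3, 1.4, 1.5]) == pytest.approx(1.0)

    def test_ten_pooled_sd_separation(self, rng):
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(10.0, 1.0, 5)
        assert per_depth_ttest(a, b) < 1e-3

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            per_depth_ttest([1.3], [1.3, 1.4])

    def test_zero_variance_equal_means(self):
        assert per_depth_ttest([1.0, 1.0], [1.0, 1.0]) == 1.0


class TestDeltaProfile:
    def test_equal_groups_give_zero_change(self, rng, nacl_calibration):
        z = np.arange(31.0)
        cells = 1.4 + rng.normal(0, 1e-3, (5, z.size))
        p = _profile(z, cells)
        dp = delta_profile(p, p, 15.0, nacl_calibration)
        assert np.allclose(dp.delta_na, 0.0)
        assert np.all(dp.p_values == 1.0)

    def test_linear_delta_r_maps_back_exactly(self, nacl_calibration):
        z = np.arange(31.0)
        a, b = -6.7, 1.47
        base = np.tile(1.4, (2, z.size))
        shift = nacl_calibration.slope * (a + b * z)
        treated = _profile(z, base + shift)
        control = _profile(z, base)
        dp = delta_profile(treated, control, 15.0, nacl_calibration)
        assert np.allclose(dp.delta_na, a + b * dp.z, atol=1e-9)
        assert dp.z.min() > 0 and dp.z.max() < 15.0

    def test_grid_mismatch_rejected(self, nacl_calibration):
        p1 = _profile(np.arange(31.0), np.ones((2, 31)))
        p2 = _profile(np.arange(30.0), np.ones((2, 30)))
        with pytest.raises(ValueError):
            delta_profile(p1, p2, 15.0, nacl_calibration)


class TestGradientFit:
    @staticmethod
    def _dp(z, dna):
        n = len(z)
        return DeltaProfile(np.asarray(z, float), np.zeros(n),
                            np.asarray(dna, float), np.ones(n),
                            np.zeros(n, bool))

    def test_perfect_line(self):
        z = np.arange(1.0, 15.0)
        fit = fit_gradient(self._dp(z, -6.7 + 1.47 * z))
        assert fit.slope == pytest.approx(1.47, rel=1e-12)
        assert fit.pearson_r == pytest.approx(1.0)
        fit2 = fit_gradient(self._dp(z, 5.0 - 2.0 * z))
        assert fit2.pearson_r == pytest.approx(-1.0)

    def test_constant_profile_degenerate(self):
        z = np.arange(1.0, 15.0)
        fit = fit_gradient(self._dp(z, np.full(z.size, 4.3)))
        assert fit.slope == 0.0
        assert fit.pearson_r == 0.0
        assert not fit.pearson_defined

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gradient(self._dp([1.0, 2.0], [0.0, 1.0]))

    def test_z_range_restriction(self):
        z = np.arange(0.0, 16.0)
        dna = -6.7 + 1.47 * z
        dna[0] += 50.0  # contaminated membrane-adjacent point
        fit = fit_gradient(self._dp(z, dna), z_min=1.0, z_max=14.0)
        assert fit.slope == pytest.approx(1.47, rel=1e-12)


class TestMeanChange:
    def test_constant_profile(self):
        fit = GradientFit(0.0, 4.3, 0.0, (1.0, 14.0), 14, pearson_defined=False)
        assert mean_concentration_change(fit, 15.0) == pytest.approx(4.3)

    def test_linear_profile_midpoint(self):
        # -6.7 mM at z=0 rising to +15.3 mM at z=15 averages to 4.3 mM
        fit = GradientFit((15.3 + 6.7) / 15.0, -6.7, 1.0, (0.0, 15.0), 16)
        assert mean_concentration_change(fit, 15.0) == pytest.approx(4.3)

    def test_matches_numerical_quadrature(self):
        fit = GradientFit(1.47, -6.7, 1.0, (0.0, 15.0), 16)
        t = 15.0
        z = np.linspace(0.0, t, 20001)
        numeric = np.trapezoid(fit.intercept + fit.slope * z, z) / t
        assert mean_concentration_change(fit, t) == pytest.approx(numeric,
                                                                  abs=1e-12)

    def test_nonpositive_thickness_rejected(self):
        fit = GradientFit(1.0, 0.0, 1.0, (0.0, 1.0), 3)
        with pytest.raises(ValueError):
            mean_concentration_change(fit, 0.0)


class TestFluxAndCurrent:
    def test_published_gradient_gives_published_flux(self):
        """+1.47 mM/um on the acquisition axis (-1.47 in the flux
        convention) with D = 1.33e-8 cm^2/s gives ~1.95e-10 mol/s/cm^2."""
        j = sodium_flux(1.47, D_NA_CM2_S)
        assert j == pytest.approx(1.33e-8 * 1.47e-2, rel=1e-12)
        assert abs(j - 1.95e-10) <= 0.01e-10

    def test_zero_gradient_zero_flux(self):
        assert sodium_flux(0.0) == 0.0

    def test_linear_in_d_and_sign(self):
        assert sodium_flux(1.0, 2e-8) == pytest.approx(2 * sodium_flux(1.0, 1e-8))
        assert sodium_flux(-1.47) == pytest.approx(-sodium_flux(1.47))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sodium_flux(np.nan)
        with pytest.raises(ValueError):
            sodium_flux(1.0, -1e-8)

    def test_published_flux_gives_published_current(self):
        assert short_circuit_current(1.95e-10) == pytest.approx(18.8, abs=0.1)

    def test_faraday_definition(self):
        assert short_circuit_current(0.0) == 0.0
        assert short_circuit_current(1.0) == pytest.approx(
            FARADAY_C_PER_MOL * 1e6, rel=1e-12)

    def test_chain_linear_in_gradient(self):
        i1 = short_circuit_current(sodium_flux(1.47))
        i2 = short_circuit_current(sodium_flux(2.94))
        assert i2 == pytest.approx(2 * i1, rel=1e-12)
        assert short_circuit_current(sodium_flux(-1.47)) == pytest.approx(-i1)
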