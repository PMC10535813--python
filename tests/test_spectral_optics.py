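"""Tissue-optics layer: absorption, scattering, Kubelka-Munk reflectance, LUT."""

import numpy as np
import pytest

from dermoptics import (
    ChromophoreLibrary,
    ScatteringParams,
    TissueParams,
    absorption_coefficient,
    dermis_reflectance,
    epidermis_transmittance,
    reduced_scattering,
    skin_reflectance,
)
from dermoptics.color_pipeline import camera_to_linear_rgb, spectral_to_camera_rgb
from dermoptics.spectra import SpectralCurve, default_wavelengths
from dermoptics.spectral_optics import km_reflectance_semi_infinite


class TestAbsorption:
    def test_no_chromophores_no_absorption(self, lib):
        assert absorption_coefficient(550, 0.0, 0.0, lib) == 0.0

    @pytest.mark.parametrize("lam", [450, 550, 620, 750])
    def test_linearity_in_each_volume_fraction(self, lib, lam):
        base = absorption_coefficient(lam, 0.05, 0.0, lib)
        assert absorption_coefficient(lam, 0.10, 0.0, lib) == pytest.approx(2 * base)
        base_h = absorption_coefficient(lam, 0.0, 0.02, lib)
        assert absorption_coefficient(lam, 0.0, 0.06, lib) == pytest.approx(3 * base_h)

    def test_additivity_against_term_by_term_oracle(self, lib):
        # independent oracle: evaluate each chromophore term on its own curve
        lam, vm, vh = 620.0, 0.1, 0.04
        expected = vm * lib.melanin_extinction(lam) + vh * lib.hemoglobin_extinction(lam)
        assert absorption_coefficient(lam, vm, vh, lib) == pytest.approx(
            expected, rel=1e-12
        )
        assert absorption_coefficient(lam, vm, vh, lib) == pytest.approx(
            absorption_coefficient(lam, vm, 0, lib)
            + absorption_coefficient(lam, 0, vh, lib)
        )

    def test_out_of_band_wavelength_rejected(self, lib):
        with pytest.raises(ValueError):
            absorption_coefficient(400, 0.1, 0.02, lib)
        with pytest.raises(ValueError):
            absorption_coefficient(800, 0.1, 0.02, lib)


class TestReducedScattering:
    def test_equals_amplitude_at_reference_wavelength(self):
        for f_ray, b in [(0.0, 1.0), (0.5, 1.3), (1.0, 2.0)]:
            p = ScatteringParams(amplitude_a=2.7, power_b=b, f_rayleigh=f_ray,
                                 lambda0_nm=500)
            assert reduced_scattering(500, p) == pytest.approx(2.7)

    def test_pure_mie_halves_at_double_wavelength(self):
        p = ScatteringParams(amplitude_a=3.0, power_b=1.0, f_rayleigh=0.0,
                             lambda0_nm=400)
        assert reduced_scattering(800, p) == pytest.approx(1.5)

    def test_pure_rayleigh_fourth_power(self):
        p = ScatteringParams(amplitude_a=3.0, power_b=1.3, f_rayleigh=1.0,
                             lambda0_nm=400)
        assert reduced_scattering(800, p) == pytest.approx(3.0 / 16)

    def test_strictly_decreasing_in_wavelength(self, scatter):
        lam = default_wavelengths()
        vals = reduced_scattering(lam, scatter)
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_wavelength_rejected(self, scatter):
        with pytest.raises(ValueError):
            reduced_scattering(0.0, scatter)


class TestEpidermis:
    def test_full_transmission_without_absorbers(self, lib):
        t0 = TissueParams(melanin_vf_range=(0.0, 0.43), baseline_blue_mm=0.0)
        assert epidermis_transmittance(550, 0.0, t0, lib) == pytest.approx(1.0)

    def test_strictly_decreasing_in_melanin(self, tissue, lib):
        vals = [
            epidermis_transmittance(650, vm, tissue, lib)
            for vm in np.linspace(0.013, 0.43, 20)
        ]
        assert np.all(np.diff(vals) < 0)
        assert all(0 < v <= 1 for v in vals)

    def test_matches_scalar_beer_lambert_oracle(self, tissue, lib):
        # scalar oracle evaluated outside the vectorized path
        lam, vm = 650.0, 0.1
        mu = vm * lib.melanin_extinction(lam) + tissue.epidermal_baseline(lam)
        expected = np.exp(-mu * tissue.epidermis_thickness_mm)
        assert epidermis_transmittance(lam, vm, tissue, lib) == pytest.approx(expected)

    def test_out_of_range_melanin_clipped_with_warning(self, tissue, lib):
        with pytest.warns(UserWarning):
            v = epidermis_transmittance(550, 0.9, tissue, lib)
        assert v == epidermis_transmittance(550, 0.43, tissue, lib)


class TestDermis:
    def test_lossless_medium_reflects_all(self):
        assert km_reflectance_semi_infinite(0.0) == pytest.approx(1.0)

    def test_closed_form_at_k_over_s_four(self):
        assert km_reflectance_semi_infinite(4.0) == pytest.approx(5 - np.sqrt(24))

    def test_large_absorption_limit_is_dark(self):
        assert km_reflectance_semi_infinite(1e8) < 1e-3

    def test_bounds_for_random_ratios(self, rng):
        r = km_reflectance_semi_infinite(rng.uniform(0, 100, 1000))
        assert np.all((r >= 0) & (r <= 1))

    def test_zero_scattering_rejected(self):
        # the model is undefined without scattering; the parameter object
        # refuses to represent it
        with pytest.raises(ValueError):
            ScatteringParams(amplitude_a=0.0)
        with pytest.raises(ValueError):
            km_reflectance_semi_infinite(-0.5)


class TestSkinReflectance:
    def test_compositional_oracle_at_random_points(self, tissue, scatter, lib, rng):
        lam = rng.uniform(450, 750, 200)
        vm = rng.uniform(*tissue.melanin_vf_range, 200)
        vh = rng.uniform(*tissue.hemoglobin_vf_range, 200)
        for la, m, h in zip(lam, vm, vh):
            expected = (
                epidermis_transmittance(la, m, tissue, lib) ** 2
                * dermis_reflectance(la, h, tissue, scatter, lib)
            )
            assert skin_reflectance(la, m, h, tissue, scatter, lib) == pytest.approx(
                expected, rel=1e-12
            )

    def test_monotone_nonincreasing_in_both_pigments(self, tissue, scatter, lib, rng):
        lam = default_wavelengths()
        for _ in range(50):
            m1, m2 = np.sort(rng.uniform(*tissue.melanin_vf_range, 2))
            h1, h2 = np.sort(rng.uniform(*tissue.hemoglobin_vf_range, 2))
            r_light = skin_reflectance(lam, m1, h1, tissue, scatter, lib)
            r_dark = skin_reflectance(lam, m2, h2, tissue, scatter, lib)
            assert np.all(r_dark <= r_light + 1e-12)

    def test_extreme_melanin_darker_at_every_wavelength(self, tissue, scatter, lib):
        lam = default_wavelengths()
        dark = skin_reflectance(lam, 0.43, 0.04, tissue, scatter, lib)
        light = skin_reflectance(lam, 0.013, 0.04, tissue, scatter, lib)
        assert np.all(dark < light)


def _spectral_oracle_rgb(vm, vh, tissue, scatter, lib, render_cfg):
    """Brute-force spectral pipeline for a single (vm, vh) pair."""
    lam = default_wavelengths()
    refl = SpectralCurve(lam, skin_reflectance(lam, vm, vh, tissue, scatter, lib))
    cam = spectral_to_camera_rgb(refl, 1.0, render_cfg)
    return np.clip(camera_to_linear_rgb(cam, render_cfg), 0, 1)


class TestReflectanceLUT:
    def test_nodes_match_spectral_oracle(self, lut, tissue, scatter, lib, render_cfg):
        idx = [(0, 0), (0, -1), (-1, 0), (-1, -1), (31, 17), (5, 44)]
        for i, j in idx:
            expected = _spectral_oracle_rgb(
                lut.vm_grid[i], lut.vh_grid[j], tissue, scatter, lib, render_cfg
            )
            assert np.allclose(lut.rgb_table[i, j], expected, atol=1e-9)

    def test_interpolation_identity_at_nodes(self, lut):
        vm_mesh, vh_mesh = np.meshgrid(lut.vm_grid, lut.vh_grid, indexing="ij")
        out = lut.lookup(vm_mesh, vh_mesh)
        assert np.allclose(out, lut.rgb_table, atol=1e-12)

    def test_off_node_interpolation_error_small(self, lut, tissue, scatter, lib,
                                                render_cfg, rng):
        vm = rng.uniform(*tissue.melanin_vf_range, 40)
        vh = rng.uniform(*tissue.hemoglobin_vf_range, 40)
        out = lut.lookup(vm, vh)
        for k in range(40):
            expected = _spectral_oracle_rgb(vm[k], vh[k], tissue, scatter, lib,
                                            render_cfg)
            assert np.max(np.abs(out[k] - expected)) < 1e-3

    def test_monotone_nonincreasing_in_melanin_every_channel(self, lut):
        diff = np.diff(lut.rgb_table, axis=0)
        assert np.all(diff <= 1e-12)

    def test_degenerate_grid_rejected(self, tissue, scatter, lib, render_cfg):
        from dermoptics import build_reflectance_lut

        with pytest.raises(ValueError):
            build_reflectance_lut(tissue, scatter, lib, render_cfg, grid_sizes=(1, 8))
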