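"""Synthetic scene generator: presets, forward model, determinism, noise."""

import dataclasses

import numpy as np
import pytest

from sifemu import (
    SceneConfig,
    fluo_input_grid,
    generate_class_library,
    make_band_grid,
    sif_output_grid,
    simulate_pixel,
    simulate_scene,
)
from sifemu.errors import ArgumentError
from sifemu.synth import o2a_transmittance, sif_shape, solar_irradiance


class TestBandGridPresets:
    def test_fluo_preset_band_structure(self):
        grid = fluo_input_grid()
        assert len(grid) == 1024
        assert grid.wavelengths[0] == 669.5
        assert grid.wavelengths[-1] == 781.9

    def test_sif_preset_spacing_is_one_nm(self):
        grid = sif_output_grid()
        assert len(grid) == 27
        np.testing.assert_allclose(np.diff(grid.wavelengths), 1.0, atol=1e-12)

    def test_two_band_grid(self):
        g = make_band_grid(1.0, 2.0, 2)
        np.testing.assert_array_equal(g.wavelengths, [1.0, 2.0])

    def test_invalid_arguments(self):
        with pytest.raises(ArgumentError):
            make_band_grid(700.0, 690.0, 10)
        with pytest.raises(ArgumentError):
            make_band_grid(np.nan, 700.0, 10)


class TestClassLibrary:
    def test_zero_vegetation_fraction_gives_zero_amplitudes(self):
        cfg = SceneConfig(rows=4, cols=4, vegetation_fraction=0.0)
        lib = generate_class_library(cfg, np.random.default_rng(0))
        assert np.all(lib.sif_amplitude == 0.0)

    def test_same_seed_identical_library(self):
        cfg = SceneConfig(rows=4, cols=4)
        a = generate_class_library(cfg, np.random.default_rng(5))
        b = generate_class_library(cfg, np.random.default_rng(5))
        assert np.array_equal(a.reflectance, b.reflectance)
        assert np.array_equal(a.sif_amplitude, b.sif_amplitude)

    def test_amplitudes_within_configured_range(self):
        cfg = SceneConfig(rows=4, cols=4, n_classes=12, vegetation_fraction=1.0,
                          sif_amplitude_range=(0.0, 6.0))
        lib = generate_class_library(cfg, np.random.default_rng(1))
        assert np.all((lib.sif_amplitude >= 0.0) & (lib.sif_amplitude <= 6.0))

    def test_reflectance_bounded(self):
        cfg = SceneConfig(rows=4, cols=4, n_classes=10)
        lib = generate_class_library(cfg, np.random.default_rng(2))
        assert lib.reflectance.min() >= 0.0 and lib.reflectance.max() <= 1.0


class TestSimulatePixel:
    def test_zero_sif_zero_noise_closed_form(self):
        cfg = SceneConfig(rows=2, cols=2, radiance_noise_sd=0.0,
                          input_grid=(700.0, 780.0, 50))
        grid = make_band_grid(700.0, 780.0, 50)
        rho = np.full(50, 0.3)
        radiance, true_sif = simulate_pixel(rho, 0.0, cfg)
        expected = (cfg.illumination_factor * solar_irradiance(grid.wavelengths)
                    * o2a_transmittance(grid.wavelengths, cfg.absorption_depth)
                    * rho / np.pi)
        np.testing.assert_allclose(radiance, expected, rtol=1e-12)
        assert np.all(true_sif == 0.0)

    def test_absorption_dip_present(self):
        cfg = SceneConfig(rows=2, cols=2, radiance_noise_sd=0.0,
                          absorption_depth=0.9)
        grid = fluo_input_grid()
        radiance, _ = simulate_pixel(np.full(1024, 0.3), 0.0, cfg)
        at = lambda nm: radiance[grid.index_nearest(nm)]
        assert at(760.5) < at(755.0)

    def test_true_sif_normalized_at_760(self):
        cfg = SceneConfig(rows=2, cols=2, radiance_noise_sd=0.0)
        _, true_sif = simulate_pixel(np.full(1024, 0.3), 4.2, cfg)
        band = sif_output_grid().index_nearest(760.0)
        assert abs(true_sif[band] - 4.2) < 1e-12

    def test_shape_unit_value_at_760(self):
        assert abs(sif_shape(np.array([760.0]))[0] - 1.0) < 1e-15


class TestSimulateScene:
    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(rows=10, cols=10, n_classes=2, seed=7)
        c1, t1 = simulate_scene(cfg)
        c2, t2 = simulate_scene(cfg)
        assert np.array_equal(c1.values, c2.values)
        assert np.array_equal(t1.reference_sif.values, t2.reference_sif.values)

    def test_non_vegetated_pixels_have_exactly_zero_sif(self, noisy_scene):
        _, _, truth = noisy_scene
        nonveg_classes = np.flatnonzero(truth.library.sif_amplitude == 0.0)
        mask = np.isin(truth.class_map, nonveg_classes)
        assert mask.any()
        assert np.all(truth.true_sif.values[mask] == 0.0)

    def test_all_classes_present_in_large_scene(self):
        cfg = SceneConfig(rows=100, cols=100, n_classes=8, seed=11)
        _, truth = simulate_scene(cfg)
        assert set(np.unique(truth.class_map)) == set(range(8))

    def test_radiance_nonnegative_without_noise(self):
        cfg = SceneConfig(rows=20, cols=20, radiance_noise_sd=0.0, seed=4)
        cube, _ = simulate_scene(cfg)
        assert cube.values.min() >= 0.0

    def test_illumination_linearity(self):
        base = dict(rows=12, cols=12, radiance_noise_sd=0.0,
                    sif_amplitude_range=(0.0, 0.0), amplitude_jitter_sd=0.0,
                    seed=21)
        c1, _ = simulate_scene(SceneConfig(**base, illumination_factor=1.0))
        c2, _ = simulate_scene(SceneConfig(**base, illumination_factor=2.0))
        np.testing.assert_allclose(c2.values, 2.0 * c1.values, rtol=1e-6)

    def test_reference_noise_is_zero_mean(self):
        cfg = SceneConfig(rows=100, cols=100, seed=13, reference_sif_noise_sd=0.3)
        _, truth = simulate_scene(cfg)
        resid = (truth.reference_sif.values.astype(float)
                 - truth.true_sif.values.astype(float))
        n = resid.size
        assert abs(resid.mean()) < 3 * 0.3 / np.sqrt(n)
        assert abs(resid.std() - 0.3) < 0.01

    def test_vegetated_area_fraction_near_target(self):
        fractions = []
        for seed in range(10):
            cfg = SceneConfig(rows=40, cols=40, n_classes=8, seed=seed)
            _, truth = simulate_scene(cfg)
            veg = truth.library.sif_amplitude != 0.0
            fractions.append(np.mean(veg[truth.class_map]))
        target = round(0.61 * 8) / 8
        assert abs(np.mean(fractions) - target) < 0.15

    def test_scene_pixel_matches_simulate_pixel(self):
        cfg = SceneConfig(rows=6, cols=6, radiance_noise_sd=0.0,
                          reference_sif_noise_sd=0.0, amplitude_jitter_sd=0.0,
                          reflectance_jitter_sd=0.0, seed=17)
        cube, truth = simulate_scene(cfg)
        r, c = 3, 2
        cls = truth.class_map[r, c]
        rad, sif = simulate_pixel(truth.library.reflectance[cls],
                                  float(truth.library.sif_amplitude[cls]), cfg)
        np.testing.assert_allclose(cube.values[r, c], rad, rtol=1e-5)
        np.testing.assert_allclose(truth.true_sif.values[r, c], sif, rtol=1e-5, atol=1e-6)

    def test_config_validation(self):
        with pytest.raises(ArgumentError):
            SceneConfig(rows=0)
        with pytest.raises(ArgumentError):
            SceneConfig(absorption_depth=1.0)
        with pytest.raises(ArgumentError):
            SceneConfig(illumination_factor=0.0)
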