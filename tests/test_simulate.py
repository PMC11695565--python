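"""Simulator ground truth: phantom rasterization, noise synthesis, emulation."""

import numpy as np
import pytest

from ctnoise import (
    AcquisitionConfig, GeometryError, ImageStack, Insert, IterativeEmulation,
    NoiseModel, PhantomSpec, build_phantom_image, ctp404_spec,
    emulate_iterative, generate_acquisitions, synthesize_noise_volume,
    water_cylinder_spec,
)
from conftest import make_noise_stack


@pytest.fixture(scope="module")
def small_config():
    return AcquisitionConfig(matrix_size=128, fov_mm=220.0,
                             slice_thickness_mm=0.4, n_slices=2,
                             n_repeats=4, seed=7)


class TestPhantomImage:
    def test_center_and_corner_values(self, small_config):
        img = build_phantom_image(water_cylinder_spec(), small_config)
        n = small_config.matrix_size
        assert img.shape == (2, n, n)
        assert img[0, n // 2, n // 2] == 0.0
        assert img[0, 0, 0] == -1000.0
        assert np.array_equal(img[0], img[1])  # identical across slices

    def test_in_phantom_pixel_count_matches_brute_force(self, small_config):
        img = build_phantom_image(water_cylinder_spec(), small_config)
        sp = small_config.pixel_spacing_mm
        n = small_config.matrix_size
        # independent brute-force pixel-centre-in-circle count
        count = 0
        for r in range(n):
            for c in range(n):
                y = (r - (n - 1) / 2) * sp
                x = (c - (n - 1) / 2) * sp
                if np.hypot(y, x) <= 100.0:
                    count += 1
        assert int((img[0] > -1000).sum()) == count
        assert count == pytest.approx(np.pi * (100.0 / sp) ** 2, rel=0.02)

    def test_insert_value_at_center(self, small_config):
        spec = PhantomSpec(kind="insert_module", phantom_diameter_mm=200.0,
                           background_hu=0.0,
                           inserts=(Insert("teflon-like", (0.0, 0.0), 12.0, 990.0),))
        img = build_phantom_image(spec, small_config)
        n = small_config.matrix_size
        assert img[0, n // 2, n // 2] == 990.0

    def test_phantom_larger_than_fov_rejected(self, small_config):
        with pytest.raises(GeometryError):
            build_phantom_image(water_cylinder_spec(diameter_mm=230.0),
                                small_config)

    def test_insert_outside_phantom_rejected(self):
        with pytest.raises(GeometryError):
            PhantomSpec(kind="insert_module", phantom_diameter_mm=100.0,
                        inserts=(Insert("far", (48.0, 0.0), 10.0, 100.0),))

    def test_ctp404_has_seven_inserts_inside(self):
        spec = ctp404_spec()
        assert len(spec.inserts) == 7
        names = {i.name for i in spec.inserts}
        assert {"air", "Teflon", "acrylic"} <= names


class TestNoiseSynthesis:
    def test_zero_sigma_gives_zero_field(self, small_config):
        noise = synthesize_noise_volume(small_config,
                                        NoiseModel(sigma_hu=0.0), 0)
        assert not noise.any()

    def test_white_noise_sd_recovers_sigma(self):
        # 128^3 volume: sample SD within 10 +/- 0.1 HU
        config = AcquisitionConfig(matrix_size=128, fov_mm=220.0,
                                   slice_thickness_mm=0.4, n_slices=128,
                                   n_repeats=2, seed=11)
        noise = synthesize_noise_volume(config, NoiseModel(sigma_hu=10.0), 0)
        assert np.std(noise) == pytest.approx(10.0, abs=0.1)
        assert np.mean(noise) == pytest.approx(0.0, abs=0.05)

    def test_bandpass_noise_sd_recovers_sigma(self):
        config = AcquisitionConfig(matrix_size=128, fov_mm=220.0,
                                   slice_thickness_mm=0.4, n_slices=32,
                                   n_repeats=2, seed=11)
        model = NoiseModel(sigma_hu=10.0, nps_shape="ramp_bandpass",
                           exponent_a=1.0, cutoff_fc_mm1=0.2, falloff_b=1.0)
        noise = synthesize_noise_volume(config, model, 0)
        assert np.std(noise) == pytest.approx(10.0, rel=0.02)

    def test_sigma_modulation_scales_noise(self):
        config = AcquisitionConfig(matrix_size=64, fov_mm=220.0,
                                   slice_thickness_mm=0.4, n_slices=16,
                                   n_repeats=2, seed=5)
        mod = np.ones((64, 64))
        mod[:, 32:] = 2.0
        model = NoiseModel(sigma_hu=10.0, sigma_modulation=mod)
        noise = synthesize_noise_volume(config, model, 0)
        ratio = np.std(noise[:, :, 32:]) / np.std(noise[:, :, :32])
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self, small_config):
        model = NoiseModel(nps_shape="ramp_bandpass",
                           cutoff_fc_mm1=2.0 * small_config.nyquist_mm1)
        with pytest.raises(ValueError):
            synthesize_noise_volume(small_config, model, 0)

    def test_repeats_reproducible_and_independent(self):
        config = AcquisitionConfig(matrix_size=64, fov_mm=220.0,
                                   slice_thickness_mm=0.4, n_slices=4,
                                   n_repeats=2, seed=13)
        model = NoiseModel(sigma_hu=10.0)
        a = synthesize_noise_volume(config, model, 0)
        b = synthesize_noise_volume(config, model, 0)
        c = synthesize_noise_volume(config, model, 1)
        assert np.array_equal(a, b)  # reproducible given (seed, repeat)
        r = np.corrcoef(a.ravel(), c.ravel())[0, 1]
        assert abs(r) < 3.0 / np.sqrt(a.size)  # independent repeats


class TestIterativeEmulation:
    def test_strength_zero_is_identity(self):
        stack = make_noise_stack(n_repeats=3, matrix=32, seed=1)
        flat = np.zeros(stack.values.shape[1:])
        out = emulate_iterative(stack, flat,
                                IterativeEmulation(strength=0.0))
        assert np.array_equal(out.values, stack.values)

    def test_uniform_smoothing_reduces_sd_to_filter_norm(self):
        # 3x3 uniform mean on white noise: SD -> sigma * sqrt(sum w^2) = sigma/3
        stack = make_noise_stack(n_repeats=2, matrix=256, sigma=10.0, seed=2)
        flat = np.zeros(stack.values.shape[1:])
        emu = IterativeEmulation(strength=1.0,
                                 smoothing_scale_mm=3 * stack.pixel_spacing_mm,
                                 edge_preservation=0.0)
        out = emulate_iterative(stack, flat, emu)
        interior = out.values[0, 0, 10:-10, 10:-10]
        assert np.std(interior) == pytest.approx(10.0 / 3.0, rel=0.03)

    def test_noise_nonincreasing_in_strength(self):
        stack = make_noise_stack(n_repeats=10, matrix=64, sigma=10.0, seed=4)
        flat = np.zeros(stack.values.shape[1:])
        sds = []
        for s in (0.0, 0.3, 0.6, 1.0):
            out = emulate_iterative(
                stack, flat, IterativeEmulation(strength=s,
                                                edge_preservation=0.0))
            sds.append(np.std(out.values, axis=0, ddof=1).mean())
        assert all(a >= b for a, b in zip(sds, sds[1:]))

    def test_edge_preservation_suppresses_smoothing_near_edges(self):
        spec = PhantomSpec(kind="insert_module", phantom_diameter_mm=180.0,
                           inserts=(Insert("hi", (0.0, 0.0), 24.0, 900.0),))
        config = AcquisitionConfig(matrix_size=128, fov_mm=220.0,
                                   slice_thickness_mm=0.4, n_slices=1,
                                   n_repeats=40, seed=9)
        model = NoiseModel(sigma_hu=10.0)
        stack = generate_acquisitions(spec, config, model, dtype=np.float64)
        phantom = build_phantom_image(spec, config)
        emu = IterativeEmulation(strength=1.0,
                                 smoothing_scale_mm=3 * config.pixel_spacing_mm,
                                 edge_preservation=0.05)
        out = emulate_iterative(stack, phantom, emu)
        sd = np.std(out.values, axis=0, ddof=1)[0]
        n = config.matrix_size
        # insert boundary at radius 12 mm; phantom center ~30 mm away is edge-free
        edge_col = n // 2 + int(round(12.0 / config.pixel_spacing_mm))
        sd_edge = sd[n // 2, edge_col]
        sd_far = sd[n // 2 + 20:n // 2 + 30, n // 2 + 20:n // 2 + 30].mean()
        assert sd_edge > sd_far  # less noise reduction at the boundary

    def test_geometry_mismatch_rejected(self):
        stack = make_noise_stack(n_repeats=2, matrix=32)
        with pytest.raises(GeometryError):
            emulate_iterative(stack, np.zeros((1, 16, 16)),
                              IterativeEmulation(strength=0.5))


class TestGenerateAcquisitions:
    def test_zero_noise_gives_identical_repeats(self):
        config = AcquisitionConfig(matrix_size=64, fov_mm=220.0,
                                   slice_thickness_mm=0.4, n_slices=1,
                                   n_repeats=2, seed=1)
        stack = generate_acquisitions(water_cylinder_spec(), config,
                                      NoiseModel(sigma_hu=0.0))
        assert np.array_equal(stack.values[0], stack.values[1])

    def test_fixed_seed_is_bit_reproducible(self):
        config = AcquisitionConfig(matrix_size=64, fov_mm=220.0,
                                   slice_thickness_mm=0.4, n_slices=1,
                                   n_repeats=3, seed=21)
        model = NoiseModel(sigma_hu=10.0)
        a = generate_acquisitions(water_cylinder_spec(), config, model)
        b = generate_acquisitions(water_cylinder_spec(), config, model)
        assert np.array_equal(a.values, b.values)
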