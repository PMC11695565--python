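"""3D NPS estimation, radial reduction and peak-frequency extraction."""

import numpy as np
import pytest

from ctnoise import (
    GeometryError, NPS3D, RadialNPS, average_radial_over_sets, compute_nps3d,
    extract_vois, make_only_noise_volumes, nps_integral, peak_frequency,
    radial_nps, voi_boxes,
)
from ctnoise.nps import slices_per_region
from conftest import make_noise_stack


class TestOnlyNoiseVolumes:
    def test_identical_repeats_give_zero_volumes(self):
        stack = make_noise_stack(n_repeats=4, matrix=16, sigma=0.0)
        vols = make_only_noise_volumes(stack)
        assert len(vols) == 3
        assert all(not v.values.any() for v in vols)

    def test_count_is_repeats_minus_one(self):
        stack = make_noise_stack(n_repeats=40, matrix=16, sigma=1.0, seed=1)
        assert len(make_only_noise_volumes(stack)) == 39

    def test_reference_out_of_range_rejected(self):
        stack = make_noise_stack(n_repeats=4, matrix=16)
        with pytest.raises(IndexError):
            make_only_noise_volumes(stack, reference_index=4)

    def test_difference_variance_doubles(self):
        stack = make_noise_stack(n_repeats=2, matrix=128, n_slices=8,
                                 sigma=10.0, seed=2)
        vol = make_only_noise_volumes(stack)[0]
        assert np.std(vol.values) == pytest.approx(10.0 * np.sqrt(2), rel=0.02)


class TestVoiGeometry:
    def test_protocol_defaults_give_24_vois(self):
        boxes = voi_boxes((78, 256, 256), 0.4297, 0.4)
        assert len(boxes) == 24
        assert all(b[1] - b[0] == 13 for b in boxes)  # 5.4 mm at 0.4 mm

    def test_slices_per_region_stays_within_extent(self):
        assert slices_per_region(5.4, 0.6) == 9
        assert slices_per_region(5.4, 0.4) == 13

    def test_vois_pairwise_disjoint_brute_force(self):
        stack = make_noise_stack(n_repeats=2, matrix=32, n_slices=8,
                                 thickness=0.6, sigma=1.0, seed=3)
        vol = make_only_noise_volumes(stack)[0]
        ens = extract_vois(vol, stack.pixel_spacing_mm, 0.6, n_regions=2,
                           vois_per_region=4, in_plane_size=8, z_extent_mm=2.4)
        assert len(ens.vois) == 8
        index_sets = []
        for (z0, z1, y0, y1, x0, x1) in ens.boxes:
            s = {(z, y, x) for z in range(z0, z1) for y in range(y0, y1)
                 for x in range(x0, x1)}
            index_sets.append(s)
        for i in range(len(index_sets)):
            for j in range(i + 1, len(index_sets)):
                assert not (index_sets[i] & index_sets[j])

    def test_too_short_slab_rejected(self):
        with pytest.raises(GeometryError):
            voi_boxes((10, 256, 256), 0.43, 0.4, n_regions=6,
                      in_plane_size=64, z_extent_mm=5.4)

    def test_voi_outside_phantom_rejected(self):
        with pytest.raises(GeometryError, match="phantom"):
            voi_boxes((13, 512, 512), 0.4297, 0.4, n_regions=1,
                      in_plane_size=128, phantom_diameter_mm=100.0)

    def test_voi_inside_phantom_accepted(self):
        # 20 cm phantom at 0.43 mm pixels holds four 128-px quadrant blocks
        boxes = voi_boxes((13, 512, 512), 0.4297, 0.4, n_regions=1,
                          in_plane_size=128, phantom_diameter_mm=200.0)
        assert len(boxes) == 4


class TestNps3d:
    def test_zero_volumes_give_zero_nps(self):
        vois = [np.zeros((4, 8, 8))] * 3
        nps = compute_nps3d(vois, (0.4, 0.5, 0.5))
        assert not nps.values.any()

    def test_nonuniform_voi_shapes_rejected(self):
        with pytest.raises(ValueError):
            compute_nps3d([np.zeros((4, 8, 8)), np.zeros((4, 8, 4))],
                          (0.4, 0.5, 0.5))

    def test_parseval_variance_conservation(self):
        rng = np.random.default_rng(5)
        sigma = 7.0
        vois = [sigma * rng.standard_normal((16, 32, 32)) for _ in range(8)]
        nps = compute_nps3d(vois, (0.4, 0.5, 0.5), halve=False)
        assert nps_integral(nps) == pytest.approx(sigma ** 2, rel=0.05)

    def test_noise_scaling_scales_nps_quadratically(self):
        rng = np.random.default_rng(6)
        vois = [rng.standard_normal((4, 16, 16)) for _ in range(2)]
        n1 = compute_nps3d(vois, (0.4, 0.5, 0.5))
        n3 = compute_nps3d([3 * v for v in vois], (0.4, 0.5, 0.5))
        assert np.allclose(n3.values, 9 * n1.values)

    def test_injected_sinusoid_concentrates_at_its_frequency(self):
        n = 32
        dx = 0.5
        k = 5  # cycles across the VOI -> f0 = k/(n*dx)
        x = np.arange(n)
        voi = np.broadcast_to(np.cos(2 * np.pi * k * x / n), (4, n, n)).copy()
        nps = compute_nps3d([voi], (0.4, dx, dx), halve=False)
        f0 = k / (n * dx)
        iz = np.argmin(np.abs(nps.f_z))
        plane = nps.values[iz]
        iy = np.argmin(np.abs(nps.f_y))
        peak_bins = plane[iy, np.isclose(np.abs(nps.f_x), f0)]
        assert peak_bins.sum() > 0.99 * nps.values.sum()


class TestRadialNps:
    @staticmethod
    def flat_nps(c=3.0, n=32, dx=0.5, nz=5, dz=0.4):
        values = np.full((nz, n, n), c)
        return NPS3D(values=values,
                     f_z=np.fft.fftshift(np.fft.fftfreq(nz, dz)),
                     f_y=np.fft.fftshift(np.fft.fftfreq(n, dx)),
                     f_x=np.fft.fftshift(np.fft.fftfreq(n, dx)),
                     voxel_sizes_mm=(dz, dx, dx))

    def test_isotropic_flat_plane_gives_constant_profile(self):
        radial = radial_nps(self.flat_nps(c=3.0))
        assert np.allclose(radial.values, 3.0)

    def test_radial_grid_uses_dft_spacing(self):
        radial = radial_nps(self.flat_nps(n=128, dx=0.4297))
        assert radial.frequencies_mm1[1] == pytest.approx(1 / (128 * 0.4297))
        assert radial.frequencies_mm1[0] == 0.0
        assert radial.frequencies_mm1[-1] == pytest.approx(1 / (2 * 0.4297),
                                                           rel=0.01)

    def test_anisotropic_fx_squared_averages_to_half_r_squared(self):
        nps = self.flat_nps(n=64, dx=0.5)
        nps.values = np.broadcast_to(nps.f_x[None, :] ** 2,
                                     nps.values.shape[1:])[None].repeat(
                                         nps.values.shape[0], axis=0).copy()
        radial = radial_nps(nps, n_angles=100)
        f = radial.frequencies_mm1
        sel = (f >= 4 * f[1]) & np.isfinite(radial.values) & (f < f[-1] * 0.7)
        assert np.allclose(radial.values[sel], f[sel] ** 2 / 2, rtol=0.02)

    def test_invalid_angle_count_rejected(self):
        with pytest.raises(ValueError):
            radial_nps(self.flat_nps(), n_angles=0)


class TestRadialAveraging:
    @staticmethod
    def curve(values):
        values = np.asarray(values, dtype=float)
        return RadialNPS(frequencies_mm1=np.arange(values.size) * 0.1,
                         values=values, n_angles=10)

    def test_single_input_is_identity(self):
        c = self.curve([1.0, 2.0, 3.0])
        out = average_radial_over_sets([c])
        assert np.array_equal(out.values, c.values)

    def test_pointwise_mean(self):
        out = average_radial_over_sets([self.curve([1, 2, 3]),
                                        self.curve([3, 2, 1])])
        assert np.array_equal(out.values, [2.0, 2.0, 2.0])

    def test_mismatched_grids_rejected(self):
        a = self.curve([1, 2, 3])
        b = RadialNPS(frequencies_mm1=np.array([0.0, 0.2, 0.4]),
                      values=np.ones(3), n_angles=10)
        with pytest.raises(ValueError):
            average_radial_over_sets([a, b])

    def test_averaging_shrinks_dispersion(self):
        rng = np.random.default_rng(7)
        curves = [self.curve(5.0 + rng.standard_normal(20))
                  for _ in range(39)]
        avg = average_radial_over_sets(curves)
        assert np.std(avg.values) < np.std(curves[0].values) / 3.0


class TestPeakFrequency:
    def test_unique_maximum(self):
        c = TestRadialAveraging.curve([0.0, 1.0, 5.0, 2.0])
        assert peak_frequency(c) == pytest.approx(0.2)

    def test_dc_bin_excluded(self):
        c = TestRadialAveraging.curve([100.0, 1.0, 5.0, 2.0])
        assert peak_frequency(c) == pytest.approx(0.2)

    def test_flat_spectrum_ties_break_to_lowest_nonzero(self):
        c = TestRadialAveraging.curve([1.0, 1.0, 1.0, 1.0])
        assert peak_frequency(c) == pytest.approx(0.1)

    def test_all_zero_curve_rejected(self):
        with pytest.raises(ValueError):
            peak_frequency(TestRadialAveraging.curve([0.0, 0.0, 0.0]))

    def test_smoothing_window_stabilizes_noisy_peak(self):
        rng = np.random.default_rng(8)
        f = np.arange(60) * 0.01
        shape = f * np.exp(-f / 0.2)
        noisy = shape * (1 + 0.05 * rng.standard_normal(f.size))
        c = RadialNPS(frequencies_mm1=f, values=noisy, n_angles=10)
        fp = peak_frequency(c, smoothing_window=7)
        assert abs(fp - 0.2) <= 0.03

    def test_even_smoothing_window_rejected(self):
        c = TestRadialAveraging.curve([0.0, 1.0, 5.0, 2.0])
        with pytest.raises(ValueError):
            peak_frequency(c, smoothing_window=4)
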