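"""3D noise power spectrum, radial profile and peak frequency.

Generates correlated noise with an analytically known band-pass texture
NPS(f) ~ f * exp(-f / 0.2 mm^-1) (peak at exactly 0.2 mm^-1), estimates the
3D NPS from only-noise difference volumes over a VOI ensemble, reduces it
to the angle-averaged radial spectrum on the fz = 0 plane, and extracts the
peak frequency f_p.
"""

import numpy as np

import ctnoise as cn

config = cn.AcquisitionConfig(matrix_size=128, fov_mm=55.0,  # 0.43 mm pixels
                              slice_thickness_mm=0.6, n_slices=27,
                              n_repeats=20, seed=2)
model = cn.NoiseModel(sigma_hu=10.0, nps_shape="ramp_bandpass",
                      exponent_a=1.0, cutoff_fc_mm1=0.2, falloff_b=1.0)
values = np.stack([cn.synthesize_noise_volume(config, model, r)
                   for r in range(config.n_repeats)])
stack = cn.ImageStack(values=values, pixel_spacing_mm=config.pixel_spacing_mm,
                      slice_thickness_mm=config.slice_thickness_mm,
                      label="bandpass")

radial, nps3d = cn.estimate_radial_nps(stack, n_regions=3, vois_per_region=4,
                                       in_plane_size=64, z_extent_mm=5.4,
                                       smoothing_window=5)
print(f"only-noise volumes      : {stack.n_repeats - 1}")
print(f"NPS integral            : {cn.nps_integral(nps3d):7.1f} HU^2 "
      f"(generator variance {model.sigma_hu ** 2:.0f} HU^2)")
print(f"radial bin width        : {radial.frequencies_mm1[1]:.4f} mm^-1")
print(f"peak frequency f_p      : {radial.f_p_mm1:.3f} mm^-1 "
      f"(analytic argmax {model.cutoff_fc_mm1:.3f} mm^-1)")
# Parseval: the NPS integral reproduces the per-image variance; the radial
# curve peaks at the generator's cutoff frequency to within one bin.
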