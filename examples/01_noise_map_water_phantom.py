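"""Voxelwise noise map of a simulated water-phantom protocol.

Simulates 40 repeated axial acquisitions of a 10 cm water cylinder with
white noise of known magnitude, computes the per-voxel noise map on the
central slice, and summarizes it in a central 1 cm circular ROI — the
standard way a repeated-acquisition protocol reports its noise level.
"""

import ctnoise as cn

config = cn.AcquisitionConfig(matrix_size=128, fov_mm=110.0,
                              slice_thickness_mm=0.4, n_slices=1,
                              n_repeats=40, seed=0)
model = cn.NoiseModel(sigma_hu=10.0)  # ground truth: 10 HU per voxel
stack = cn.generate_acquisitions(cn.water_cylinder_spec(100.0), config, model)

noise_map = cn.compute_noise_map(stack, slice_selection="central")
stat = cn.roi_statistics(noise_map, diameter_mm=10.0)

print(f"simulated sigma        : {model.sigma_hu:.1f} HU")
print(f"noise map ROI mean     : {stat.mean:.2f} HU "
      f"(SD {stat.sd:.2f} HU over {stat.n_voxels} voxels)")
# The ROI mean recovers the generator sigma to within a few tenths of an HU;
# the ~11% ROI SD is the intrinsic dispersion of a 40-repeat SD estimate.
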