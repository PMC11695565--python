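"""Iterative-reconstruction emulation: noise reduction and the edge effect.

Applies the edge-aware smoothing emulator at increasing strength to a
contrast-insert phantom and reports (i) the central-ROI percent noise
reduction relative to the unsmoothed stack and (ii) the noise
non-uniformity index (NUI). Because smoothing is suppressed near insert
boundaries, noise stays high there while it drops elsewhere — so the NUI
rises with iterative strength even as the mean noise falls.
"""

import ctnoise as cn

config = cn.AcquisitionConfig(matrix_size=192, fov_mm=220.0,
                              slice_thickness_mm=0.4, n_slices=1,
                              n_repeats=40, seed=1)
spec = cn.ctp404_spec()  # 7 contrast inserts on a ring
model = cn.NoiseModel(sigma_hu=10.0)
base = cn.generate_acquisitions(spec, config, model)
phantom = cn.build_phantom_image(spec, config)
ref_map = cn.compute_noise_map(base)
grid = cn.build_roi_grid(150.0, 8.0, ref_map.pixel_spacing_mm,
                         ref_map.central_slice.shape)

print(f"{'strength':>8} {'reduction %':>12} {'NUI %':>8}   (k = {grid.k} ROIs)")
for strength in (0.0, 0.25, 0.5, 0.75, 1.0):
    emu = cn.IterativeEmulation(strength=strength,
                                smoothing_scale_mm=3 * config.pixel_spacing_mm,
                                edge_preservation=0.01)
    out = cn.emulate_iterative(base, phantom, emu)
    nm = cn.compute_noise_map(out)
    red = cn.compute_reduction_map(ref_map, nm)
    red_stat = cn.roi_statistics(red, diameter_mm=10.0)
    nui = cn.compute_nui(nm, grid)
    print(f"{strength:8.2f} {red_stat.mean:12.1f} {nui.nui_percent:8.2f}")
# Reduction climbs toward the 3x3-box limit of ~66% while NUI rises several
# fold: exactly the qualitative edge-effect signature of iterative
# reconstruction on insert phantoms.
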