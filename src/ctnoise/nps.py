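"""3D noise power spectrum estimation from only-noise difference volumes.

The estimator follows the standard repeated-acquisition recipe for CT:

1. "Only-noise" volumes are formed by subtracting one reference repeat from
   each of the remaining ones; the subtraction doubles the noise variance,
   which the 1/2 prefactor of the estimator compensates.
2. An ensemble of disjoint parallelepiped VOIs is carved out of the phantom
   interior (several contiguous z-regions, several in-plane blocks placed
   symmetrically about the phantom centre in each region).
3. For each VOI, the 3D NPS is

       NPS(fx, fy, fz) = (1/2) * (dx*dy*dz) / (Nx*Ny*Nz) * <|FFT3(VOI)|^2>

   with <.> the average over the VOI ensemble; units HU^2 * mm^3.
4. The fz = 0 plane is reduced to a 1D radial spectrum by averaging many
   uniformly spaced radial profiles (bilinear interpolation), and the final
   curve is the pointwise mean over all only-noise volumes.
5. The peak frequency f_p of the radial curve (the texture summary that
   shifts toward low frequencies under smoothing-type noise reduction) is
   the location of its maximum, excluding the f = 0 bin.

Each VOI is mean-subtracted before the transform: difference volumes are
zero-mean in expectation only, and a residual DC offset would otherwise
leak into the lowest-frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .simulate import GeometryError, ImageStack

__all__ = [
    "OnlyNoiseVolume", "VoiEnsemble", "NPS3D", "RadialNPS",
    "make_only_noise_volumes", "voi_boxes", "extract_vois", "compute_nps3d",
    "radial_nps", "average_radial_over_sets", "peak_frequency", "nps_integral",
    "estimate_radial_nps",
]


@dataclass
class OnlyNoiseVolume:
    """Difference of two repeats; its NPS is twice the single-image NPS."""

    values: np.ndarray  # 3D (slice, row, col), HU
    reference_index: int
    other_index: int


@dataclass
class VoiEnsemble:
    """Disjoint parallelepiped VOIs cut from one only-noise volume."""

    vois: list[np.ndarray]
    boxes: tuple[tuple[int, int, int, int, int, int], ...]  # (z0,z1,y0,y1,x0,x1)
    in_plane_size: int
    n_z: int
    n_regions: int
    vois_per_region: int


@dataclass
class NPS3D:
    """3D NPS on the (shifted) DFT frequency grid, units HU^2 mm^3.

    ``values`` has axes (fz, fy, fx), frequencies ascending (fftshifted).
    """

    values: np.ndarray
    f_z: np.ndarray
    f_y: np.ndarray
    f_x: np.ndarray
    voxel_sizes_mm: tuple[float, float, float]  # (dz, dy, dx)
    halved: bool = True


@dataclass
class RadialNPS:
    """Angle-averaged radial NPS on the fz = 0 plane.

    The values are the fz = 0 slice of the 3D estimator (HU^2 mm^3); the
    radial grid runs from 0 to the in-plane Nyquist with the DFT spacing
    1/(N*dx).
    """

    frequencies_mm1: np.ndarray
    values: np.ndarray
    n_angles: int
    f_p_mm1: float | None = None


def make_only_noise_volumes(stack: ImageStack,
                            reference_index: int = 0) -> list[OnlyNoiseVolume]:
    """Subtract the reference repeat from every other repeat.

    The same reference is used for all differences, so the n-1 volumes share
    its noise and are mutually correlated; this is accepted as part of the
    estimation recipe (the ensemble averaging step absorbs it).
    """
    if stack.n_repeats < 2:
        raise ValueError("need at least 2 repeats for only-noise volumes")
    if not 0 <= reference_index < stack.n_repeats:
        raise IndexError(f"reference_index {reference_index} out of range "
                         f"[0, {stack.n_repeats})")
    ref = stack.values[reference_index].astype(np.float64)
    return [OnlyNoiseVolume(values=stack.values[r].astype(np.float64) - ref,
                            reference_index=reference_index, other_index=r)
            for r in range(stack.n_repeats) if r != reference_index]


def slices_per_region(z_extent_mm: float, slice_thickness_mm: float) -> int:
    """Slices per VOI region: the largest count staying within ``z_extent_mm``.

    5.4 mm at 0.4 mm slices gives 13 (5.2 mm), at 0.6 mm slices exactly 9.
    """
    return max(int(np.floor(z_extent_mm / slice_thickness_mm + 1e-9)), 1)


def voi_boxes(volume_shape: tuple[int, int, int], pixel_spacing_mm: float,
              slice_thickness_mm: float, n_regions: int = 6,
              vois_per_region: int = 4, in_plane_size: int = 128,
              z_extent_mm: float = 5.4,
              phantom_diameter_mm: float | None = None
              ) -> tuple[tuple[int, int, int, int, int, int], ...]:
    """Index bounds of the VOI ensemble, disjoint by construction.

    Regions are contiguous along z and centred in the slab (avoiding the
    extremities). Within each region the in-plane blocks abut the image
    centre: 4 blocks fill the four quadrants, 2 sit left/right, 1 is
    centred. If ``phantom_diameter_mm`` is given, every block corner must
    lie inside that circle, else a :class:`GeometryError` names the block.
    """
    nz, ny, nx = volume_shape
    n_z = slices_per_region(z_extent_mm, slice_thickness_mm)
    total_z = n_regions * n_z
    if total_z > nz:
        raise GeometryError(
            f"{n_regions} regions x {n_z} slices = {total_z} exceed the "
            f"{nz}-slice volume")
    z_start = (nz - total_z) // 2
    s = in_plane_size
    cy, cx = ny // 2, nx // 2
    if vois_per_region == 4:
        planes = [(cy - s, cy, cx - s, cx), (cy - s, cy, cx, cx + s),
                  (cy, cy + s, cx - s, cx), (cy, cy + s, cx, cx + s)]
    elif vois_per_region == 2:
        planes = [(cy - s // 2, cy - s // 2 + s, cx - s, cx),
                  (cy - s // 2, cy - s // 2 + s, cx, cx + s)]
    elif vois_per_region == 1:
        planes = [(cy - s // 2, cy - s // 2 + s, cx - s // 2, cx - s // 2 + s)]
    else:
        raise ValueError("vois_per_region must be 1, 2 or 4")
    boxes = []
    for g in range(n_regions):
        z0 = z_start + g * n_z
        for (y0, y1, x0, x1) in planes:
            if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
                raise GeometryError(
                    f"VOI block rows [{y0},{y1}) cols [{x0},{x1}) exits the "
                    f"{ny}x{nx} image")
            if phantom_diameter_mm is not None:
                r = phantom_diameter_mm / 2.0
                for py in (y0, y1 - 1):
                    for px in (x0, x1 - 1):
                        dy = (py - (ny - 1) / 2.0) * pixel_spacing_mm
                        dx = (px - (nx - 1) / 2.0) * pixel_spacing_mm
                        if np.hypot(dy, dx) > r:
                            raise GeometryError(
                                f"VOI block rows [{y0},{y1}) cols [{x0},{x1}) "
                                f"exits the phantom (corner at "
                                f"{np.hypot(dy, dx):.1f} mm > {r:.1f} mm)")
            boxes.append((z0, z0 + n_z, y0, y1, x0, x1))
    return tuple(boxes)


def extract_vois(volume: OnlyNoiseVolume | np.ndarray, pixel_spacing_mm: float,
                 slice_thickness_mm: float, n_regions: int = 6,
                 vois_per_region: int = 4, in_plane_size: int = 128,
                 z_extent_mm: float = 5.4,
                 phantom_diameter_mm: float | None = None) -> VoiEnsemble:
    """Cut the disjoint VOI ensemble out of one only-noise volume."""
    values = volume.values if isinstance(volume, OnlyNoiseVolume) else volume
    boxes = voi_boxes(values.shape, pixel_spacing_mm, slice_thickness_mm,
                      n_regions, vois_per_region, in_plane_size, z_extent_mm,
                      phantom_diameter_mm)
    vois = [values[z0:z1, y0:y1, x0:x1] for (z0, z1, y0, y1, x0, x1) in boxes]
    return VoiEnsemble(vois=vois, boxes=boxes, in_plane_size=in_plane_size,
                       n_z=boxes[0][1] - boxes[0][0], n_regions=n_regions,
                       vois_per_region=vois_per_region)


def compute_nps3d(vois: list[np.ndarray] | VoiEnsemble,
                  voxel_sizes_mm: tuple[float, float, float],
                  halve: bool = True, window: str | None = None) -> NPS3D:
    """Ensemble-averaged 3D NPS of a set of identically shaped VOIs.

    ``voxel_sizes_mm`` is (dz, dy, dx). ``halve=True`` applies the 1/2
    compensation for difference-volume input; pass ``False`` for VOIs taken
    directly from single-repeat noise fields. ``window="hann"`` applies a
    separable Hann taper (off by default: the plain periodogram matches the
    estimator definition).
    """
    if isinstance(vois, VoiEnsemble):
        vois = vois.vois
    if not vois:
        raise ValueError("need at least one VOI")
    shape = vois[0].shape
    if any(v.shape != shape for v in vois):
        raise ValueError("all VOIs must share one shape")
    nzv, nyv, nxv = shape
    dz, dy, dx = voxel_sizes_mm
    if window is None:
        taper = None
        power_norm = 1.0
    elif window == "hann":
        wz = np.hanning(nzv)[:, None, None] if nzv > 1 else np.ones((1, 1, 1))
        wy = np.hanning(nyv)[None, :, None]
        wx = np.hanning(nxv)[None, None, :]
        taper = wz * wy * wx
        power_norm = np.mean(taper ** 2)
    else:
        raise ValueError(f"unknown window {window!r}")
    acc = np.zeros(shape, dtype=np.float64)
    for v in vois:
        v = v.astype(np.float64)
        v = v - v.mean()
        if taper is not None:
            v = v * taper
        acc += np.abs(np.fft.fftn(v)) ** 2
    acc /= len(vois) * power_norm
    scale = (dx * dy * dz) / (nxv * nyv * nzv)
    if halve:
        scale *= 0.5
    values = np.fft.fftshift(acc * scale)
    f_z = np.fft.fftshift(np.fft.fftfreq(nzv, d=dz))
    f_y = np.fft.fftshift(np.fft.fftfreq(nyv, d=dy))
    f_x = np.fft.fftshift(np.fft.fftfreq(nxv, d=dx))
    return NPS3D(values=values, f_z=f_z, f_y=f_y, f_x=f_x,
                 voxel_sizes_mm=(dz, dy, dx), halved=halve)


def nps_integral(nps3d: NPS3D) -> float:
    """Integral of the NPS over the full frequency cell (= noise variance, HU^2)."""
    dz, dy, dx = nps3d.voxel_sizes_mm
    dfz = 1.0 / (nps3d.f_z.size * dz)
    dfy = 1.0 / (nps3d.f_y.size * dy)
    dfx = 1.0 / (nps3d.f_x.size * dx)
    return float(nps3d.values.sum() * dfz * dfy * dfx)


def radial_nps(nps3d: NPS3D, n_angles: int = 100) -> RadialNPS:
    """Angle-averaged radial profile of the fz = 0 plane.

    ``n_angles`` directions uniformly cover [0, pi) (opposite directions are
    redundant by Hermitian symmetry); each profile is sampled by bilinear
    interpolation on a radial grid with the in-plane DFT spacing, from 0 to
    the Nyquist frequency. Radii whose sample point falls outside the
    rectangular DFT grid for some angles (the corner region near Nyquist)
    are averaged over the remaining angles.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    ny, nx = nps3d.f_y.size, nps3d.f_x.size
    if ny != nx or not np.isclose(nps3d.voxel_sizes_mm[1], nps3d.voxel_sizes_mm[2]):
        raise ValueError("radial averaging requires square in-plane VOIs and pixels")
    iz = int(np.argmin(np.abs(nps3d.f_z)))
    plane = nps3d.values[iz]
    dx = nps3d.voxel_sizes_mm[2]
    df = 1.0 / (nx * dx)
    nyquist = 1.0 / (2.0 * dx)
    freqs = np.arange(int(np.floor(nyquist / df)) + 1) * df
    interp = RegularGridInterpolator((nps3d.f_y, nps3d.f_x), plane,
                                     method="linear", bounds_error=False,
                                     fill_value=np.nan)
    angles = np.pi * np.arange(n_angles) / n_angles
    fy = freqs[:, None] * np.sin(angles)[None, :]
    fx = freqs[:, None] * np.cos(angles)[None, :]
    samples = interp(np.stack([fy.ravel(), fx.ravel()], axis=-1))
    samples = samples.reshape(freqs.size, n_angles)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(samples, axis=1)
    return RadialNPS(frequencies_mm1=freqs, values=values, n_angles=n_angles)


def average_radial_over_sets(radials: list[RadialNPS]) -> RadialNPS:
    """Pointwise mean of radial NPS curves over the only-noise volumes."""
    if not radials:
        raise ValueError("need at least one radial NPS")
    f0 = radials[0].frequencies_mm1
    for r in radials[1:]:
        if r.frequencies_mm1.shape != f0.shape or \
                not np.allclose(r.frequencies_mm1, f0):
            raise ValueError("radial grids do not match")
    values = np.mean([r.values for r in radials], axis=0)
    return RadialNPS(frequencies_mm1=f0.copy(), values=values,
                     n_angles=radials[0].n_angles)


def peak_frequency(radial: RadialNPS, smoothing_window: int | None = None) -> float:
    """Frequency of the radial-NPS maximum, excluding the f = 0 bin.

    ``smoothing_window`` applies a centred moving average of that (odd)
    width before the search. Ties break toward the lowest frequency; an
    all-zero curve raises.
    """
    if radial.frequencies_mm1.size < 3:
        raise ValueError("need at least 3 radial points")
    vals = np.asarray(radial.values, dtype=np.float64).copy()
    finite = np.isfinite(vals)
    if not np.any(vals[finite] != 0):
        raise ValueError("peak frequency undefined for an all-zero spectrum")
    if smoothing_window is not None:
        if smoothing_window < 1 or smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        kernel = np.ones(smoothing_window) / smoothing_window
        filled = np.where(finite, vals, 0.0)
        norm = np.convolve(finite.astype(float), kernel, mode="same")
        vals = np.convolve(filled, kernel, mode="same") / np.maximum(norm, 1e-300)
    vals[~finite] = -np.inf
    vals[0] = -np.inf  # residual DC is estimator artifact
    j = int(np.argmax(vals))  # argmax takes the first max: ties -> lowest f
    return float(radial.frequencies_mm1[j])


def estimate_radial_nps(stack: ImageStack, reference_index: int = 0,
                        n_regions: int = 6, vois_per_region: int = 4,
                        in_plane_size: int = 128, z_extent_mm: float = 5.4,
                        n_angles: int = 100,
                        phantom_diameter_mm: float | None = None,
                        smoothing_window: int | None = None
                        ) -> tuple[RadialNPS, NPS3D]:
    """Full-chain radial NPS of a repeated-acquisition stack.

    Per only-noise volume: VOI ensemble -> 3D NPS -> radial profile; the
    returned curve is the mean over volumes, with ``f_p_mm1`` filled in.
    Also returns the 3D NPS averaged over all volumes.
    """
    volumes = make_only_noise_volumes(stack, reference_index)
    boxes = voi_boxes(volumes[0].values.shape, stack.pixel_spacing_mm,
                      stack.slice_thickness_mm, n_regions, vois_per_region,
                      in_plane_size, z_extent_mm, phantom_diameter_mm)
    voxel_sizes = (stack.slice_thickness_mm, stack.pixel_spacing_mm,
                   stack.pixel_spacing_mm)
    radials = []
    acc3d = None
    for vol in volumes:
        vois = [vol.values[z0:z1, y0:y1, x0:x1]
                for (z0, z1, y0, y1, x0, x1) in boxes]
        nps3d = compute_nps3d(vois, voxel_sizes, halve=True)
        radials.append(radial_nps(nps3d, n_angles=n_angles))
        acc3d = nps3d.values if acc3d is None else acc3d + nps3d.values
    mean3d = NPS3D(values=acc3d / len(volumes), f_z=nps3d.f_z, f_y=nps3d.f_y,
                   f_x=nps3d.f_x, voxel_sizes_mm=voxel_sizes, halved=True)
    final = average_radial_over_sets(radials)
    final.f_p_mm1 = peak_frequency(final, smoothing_window=smoothing_window)
    return final, mean3d
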