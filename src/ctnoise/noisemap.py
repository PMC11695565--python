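"""Voxelwise noise maps and noise-reduction maps from repeated acquisitions.

The noise map is the per-voxel sample standard deviation of the CT number
across repeats; it is the primary object of the whole characterization and
everything downstream (non-uniformity index, histogram descriptors) consumes
it. Reduction maps express, voxel by voxel, how much a comparison
reconstruction lowers the noise relative to a reference, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import circle_inside_image, circle_mask
from .simulate import GeometryError, ImageStack

__all__ = ["NoiseMap", "ReductionMap", "RoiStat",
           "compute_noise_map", "compute_reduction_map", "roi_statistics"]


@dataclass
class NoiseMap:
    """Per-voxel noise (sample SD across repeats), HU, axes (slice, row, col)."""

    values: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    n_repeats: int
    source_label: str = ""

    @property
    def central_slice(self) -> np.ndarray:
        return self.values[(self.values.shape[0] - 1) // 2]


@dataclass
class ReductionMap:
    """Percent noise reduction of ``comparison`` relative to ``reference``.

    ``values`` holds ``100 * (ref - cmp) / ref``; voxels where the reference
    noise is zero are NaN (masked) rather than infinite, and ``n_masked``
    counts them. Values never exceed 100; negative values mean noise
    amplification.
    """

    values: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    reference_label: str = ""
    comparison_label: str = ""
    n_masked: int = 0

    @property
    def central_slice(self) -> np.ndarray:
        return self.values[(self.values.shape[0] - 1) // 2]


@dataclass(frozen=True)
class RoiStat:
    """Mean/SD over a circular ROI, with its geometry and voxel count."""

    mean: float
    sd: float
    roi_center_mm: tuple[float, float]
    roi_diameter_mm: float
    n_voxels: int
    n_masked: int = 0


def compute_noise_map(stack: ImageStack, slice_selection="central") -> NoiseMap:
    """Noise map of a repeated-acquisition stack.

    Parameters
    ----------
    stack:
        Repeated reconstructions, axes (repeat, slice, row, col).
    slice_selection:
        ``"central"`` keeps only the middle slice (lower median index for an
        even count), ``"all"`` keeps every slice, an integer keeps that
        slice index.

    The estimator is the sample standard deviation with divisor ``n - 1``.
    """
    if stack.n_repeats < 2:
        raise ValueError("need at least 2 repeats to estimate noise")
    vals = stack.values
    if slice_selection == "central":
        idx = (stack.n_slices - 1) // 2
        vals = vals[:, idx:idx + 1]
    elif slice_selection == "all":
        pass
    else:
        idx = int(slice_selection)
        if not 0 <= idx < stack.n_slices:
            raise IndexError(f"slice index {idx} out of range")
        vals = vals[:, idx:idx + 1]
    sd = np.std(vals.astype(np.float64), axis=0, ddof=1)
    return NoiseMap(values=sd, pixel_spacing_mm=stack.pixel_spacing_mm,
                    slice_thickness_mm=stack.slice_thickness_mm,
                    n_repeats=stack.n_repeats, source_label=stack.label)


def compute_reduction_map(reference: NoiseMap, comparison: NoiseMap) -> ReductionMap:
    """Percent-noise-reduction map ``100 * (reference - comparison) / reference``."""
    if reference.values.shape != comparison.values.shape:
        raise GeometryError(
            f"shape mismatch {reference.values.shape} vs {comparison.values.shape}")
    if not np.isclose(reference.pixel_spacing_mm, comparison.pixel_spacing_mm):
        raise GeometryError("pixel spacing mismatch between noise maps")
    ref = reference.values
    zero = ref == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        red = 100.0 * (ref - comparison.values) / ref
    red[zero] = np.nan
    return ReductionMap(values=red,
                        pixel_spacing_mm=reference.pixel_spacing_mm,
                        slice_thickness_mm=reference.slice_thickness_mm,
                        reference_label=reference.source_label,
                        comparison_label=comparison.source_label,
                        n_masked=int(zero.sum()))


def roi_statistics(map_obj: NoiseMap | ReductionMap,
                   center_mm: tuple[float, float] = (0.0, 0.0),
                   diameter_mm: float = 10.0) -> RoiStat:
    """Mean/SD of a map over a circular ROI on its central slice.

    ``center_mm`` is the (y, x) offset of the ROI centre from the image
    centre; membership is by pixel-centre-in-circle. Masked (NaN) voxels are
    excluded and counted. Raises :class:`GeometryError` if the circle is not
    fully inside the image.
    """
    plane = map_obj.central_slice
    sp = map_obj.pixel_spacing_mm
    if not circle_inside_image(plane.shape, sp, diameter_mm, center_mm):
        raise GeometryError(
            f"ROI (centre {center_mm} mm, diameter {diameter_mm} mm) not fully "
            f"inside the image")
    mask = circle_mask(plane.shape, sp, diameter_mm, center_mm)
    vals = plane[mask]
    finite = np.isfinite(vals)
    n_masked = int((~finite).sum())
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError("ROI contains no unmasked voxels")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RoiStat(mean=float(np.mean(vals)), sd=sd, roi_center_mm=center_mm,
                   roi_diameter_mm=diameter_mm, n_voxels=int(vals.size),
                   n_masked=n_masked)
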