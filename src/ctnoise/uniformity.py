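"""Noise non-uniformity index (NUI) over a grid of square ROIs.

The NUI (an AAPM TG-233-style metric) quantifies spatial non-uniformity of a
noise map: a large central circular region is tiled with k disjoint square
ROIs, the mean noise m_i of each ROI is taken, and the NUI is the percent
coefficient of variation of the m_i:

    NUI = (100 / <m>) * sqrt( sum_i (m_i - <m>)^2 / (k - 1) )

with <m> the mean of the m_i. A perfectly uniform noise map gives NUI = 0;
edge effects of iterative reconstruction raise it.

The achieved k depends on pixel rounding of the ROI side, on the grid
alignment, and on the inclusion rule (all four corner pixel centres of the
ROI inside the circle), so the grid builder exposes the alignment and always
reports its k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import pixel_centers_mm
from .noisemap import NoiseMap, ReductionMap

__all__ = ["RoiGrid", "NuiResult", "build_roi_grid", "compute_nui", "nui_from_means"]


@dataclass(frozen=True)
class RoiGrid:
    """Square-ROI tiling of a central circle.

    ``roi_boxes`` are half-open pixel bounds ``(row0, col0, row1, col1)``;
    boxes are pairwise disjoint by construction.
    """

    circle_diameter_mm: float
    roi_size_mm: float
    roi_side_px: int
    roi_boxes: tuple[tuple[int, int, int, int], ...]
    alignment: str
    offset_mm: tuple[float, float]

    @property
    def k(self) -> int:
        return len(self.roi_boxes)


@dataclass(frozen=True)
class NuiResult:
    nui_percent: float
    k: int
    roi_means: np.ndarray
    grand_mean: float


def build_roi_grid(circle_diameter_mm: float, roi_size_mm: float,
                   pixel_spacing_mm: float, image_shape: tuple[int, int],
                   alignment: str = "centered",
                   offset_mm: tuple[float, float] = (0.0, 0.0)) -> RoiGrid:
    """Tile a central circle with disjoint axis-aligned square ROIs.

    The ROI side is ``round(roi_size_mm / pixel_spacing_mm)`` pixels so all
    ROIs are congruent. ``alignment="centered"`` centres one ROI on the
    image centre; ``"corner"`` puts an ROI corner there. ``offset_mm``
    shifts the whole grid. An ROI is kept iff the centres of its four
    corner pixels lie within the circle and the box is inside the image.
    """
    if roi_size_mm >= circle_diameter_mm:
        return RoiGrid(circle_diameter_mm, roi_size_mm,
                       max(int(round(roi_size_mm / pixel_spacing_mm)), 0), (),
                       alignment, offset_mm)
    side = int(round(roi_size_mm / pixel_spacing_mm))
    if side < 2:
        raise ValueError("ROI side must be at least 2 pixels")
    if alignment not in ("centered", "corner"):
        raise ValueError(f"unknown alignment {alignment!r}")
    rows, cols = image_shape
    radius = circle_diameter_mm / 2.0
    # pixel-centre coordinates (mm from image centre) along each axis
    ypos = pixel_centers_mm(rows, pixel_spacing_mm)
    xpos = pixel_centers_mm(cols, pixel_spacing_mm)

    def base_start(n: int, off_mm: float) -> float:
        c = (n - 1) / 2.0 + off_mm / pixel_spacing_mm
        return c - (side - 1) / 2.0 if alignment == "centered" else c

    r_base = base_start(rows, offset_mm[0])
    c_base = base_start(cols, offset_mm[1])
    n_cells = int(np.ceil(radius / (side * pixel_spacing_mm))) + 1
    boxes = []
    for j in range(-n_cells, n_cells + 1):
        r0 = int(round(r_base + j * side))
        r1 = r0 + side
        if r0 < 0 or r1 > rows:
            continue
        for i in range(-n_cells, n_cells + 1):
            c0 = int(round(c_base + i * side))
            c1 = c0 + side
            if c0 < 0 or c1 > cols:
                continue
            corners_ok = all(
                np.hypot(ypos[r], xpos[c]) <= radius
                for r in (r0, r1 - 1) for c in (c0, c1 - 1))
            if corners_ok:
                boxes.append((r0, c0, r1, c1))
    return RoiGrid(circle_diameter_mm, roi_size_mm, side, tuple(boxes),
                   alignment, offset_mm)


def nui_from_means(roi_means: np.ndarray) -> NuiResult:
    """NUI of a set of per-ROI mean noise values (percent CV, divisor k - 1)."""
    m = np.asarray(roi_means, dtype=np.float64)
    k = m.size
    if k < 2:
        raise ValueError("NUI requires at least 2 ROIs")
    grand = float(m.mean())
    if grand == 0:
        raise ZeroDivisionError("NUI undefined: mean ROI noise is zero")
    nui = 100.0 / grand * float(np.sqrt(np.sum((m - grand) ** 2) / (k - 1)))
    return NuiResult(nui_percent=nui, k=k, roi_means=m, grand_mean=grand)


def compute_nui(map_obj: NoiseMap | ReductionMap, grid: RoiGrid) -> NuiResult:
    """NUI of a noise map over a prepared ROI grid (central slice)."""
    plane = map_obj.central_slice
    if grid.k < 2:
        raise ValueError("NUI requires a grid with at least 2 ROIs")
    for (r0, c0, r1, c1) in grid.roi_boxes:
        if r1 > plane.shape[0] or c1 > plane.shape[1]:
            raise ValueError("ROI grid extends beyond the map")
    means = np.array([np.nanmean(plane[r0:r1, c0:c1])
                      for (r0, c0, r1, c1) in grid.roi_boxes])
    return nui_from_means(means)
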