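"""Pixel-grid geometry helpers.

Conventions used across the package:

* image arrays are indexed ``(slice, row, col)``; the in-plane axes map to
  ``(y, x)`` with row -> y and col -> x;
* in-plane positions are expressed in mm relative to the image centre, the
  centre of pixel ``i`` along an axis of ``n`` pixels sitting at
  ``(i - (n - 1) / 2) * spacing``;
* circular-region membership is decided by a pixel-centre-in-circle test.
"""

from __future__ import annotations

import numpy as np


def pixel_centers_mm(n: int, spacing_mm: float) -> np.ndarray:
    """Positions (mm, relative to image centre) of the pixel centres along one axis."""
    return (np.arange(n) - (n - 1) / 2.0) * spacing_mm


def radius_grid_mm(shape: tuple[int, int], spacing_mm: float,
                   center_mm: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """2D grid of distances (mm) of each pixel centre from ``center_mm`` = (y, x)."""
    y = pixel_centers_mm(shape[0], spacing_mm) - center_mm[0]
    x = pixel_centers_mm(shape[1], spacing_mm) - center_mm[1]
    return np.hypot(y[:, None], x[None, :])


def circle_mask(shape: tuple[int, int], spacing_mm: float, diameter_mm: float,
                center_mm: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within the circle (inclusive)."""
    return radius_grid_mm(shape, spacing_mm, center_mm) <= diameter_mm / 2.0


def circle_inside_image(shape: tuple[int, int], spacing_mm: float, diameter_mm: float,
                        center_mm: tuple[float, float] = (0.0, 0.0)) -> bool:
    """Whether the circle lies fully inside the physical extent of the image."""
    r = diameter_mm / 2.0
    for ax, c in zip(shape, center_mm):
        half_extent = ax * spacing_mm / 2.0
        if c - r < -half_extent or c + r > half_extent:
            return False
    return True
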