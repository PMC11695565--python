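"""Descriptors of the noise-value distribution inside a central circular ROI.

Median, interquartile range, skewness and excess kurtosis summarize the
histogram of noise-map values; for repeated acquisitions of a homogeneous
phantom the distribution is approximately a scaled chi (near-Gaussian for
many repeats), and departures — tails, skew growth with iterative power —
are the quantities of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import circle_inside_image, circle_mask
from .noisemap import NoiseMap
from .simulate import GeometryError

__all__ = ["HistogramDescriptors", "describe_values", "describe_noise_histogram"]

#: Quantile rule used for median/IQR (numpy's linear interpolation between
#: order statistics); recorded in the result because conventions differ.
QUANTILE_RULE = "linear"


@dataclass(frozen=True)
class HistogramDescriptors:
    """Distribution summary of noise values.

    ``skewness`` is the third standardized central moment and
    ``kurtosis_excess`` the fourth minus 3 (zero for a Gaussian). Both are
    ``None`` (``moments_defined=False``) for a constant sample, where they
    are undefined rather than zero. ``moment_estimator`` records whether
    plain ``1/n`` central moments ("population", the default) or
    bias-corrected estimators were used.
    """

    median: float
    iqr: float
    skewness: float | None
    kurtosis_excess: float | None
    n_values: int
    moments_defined: bool = True
    quantile_rule: str = QUANTILE_RULE
    moment_estimator: str = "population"


def describe_values(values: np.ndarray,
                    moment_estimator: str = "population") -> HistogramDescriptors:
    """Histogram descriptors of a flat sample of noise values."""
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 values for histogram descriptors")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    m2 = np.mean((v - v.mean()) ** 2)
    if np.all(v == v[0]) or m2 == 0:
        return HistogramDescriptors(median=float(med), iqr=float(q3 - q1),
                                    skewness=None, kurtosis_excess=None,
                                    n_values=v.size, moments_defined=False,
                                    moment_estimator=moment_estimator)
    if moment_estimator == "population":
        d = v - v.mean()
        skew = float(np.mean(d ** 3) / m2 ** 1.5)
        kurt = float(np.mean(d ** 4) / m2 ** 2 - 3.0)
    elif moment_estimator == "unbiased":
        from scipy import stats
        skew = float(stats.skew(v, bias=False))
        kurt = float(stats.kurtosis(v, fisher=True, bias=False))
    else:
        raise ValueError(f"unknown moment_estimator {moment_estimator!r}")
    return HistogramDescriptors(median=float(med), iqr=float(q3 - q1),
                                skewness=skew, kurtosis_excess=kurt,
                                n_values=v.size,
                                moment_estimator=moment_estimator)


def describe_noise_histogram(map_obj: NoiseMap, circle_diameter_mm: float = 150.0,
                             moment_estimator: str = "population"
                             ) -> HistogramDescriptors:
    """Descriptors of noise-map values within a central circular ROI."""
    plane = map_obj.central_slice
    sp = map_obj.pixel_spacing_mm
    if not circle_inside_image(plane.shape, sp, circle_diameter_mm):
        raise GeometryError(
            f"histogram circle (diameter {circle_diameter_mm} mm) not inside image")
    mask = circle_mask(plane.shape, sp, circle_diameter_mm)
    return describe_values(plane[mask], moment_estimator=moment_estimator)
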