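"""Synthetic repeated CT phantom acquisitions with known noise ground truth.

The simulator emulates what a stack of repeated axial reconstructions of a
quality-assurance phantom looks like from the point of view of noise
analysis: a noiseless object (water cylinder or a sensitometry module with
contrast inserts), plus stationary correlated Gaussian noise whose radial
noise power spectrum (NPS) is prescribed analytically, optionally passed
through an edge-aware smoothing operator that mimics the noise-reduction
behaviour of iterative reconstruction algorithms.

No projection/sinogram physics is simulated: the analysis pipeline this
package implements operates on reconstructed images only, and reconstruction
kernels are represented purely through the noise magnitude and NPS-shape
parameters of :class:`NoiseModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import pixel_centers_mm

__all__ = [
    "Insert",
    "PhantomSpec",
    "AcquisitionConfig",
    "NoiseModel",
    "IterativeEmulation",
    "ImageStack",
    "water_cylinder_spec",
    "ctp404_spec",
    "build_phantom_image",
    "synthesize_noise_volume",
    "emulate_iterative",
    "generate_acquisitions",
    "write_fixture",
]


class GeometryError(ValueError):
    """A phantom/ROI/VOI does not fit the requested image geometry."""


@dataclass(frozen=True)
class Insert:
    """A cylindrical contrast insert: centre offset (x, y) in mm from the phantom centre."""

    name: str
    center_xy_mm: tuple[float, float]
    diameter_mm: float
    hu: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric/HU description of the simulated object."""

    kind: str  # "water_cylinder" | "insert_module"
    phantom_diameter_mm: float
    background_hu: float = 0.0
    outside_hu: float = -1000.0
    inserts: tuple[Insert, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("water_cylinder", "insert_module"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.phantom_diameter_mm <= 0:
            raise ValueError("phantom_diameter_mm must be positive")
        r = self.phantom_diameter_mm / 2.0
        for ins in self.inserts:
            if ins.diameter_mm <= 0:
                raise ValueError(f"insert {ins.name!r}: diameter must be positive")
            cx, cy = ins.center_xy_mm
            if np.hypot(cx, cy) + ins.diameter_mm / 2.0 > r:
                raise GeometryError(
                    f"insert {ins.name!r} extends outside the phantom circle")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Matrix/FOV/slab geometry and repetition count of one simulated protocol."""

    matrix_size: int = 512
    fov_mm: float = 220.0
    slice_thickness_mm: float = 0.4
    n_slices: int = 1
    n_repeats: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size < 2 or self.fov_mm <= 0:
            raise ValueError("matrix_size >= 2 and fov_mm > 0 required")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def pixel_spacing_mm(self) -> float:
        return self.fov_mm / self.matrix_size

    @property
    def nyquist_mm1(self) -> float:
        return 1.0 / (2.0 * self.pixel_spacing_mm)


@dataclass(frozen=True)
class NoiseModel:
    """Stationary Gaussian noise with a prescribed in-plane NPS shape.

    ``nps_shape="white"`` gives i.i.d. voxel noise. ``"ramp_bandpass"``
    shapes the in-plane spectrum as ``NPS(f) ∝ f**a * exp(-(f/f_c)**b)``,
    the classic band-pass form of filtered-backprojection noise texture:
    the ramp exponent ``a`` controls low-frequency suppression and
    ``(f_c, b)`` the apodization roll-off, so the radial NPS of the
    generated noise peaks at ``f_c * (a/b)**(1/b)`` (``= f_c`` for
    ``a = b = 1``). Noise is independent between slices: the analysis
    consumes the ``f_z = 0`` plane of the 3D NPS, so in-plane texture is
    the part that must be emulated.

    ``sigma`` is the target per-voxel standard deviation (HU) of a single
    acquisition; the synthesis filter is normalized analytically so the
    realized SD matches it in expectation. ``sigma_modulation``, if given,
    is a strictly positive unitless field (2D in-plane, or full 3D) that
    multiplies the noise voxelwise, for spatially varying noise levels.
    """

    sigma_hu: float = 10.0
    nps_shape: str = "white"  # "white" | "ramp_bandpass"
    exponent_a: float = 1.0
    cutoff_fc_mm1: float = 0.2
    falloff_b: float = 1.0
    sigma_modulation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sigma_hu < 0:
            raise ValueError("sigma_hu must be >= 0")
        if self.nps_shape not in ("white", "ramp_bandpass"):
            raise ValueError(f"unknown nps_shape {self.nps_shape!r}")
        if self.sigma_modulation is not None and not np.all(self.sigma_modulation > 0):
            raise ValueError("sigma_modulation must be strictly positive")

    def validate_for(self, config: AcquisitionConfig) -> None:
        if self.nps_shape == "ramp_bandpass":
            if not (0.0 < self.cutoff_fc_mm1 <= config.nyquist_mm1):
                raise ValueError(
                    f"cutoff_fc_mm1={self.cutoff_fc_mm1} outside (0, Nyquist="
                    f"{config.nyquist_mm1:.4f}] mm^-1")


@dataclass(frozen=True)
class IterativeEmulation:
    """Edge-aware noise-reduction operator standing in for iterative reconstruction.

    Each repeat is blended with a smoothed version of itself,
    ``out = (1 - w) * in + w * smooth(in)`` with a voxelwise weight
    ``w = strength * exp(-edge_preservation * |∇phantom|)``. The gradient is
    taken on the *noiseless* phantom (HU/mm), so smoothing is suppressed
    near material boundaries — reproducing the reduced effectiveness of
    iterative noise reduction near edges — while the operator's ground
    truth stays analytic. ``strength = 0`` is the identity.
    """

    strength: float = 0.0
    smoothing_scale_mm: float = 1.3
    edge_preservation: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must be in [0, 1]")
        if self.smoothing_scale_mm <= 0:
            raise ValueError("smoothing_scale_mm must be positive")
        if self.edge_preservation < 0:
            raise ValueError("edge_preservation must be >= 0")

    def kernel_size_px(self, pixel_spacing_mm: float) -> int:
        """Odd in-plane box-kernel side, nearest to smoothing_scale in pixels (min 3)."""
        size = int(round(self.smoothing_scale_mm / pixel_spacing_mm))
        if size % 2 == 0:
            size += 1
        return max(size, 3)


@dataclass
class ImageStack:
    """N repeated reconstructions of one phantom/protocol with shared geometry.

    ``values`` has axes ``(repeat, slice, row, col)`` and is in HU.
    """

    values: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("values must be 4D (repeat, slice, row, col)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stack contains non-finite values")

    @property
    def n_repeats(self) -> int:
        return self.values.shape[0]

    @property
    def n_slices(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# phantom presets

def water_cylinder_spec(diameter_mm: float = 200.0) -> PhantomSpec:
    """Homogeneous water cylinder (water = 0 HU, air outside)."""
    return PhantomSpec(kind="water_cylinder", phantom_diameter_mm=diameter_mm,
                       background_hu=0.0, outside_hu=-1000.0)


#: Nominal sensitometry-insert HU values (editable defaults, not used in any math).
CTP404_INSERT_HU: dict[str, float] = {
    "air": -1000.0,
    "PMP": -200.0,
    "LDPE": -100.0,
    "polystyrene": -35.0,
    "acrylic": 120.0,
    "Delrin": 340.0,
    "Teflon": 990.0,
}


def ctp404_spec(diameter_mm: float = 200.0,
                insert_radius_mm: float = 58.4,
                insert_diameter_mm: float = 12.2,
                insert_hu: dict[str, float] | None = None,
                background_hu: float = 20.0) -> PhantomSpec:
    """Sensitometry module with seven contrast inserts on a ring.

    Insert HU values default to the nominal CTP404 materials and can be
    overridden per material via ``insert_hu``.
    """
    hu = dict(CTP404_INSERT_HU)
    if insert_hu:
        hu.update(insert_hu)
    names = list(hu)
    inserts = []
    for i, name in enumerate(names):
        theta = 2.0 * np.pi * i / len(names)
        cx = insert_radius_mm * np.cos(theta)
        cy = insert_radius_mm * np.sin(theta)
        inserts.append(Insert(name=name, center_xy_mm=(cx, cy),
                              diameter_mm=insert_diameter_mm, hu=hu[name]))
    return PhantomSpec(kind="insert_module", phantom_diameter_mm=diameter_mm,
                       background_hu=background_hu, outside_hu=-1000.0,
                       inserts=tuple(inserts))


# ---------------------------------------------------------------------------
# operations

def build_phantom_image(spec: PhantomSpec, config: AcquisitionConfig) -> np.ndarray:
    """Noiseless 3D image (slice, row, col) of the phantom, in HU.

    Pixel membership is by centre-in-circle; the image is identical across
    slices. Raises :class:`GeometryError` if the phantom does not fit the FOV.
    """
    if spec.phantom_diameter_mm > config.fov_mm:
        raise GeometryError(
            f"phantom diameter {spec.phantom_diameter_mm} mm exceeds FOV "
            f"{config.fov_mm} mm")
    n = config.matrix_size
    sp = config.pixel_spacing_mm
    y = pixel_centers_mm(n, sp)
    x = pixel_centers_mm(n, sp)
    ry = y[:, None]
    rx = x[None, :]
    plane = np.full((n, n), spec.outside_hu, dtype=np.float64)
    inside = np.hypot(ry, rx) <= spec.phantom_diameter_mm / 2.0
    plane[inside] = spec.background_hu
    for ins in spec.inserts:
        cx, cy = ins.center_xy_mm
        m = np.hypot(ry - cy, rx - cx) <= ins.diameter_mm / 2.0
        plane[m] = ins.hu
    return np.broadcast_to(plane, (config.n_slices, n, n)).copy()


def _ramp_bandpass_filter(n: int, spacing_mm: float, a: float, fc: float,
                          b: float) -> np.ndarray:
    """DFT-domain amplitude filter with |H|^2 ∝ f^a exp(-(f/fc)^b), unit mean power."""
    f = np.fft.fftfreq(n, d=spacing_mm)
    fr = np.hypot(f[:, None], f[None, :])
    with np.errstate(divide="ignore"):
        power = np.where(fr > 0, fr, 0.0) ** a * np.exp(-((fr / fc) ** b))
    power[0, 0] = 0.0 if a > 0 else np.exp(0.0)
    h = np.sqrt(power)
    # unit mean |H|^2 so filtered unit-variance white noise keeps unit variance
    h /= np.sqrt(np.mean(h ** 2))
    return h


def synthesize_noise_volume(config: AcquisitionConfig, model: NoiseModel,
                            repeat_index: int) -> np.ndarray:
    """One zero-mean Gaussian noise realization, shape (n_slices, N, N), in HU.

    The random stream is keyed by ``(config.seed, repeat_index)`` so any
    repeat is reproducible in isolation and distinct repeats are
    statistically independent. For the ``ramp_bandpass`` shape the noise is
    produced by Fourier-domain filtering of white noise, slice by slice,
    with an analytically normalized filter so the per-voxel SD equals
    ``model.sigma_hu`` in expectation.
    """
    model.validate_for(config)
    n = config.matrix_size
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, repeat_index]))
    if model.sigma_hu == 0:
        return np.zeros((config.n_slices, n, n))
    white = rng.standard_normal((config.n_slices, n, n))
    if model.nps_shape == "white":
        noise = model.sigma_hu * white
    else:
        h = _ramp_bandpass_filter(n, config.pixel_spacing_mm, model.exponent_a,
                                  model.cutoff_fc_mm1, model.falloff_b)
        spectrum = np.fft.fft2(white, axes=(-2, -1)) * h
        noise = model.sigma_hu * np.fft.ifft2(spectrum, axes=(-2, -1)).real
    if model.sigma_modulation is not None:
        noise = noise * model.sigma_modulation
    return noise


def emulate_iterative(stack: ImageStack, phantom: np.ndarray,
                      emu: IterativeEmulation) -> ImageStack:
    """Apply the edge-aware noise-reduction blend to every repeat.

    ``phantom`` is the noiseless 3D image the stack was built from; its
    in-plane gradient magnitude (HU/mm) drives the edge-preservation weight.
    """
    if stack.values.shape[1:] != phantom.shape:
        raise GeometryError(
            f"stack geometry {stack.values.shape[1:]} does not match phantom "
            f"{phantom.shape}")
    if emu.strength == 0.0:
        return ImageStack(values=stack.values.copy(),
                          pixel_spacing_mm=stack.pixel_spacing_mm,
                          slice_thickness_mm=stack.slice_thickness_mm,
                          label=stack.label)
    sp = stack.pixel_spacing_mm
    gy, gx = np.gradient(phantom.astype(np.float64), sp, axis=(1, 2))
    grad_mag = np.hypot(gy, gx)
    g = np.exp(-emu.edge_preservation * grad_mag) if emu.edge_preservation > 0 \
        else np.ones_like(grad_mag)
    w = emu.strength * g
    size = emu.kernel_size_px(sp)
    out = np.empty_like(stack.values, dtype=np.float64)
    for r in range(stack.n_repeats):
        vol = stack.values[r].astype(np.float64)
        smoothed = ndimage.uniform_filter(vol, size=(1, size, size), mode="nearest")
        out[r] = (1.0 - w) * vol + w * smoothed
    return ImageStack(values=out.astype(stack.values.dtype),
                      pixel_spacing_mm=stack.pixel_spacing_mm,
                      slice_thickness_mm=stack.slice_thickness_mm,
                      label=f"{stack.label}+ir{emu.strength:g}")


def generate_acquisitions(spec: PhantomSpec, config: AcquisitionConfig,
                          model: NoiseModel,
                          emu: IterativeEmulation | None = None,
                          dtype=np.float32,
                          label: str | None = None) -> ImageStack:
    """Simulate ``n_repeats`` acquisitions: phantom + independent noise (+ emulation)."""
    phantom = build_phantom_image(spec, config)
    n = config.matrix_size
    values = np.empty((config.n_repeats, config.n_slices, n, n), dtype=dtype)
    for r in range(config.n_repeats):
        values[r] = phantom + synthesize_noise_volume(config, model, r)
    stack = ImageStack(values=values,
                       pixel_spacing_mm=config.pixel_spacing_mm,
                       slice_thickness_mm=config.slice_thickness_mm,
                       label=label if label is not None else spec.kind)
    if emu is not None and emu.strength > 0:
        stack = emulate_iterative(stack, phantom, emu)
    return stack


def write_fixture(stack: ImageStack, path, fmt: str = "array_stack") -> None:
    """Write a stack as an on-disk fixture (delegates to :mod:`ctnoise.io`)."""
    from . import io as _io

    if fmt == "array_stack":
        _io.write_array_stack(stack, path)
    elif fmt == "dicom_series":
        _io.write_dicom_series(stack, path)
    else:
        raise ValueError(f"unsupported fixture format {fmt!r}")
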