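# Methods

This note documents the estimators, the simulator they are validated
against, the numerical conventions, and the choices made where more than
one reasonable convention exists.

## Noise maps and ROI statistics

The noise map is the per-voxel sample standard deviation across repeats
with divisor n − 1 (the convention is not universal in the QA literature;
the unbiased-variance form is the default here and is what the tests
calibrate against). `slice_selection="central"` keeps the middle slice,
taking the lower median index for an even slice count.

Reduction maps are `100·(σ_ref − σ_cmp)/σ_ref`; voxels with σ_ref = 0 are
masked (NaN) rather than infinite, excluded from ROI statistics, and
counted in the output. Values are ≤ 100 by construction and may be
negative (noise amplification).

Circular-ROI membership is a pixel-centre-in-circle test (inclusive at the
boundary), with ROI centres given in mm from the image centre; the centre
of pixel i along an axis of n pixels is at (i − (n−1)/2)·spacing. The voxel
count is always reported so the exact ROI discretization is auditable.

## Non-uniformity index

NUI is the percent coefficient of variation (divisor k − 1) of the mean
noise over k congruent square ROIs tiling a central circle. The grid
builder rounds the ROI side to the nearest whole pixel (so every m_i
averages the same number of voxels), places ROIs on a regular disjoint
grid with a selectable alignment ("centered": one ROI centred on the image
centre; "corner": an ROI corner there; plus an arbitrary mm offset), and
keeps an ROI iff its four corner pixel centres lie inside the circle. The
achieved k depends on pixel size, alignment and inclusion rule — at the
512-matrix protocol geometry (0.4297 mm pixels, 15 cm circle, 8 mm ROIs)
the centred grid yields k in the ~240s — so k is always reported next to
the NUI value rather than assumed.

For stationary noise the NUI measures pure estimator sampling error and
decays like 1/√(2(n−1)) with the repeat count; the validation suite checks
this decay, and it is the reason NUI values from different repeat counts
are not directly comparable.

## Histogram descriptors

Median and IQR use linear interpolation between order statistics (numpy's
default quantile rule; recorded in the result since conventions differ).
Skewness and excess kurtosis use plain 1/n central moments by default —
matching the "fourth moment minus 3" definition — with a bias-corrected
option (`moment_estimator="unbiased"`). For a constant sample the moments
are reported as undefined (None with a flag), not zero. Noise-map values
from Gaussian repeats follow a scaled chi distribution: slightly
right-skewed, with the skew shrinking as repeats grow; the tests verify
this qualitative behaviour rather than a specific value.

## 3D and radial NPS

Only-noise volumes subtract one fixed reference repeat from each of the
remaining n − 1; the estimator's ½ factor compensates the doubled
variance. Using a single shared reference makes the n − 1 volumes mutually
correlated; this is part of the estimation recipe and is absorbed by the
ensemble averaging (it inflates the estimator variance somewhat but not
its expectation, as the difference-vs-direct equivalence study confirms).

The VOI ensemble is deterministic: contiguous z-regions centred in the
slab (avoiding slab extremities), each region holding 1, 2 or 4 disjoint
in-plane blocks abutting the image centre (quadrants for 4). Slices per
region are the largest count staying within the requested z extent
(5.4 mm → 13 slices at 0.4 mm, 9 at 0.6 mm). If a phantom diameter is
supplied, every block corner must lie inside it; violations raise an error
naming the block.

Each VOI is mean-subtracted before the 3D FFT (difference volumes are
zero-mean in expectation only; residual DC would otherwise leak into the
lowest bins). No taper is applied by default — the plain periodogram is
the estimator definition — with an optional Hann window for strongly
coloured spectra. The reported 3D NPS is in HU²·mm³ on the fftshifted DFT
grid.

The radial curve samples the fz = 0 plane by bilinear interpolation along
100 directions uniform in [0, π) (opposite directions are redundant by
Hermitian symmetry), on a radial grid with the DFT spacing 1/(N·Δx) from 0
to the in-plane Nyquist. Radii whose sample point leaves the rectangular
grid for some angles (the corner region near Nyquist on even-sized grids)
average over the remaining angles. The reported curve is the fz = 0 slice
of the 3D estimator, not rescaled to a 2D NPS; the units make this
explicit. The final curve averages the per-volume radial curves pointwise.

Peak frequency is the argmax of the radial curve excluding the f = 0 bin
(residual DC is estimator artifact and physical texture peaks are strictly
positive), ties breaking toward the lowest frequency, with an optional
centred moving-average window applied first. For band-pass textures of the
form f·exp(−f/f_c) the peak is extremely flat — the curve drops only ~0.1 %
one bin away at protocol spacing — so the raw argmax rides on per-bin
estimator noise; the validation studies use a fixed 5-bin window, chosen
from that flatness analysis, and the window in force is always part of the
result.

## Simulator

The simulator emulates reconstructed-image noise only; there is no
projection/sinogram or spectral physics, and reconstruction kernels are
represented purely by the noise parameters (σ, and the NPS shape
f^a·exp(−(f/f_c)^b)). Defaults mirror a modern thin-slice phantom
protocol: 40 repeats, 512² matrix over a 220 mm FOV, 0.4–0.6 mm slices, a
20 cm water cylinder, and an insert module with seven CTP404-like contrast
rods (nominal HU from the phantom datasheet, editable per material — they
parameterize the object, never the estimators). Noise is stationary
Gaussian, correlated in-plane via Fourier-domain filtering of white noise
and independent between slices: the analysis consumes the fz = 0 plane of
the 3D NPS, so in-plane texture is what must be faithful. The synthesis
filter is normalized analytically (unit mean |H|²), so the per-voxel SD
equals σ in expectation with no empirical rescaling; realized SDs match
within 2 % at 128³ voxels. Random streams are keyed by (seed,
repeat_index), making any repeat reproducible in isolation and distinct
repeats independent.

The iterative-reconstruction emulator blends each repeat with a smoothed
copy of itself, out = (1−w)·in + w·smooth(in), where
w = strength·exp(−edge_preservation·|∇phantom|) uses the *noiseless*
phantom gradient (HU/mm), keeping the operator's ground truth analytic.
The smoother is an odd-sized in-plane box kernel (side ≈
smoothing_scale/pixel, minimum 3); at 3×3 the filter norm is exactly 1/3,
giving the closed-form 66.7 % reduction oracle. Strength 0 is the
identity; noise is non-increasing in strength; with edge preservation on,
noise reduction is weaker near HU gradients, reproducing the edge effect
that drives NUI upward on insert phantoms.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real scanners: nonstationarity of real iterative
reconstructions (the emulator's weight field is deterministic, real
algorithms adapt to the noisy data), inter-slice noise correlation, beam
hardening/scatter artifacts, dose-dependent noise scaling across the FOV,
and any detector-physics difference between scanner types. Results on real
data depend on those; the package's claims are about estimator
correctness, which the synthetic ground truth fully exercises.

## Validation problem sizes

The validation studies (`ctnoise.validation`, mirrored by
`scripts/acceptance.py`) run at protocol-scale ensembles chosen to keep a
desk-class machine comfortable: 40 repeats; 39 only-noise volumes; 24 VOIs
of 128 × 128 × 13; a 256-pixel matrix. For the texture study the 256²
matrix spans half the FOV so the pixel pitch (0.4297 mm) — and with it the
VOI frequency grid and radial bin width — matches the 512-matrix protocol;
the noise fields there contain no phantom, so pixel pitch is the only
geometric quantity that matters. The trend study uses strengths 0–1 in
steps of 0.25, 64² VOIs inside the 20 cm phantom, and an insert-module
stack with edge_preservation = 0.01 mm/HU. Tolerances follow the
underlying statistics: 2 % parameter recovery where the SE is a few per
mil, 5 % on Parseval integrals, 10 % NRMSD on curve shapes, one radial bin
on f_p, and three asymptotic SEs on moment recovery.

## Known limitations

* The NUI k achieved by a given alignment is geometry-sensitive; compare
  NUI values only at matched k and grid settings.
* Radial bins near Nyquist average fewer angles (rectangular-grid corner);
  treat the top ~10 % of the frequency axis with care.
* The DICOM writer emits a minimal CT-image IOD (geometry, rescale,
  int16 pixels) sufficient for round-tripping QA stacks, not a complete
  vendor-grade header.
* `compute_noise_map` loads the full 4D stack in memory; at 40 × 512² ×
  many slices use float32 stacks (the simulator's default).
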