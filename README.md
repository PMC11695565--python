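# ctnoise — voxelwise CT noise characterization

`ctnoise` implements the repeated-acquisition ("ensemble") approach to CT
image-noise analysis used in phantom quality-assurance studies. Instead of
the usual single-ROI standard deviation — which is only meaningful for
stationary, uncorrelated noise — the same phantom is scanned N times
without table movement and noise is characterized voxel by voxel:

* **Noise map** — per-voxel sample standard deviation of the CT number
  across the N repeats (HU), and **reduction maps**
  `100·(σ_ref − σ_cmp)/σ_ref` comparing reconstructions voxelwise.
* **Non-uniformity index (NUI)** — an AAPM TG-233-style metric: a 15 cm
  central circle is tiled with k disjoint 8 mm × 8 mm ROIs with mean noise
  values m_i, and

  NUI = (100 / ⟨m⟩) · √( Σᵢ (mᵢ − ⟨m⟩)² / (k − 1) ),

  the percent coefficient of variation of local noise.
* **Histogram descriptors** — median, IQR, skewness and excess kurtosis
  (fourth standardized moment minus 3) of noise values in a central circle.
* **3D noise power spectrum** — from "only-noise" volumes (each repeat
  minus a reference repeat) over an ensemble of disjoint parallelepiped
  VOIs:

  NPS(fx, fy, fz) = ½ · (Δx Δy Δz)/(Nx Ny Nz) · ⟨|FFT₃(VOI)|²⟩  [HU²·mm³],

  with the ½ compensating the variance doubling of the subtraction. The
  fz = 0 plane is reduced to a radial curve by averaging 100 uniformly
  spaced angular profiles, and the **peak frequency f_p** summarizes the
  noise texture (f_p shifts toward low frequencies under smoothing-type
  iterative reconstruction).

Because real repeated-acquisition series are rarely shareable, the package
ships a first-class **simulator**: cylindrical water phantoms and a
CTP404-like insert module, stationary Gaussian noise with an analytic
band-pass NPS shape `NPS(f) ∝ f^a·exp(−(f/f_c)^b)`, and an edge-aware
smoothing operator that emulates the noise behaviour of iterative
reconstruction (including its reduced effectiveness near edges). Every
estimator can therefore be validated against closed-form ground truth.

Intended users: medical physicists and imaging scientists doing CT QA or
reconstruction-algorithm noise assessment, and anyone needing a tested
reference implementation of the 3D NPS / NUI estimators.

## Worked example

```python
import ctnoise as cn

config = cn.AcquisitionConfig(matrix_size=128, fov_mm=110.0,
                              slice_thickness_mm=0.4, n_slices=1,
                              n_repeats=40, seed=0)
stack = cn.generate_acquisitions(cn.water_cylinder_spec(100.0), config,
                                 cn.NoiseModel(sigma_hu=10.0))
noise_map = cn.compute_noise_map(stack)
stat = cn.roi_statistics(noise_map, diameter_mm=10.0)
print(f"{stat.mean:.2f} HU (SD {stat.sd:.2f} over {stat.n_voxels} voxels)")
```

prints

```
9.96 HU (SD 1.10 over 112 voxels)
```

the central 1 cm ROI mean of the noise map: it recovers the simulated
10 HU noise level (the 0.04 HU shortfall is the well-known small-sample
bias of the SD estimator at 40 repeats), and the ~1.1 HU spread is the
intrinsic ~11 % dispersion of a 40-repeat SD estimate, not spatial
structure. The scripts in `examples/` walk through the other capabilities
one by one (reduction maps and the edge-effect NUI trend, radial NPS and
f_p, and the full pipeline report); each prints its numbers with a note on
what they mean. A thin CLI mirrors the library:

```bash
ctnoise simulate --phantom water --repeats 40 --out stack/
ctnoise noisemap --stack stack/ --out map.npy --report stats.json
ctnoise nui --map map.npy --spacing-mm 0.4297 --circle-mm 150
ctnoise nps --stack stack/ --out nps.json
ctnoise run --config run.yaml
```

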