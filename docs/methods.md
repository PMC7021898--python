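# Methods

This note records the models, numerical choices and known limitations of the
toolkit, in the spirit of a methods section: what is simulated, under which
assumptions, and what the passing tests do and do not demonstrate about real
data.

## Optical model

**Geometry and units.** z = 0 µm is the native focal plane of the detection
objective, positive z toward the objective; lateral origin at the centre of
the central lenslet; arrays are (z, y, x); all lengths in µm, times in
seconds. The object-space footprint of one lenslet is `pitch / M`; the
reconstruction grid supersamples it by an odd factor s (default 5), giving a
lateral voxel of `pitch / (M·s)` — 0.94 µm at 32×, 1.5 µm at 20×.

**Wave-optics PSF.** The amplitude PSF of the objective is the scalar Debye
integral with paraxial defocus,
`h(r, z) = ∫₀¹ J₀(k·NA·r·ρ) · exp(i·k·(NA²/n)·z·ρ²/2) · ρ dρ` (k = 2π/λ),
evaluated on a radial grid and interpolated onto the image plane (object
coordinates scaled by the magnification). The square-aperture lenslet array
contributes a tiled quadratic phase `exp(−i·k₀·r_loc²/(2f))`, and the field
is Fresnel-propagated the focal length f to the sensor with the
transfer-function method; intensity is integrated over camera pixels
(3 field samples per 10 µm pixel by default). Mirror and transpose symmetry
of the train reduce the s² sub-lenslet phases per z-plane to the unique set
0 ≤ a ≤ b ≤ (s−1)/2. Kernels are cropped where cumulative energy reaches
99.9% and normalised by the global mean energy, so the per-z energies stay
interpretable; their spread across z is checked (< 5%) as an
energy-conservation diagnostic. At deep defocus (|z| ≳ 45 µm at 32×) the
defocus phase curvature approaches the Nyquist limit of the default field
sampling at the window edge, and the diagnostic can sit marginally above 5%;
raising `oversampling` removes this at quadratic cost. The model is
monochromatic (default 0.52 µm, GFP-like emission), with no refractive-index
mismatch or aberration terms. Emission wavelength, camera pixel pitch
(10 µm) and medium index (1.33) are assumptions, flagged as such in the PSF
file metadata: the imaging hardware they describe does not pin them down
here.

**Geometric fallback.** `psf_model="geometric"` replaces the wave
computation with a ray-optics heuristic: per-lenslet energy weights from a
Gaussian blur-disc model at the MLA plane, per-lenslet sensor spots at the
chief-ray position with a width combining the defocus-imaging blur and the
lenslet diffraction spot. Because the per-axis construction is separable the
kernel is a rank-1 outer product — orders of magnitude cheaper. It preserves
the qualitative structure (footprint growth with |z|, sub-lenslet phase
dependence, energy conservation to ~2%) and is used for smoke tests and the
contrast studies, never for resolution claims.

**Projector.** Forward and adjoint projections are direct scatter/gather
loops over (z-plane, sub-lenslet phase, lenslet), jit-compiled with numba.
The two directions share kernels, anchors and boundary clipping, so they are
exact adjoints — verified to 1e-5 relative by inner-product identity tests —
and the forward map is exactly linear and lattice-periodic.

## Reconstruction

Richardson–Lucy multiplicative updates with the sensitivity normalisation
`Aᵀ1`, started from a flux-matched uniform volume (deterministic), with the
denominator clamped at 1e-12 of its maximum and early stop when the relative
change of the Poisson negative log-likelihood falls below 1e-6. Default 30
iterations. The reconstruction z-range is selected out of the PSF's planes
by `z_extent` / `z_sampling` / `z_center`; `z_extent` is validated against a
400 µm ceiling at ≥ 2 µm sampling, matching the largest volume the original
GPU pipeline handled. Camera dark counts can be removed beforehand by scalar
or dark-frame subtraction clipped at zero. Grid-like artifacts concentrated
around the native focal plane are an expected feature of light-field
deconvolution; nothing here attempts to suppress them, and quantitative
comparisons exclude |z| ≤ 10 µm for that reason.

**Rectification.** Lenslet spots of a uniform-illumination calibration frame
are detected, refined to sub-pixel centroids (background-subtracted centre
of mass), assigned integer lattice indices against the nearest detected spot
to the cloud centre, and fit by least squares; the fitted 2×2 lattice matrix
is projected by SVD onto rotation × isotropic scale to read off sub-pixel
pitch and rotation (recovered to 0.02 px / 0.05° on synthetic grids, with or
without 1% multiplicative noise). Resampling onto the integer lenslet grid
uses bilinear interpolation scaled by the Jacobian, conserving total
intensity to < 0.5% for interior content.

## What the bead round trip measures

The resolution protocol simulates a 0.5 µm bead ~20 µm off the native focal
plane, forms its noiseless light-field image with the wave-optics PSF, and
reconstructs with 30 RL iterations at 2 µm z-sampling. Its output must be
read carefully: **on an isolated point source the width of the converged RL
point image is a localization quantity, not a two-point resolution**. With
exact model match and no background, successive multiplicative updates keep
contracting the point image (measured at 32×/0.8: lateral/axial FWHM
4.7/11.3 µm after 1 iteration, 2.5/6.0 after 4, 1.2/2.6 after 30); photon
noise at realistic budgets leaves the converged width essentially unchanged,
while volumetric background stalls it at a broader plateau. Nominal system
resolution figures for these optics (~3/6 µm at 32×/0.8, ~4/12 µm at
20×/0.5) describe the band limit of the optical train and are approached by
the RL point image only at few iterations; after 30 the reconstruction
localises the bead more tightly than the band limit, so the reported FWHMs
(≈1.2/2.6 µm and ≈1.6/4.3 µm) sit below those nominal figures. The ratios
between lateral and axial widths and between the two configurations track
the optics as expected. A depth-dependent band-limiting filter applied to
the PSF would pin the point image at the nominal resolution independent of
iteration count; it is not implemented because its exact reference
definition is not available, and an invented one would be arbitrary.

**Problem sizes.** The round trip runs on a 15×15-lenslet field with 25
reconstruction planes (z ∈ [−46, +2] µm) in the reproduction script and an
11×11 field in the test suite; the measured FWHMs are insensitive to the
field size since the bead's sensor footprint fits either field.

## Phantoms and study conditions

All generators are pure functions of (parameters, seed); geometry and noise
draw from independently derived substreams (crc32-named children of the
seed), so the same call is bit-reproducible.

* **Beads**: Gaussian blobs with FWHM equal to the stated diameter (0.5 µm
  beads are sub-voxel and act as point emitters), placed uniformly inside a
  margin.
* **Vessels**: smooth cubic-spline tubes (or straight axial tubes) of
  constant circular cross-section, anti-aliased over one lateral voxel so a
  cross-section FWHM equals the diameter to within half a voxel; 5 µm
  diameter by default, matching small blood vessels.
* **Nuclei**: static ellipsoids (5 µm lateral / 10 µm axial FWHM, the
  effective size of nuclear-localised indicators in these reconstructions)
  whose traces are `baseline + amplitude · (Poisson spike train ⊛ one-sided
  exponential)`; decay 1.5 s (GCaMP6s-like), firing 0.1 Hz, 100 frames at
  1 volume/s — spontaneous-activity-like conditions; a configurable fraction
  of cells is silent.
* **Flow**: particles advected through a supplied velocity field (Euler step
  per frame, exact for uniform flow), e.g. 40 µm/s at 20 volumes/s.
* **Illumination**: a selective slab with raised-cosine edges whose 10–90%
  falloff is `edge_width` (default 5 µm; 0 gives sharp edges), or unit
  wide-field weight. Two-photon excitation is represented only through its
  consequences (less out-of-slab background, no visually-driven always-on
  population), not as nonlinear optics.
* **Noise**: the image is rescaled so its mean photon count equals λ, then
  each pixel replaced by a Poisson draw — background noise spatially
  correlated with the image. λ = 8400 corresponds to a 300 µm illumination
  extent in the reference data; the lower levels used in the noise study
  (50, 500) probe the photon-sparse regime where the effect on
  reconstructions is visible at desk scale.

**Contrast-vs-extent study.** Vessels confined to |z| < 40 µm plus
out-of-slab "autofluorescent tissue" emitters (|z| > 55 µm, up to ±250 µm);
SVI-100 excites essentially none of the background, SVI-300 part of it,
wide-field all of it, and the per-slice reconstruction contrast orders
accordingly at every |z| > 10 µm. **Contrast-vs-noise study.** A dense scene
(vessels over diffuse tissue) so the shot-noise speckle reprojected by RL is
measurable against structural contrast; contrast then decreases strictly as
λ grows toward the noiseless limit.

What passing these synthetic studies shows: the implemented chain responds
to illumination extent and photon budget in the directions and orderings
expected from the physics. What it does not show: quantitative agreement
with any particular animal dataset — the phantoms have no scattering, no
anatomy, no photobleaching and no motion.

## Analysis defaults

* **Contrast**: sample (N−1) standard deviation over mean; scale- and
  permutation-invariant, independent of pixel count; slices with zero mean
  are flagged NaN, never fabricated. The 12-plane moving average matches a
  finely-sampled stack to the ~12 µm axial response of the light-field
  modality before comparison. Images may be 16-bit rescaled for
  presentation; scale invariance makes this irrelevant to the metric, and
  the display-only percentile stretch (0.4% saturation) lives in
  `svim.display`, outside every quantitative path.
* **FWHM**: baseline = median of the outer 20% of the profile, peak
  normalised to 1, crossings nearest the peak by linear interpolation.
* **Segmentation**: single-scale anisotropy-normalised Laplacian-of-Gaussian
  at the (5, 10) µm ellipsoid, response calibrated so a matched
  unit-amplitude blob scores 1; threshold by Otsu over the positive response
  (assumes a clear background population — override `threshold` on difficult
  data, and use a fixed threshold when comparing counts across noise
  levels); greedy non-maximum suppression in the ellipsoid-normalised metric
  forbids centres closer than one diameter; sub-voxel refinement by local
  centre of mass.
* **ΔF/F₀**: F₀ defaults to the 20th percentile over a rolling 60 s window
  (robust to drift); fixed-percentile and pre-stimulus-mean alternatives are
  selectable. Masks with ~zero baseline are flagged invalid rather than
  emitted as infinities. The seconds-to-frames convention is inclusive:
  frame i covers [i·Δt, (i+1)·Δt), so a window of t = 1–100 s at 1 volume/s
  is exactly frames 1..100.
* **Clustering / evoked**: k-means on z-scored traces, 10 seeded restarts
  (k: caller-chosen, 5 is a reasonable default for brain-wide recordings);
  the cluster with the largest post-onset mean increase is flagged evoked
  only if the increase exceeds 3 pre-onset standard deviations, and at most
  one cluster is flagged. Note z-scoring removes pure amplitude differences
  between otherwise identical response shapes.
* **Tracking**: optimal bipartite matching per frame pair (cost = squared
  displacement, hard cutoff at `max_displacement`, maximum cardinality then
  minimum cost — equal to brute-force enumeration on small instances); no
  gap closing (a missed detection ends a track); minimum track length 3.
  Speeds are per step; smoothing is left to the caller.

## Known limitations

* No scattering, aberrations, index mismatch or vectorial effects in the
  PSF; no multi-view or Fourier-domain light-field geometries.
* The geometric PSF model is a documented heuristic: adequate for ordering
  and smoke tests, not for resolution quantification.
* The bead round trip reports RL localization width, not band-limited system
  resolution (see above).
* Spot segmentation with the adaptive Otsu threshold over-detects on
  noise-dominated volumes; cross-condition comparisons must fix the
  threshold.
* No motion correction or registration anywhere in the activity pipeline
  (appropriate for embedded, stationary samples only).
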