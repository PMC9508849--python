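# Methods

## Scope and conventions

`exepi` analyses multi-channel 3D fluorescence z-stacks of cell nuclei:
one nuclear-stain channel (DAPI), one punctate epigenetic-reader channel,
and one histone-mark ("marker") channel. Arrays are indexed
`(channel, z, y, x)`, 0-based; sub-pixel coordinates are continuous in
voxel units with voxel centers at integers; physical position is
`index × spacing`. Anisotropy (`dz ≠ dx`) is handled in every distance
computation, never by resampling — the target stacks are thin (9–11
slices at a 0.2 µm z-step) and interpolating across such stacks creates
artifacts. Intensities are arbitrary units and are never compared across
channels. Inputs are assumed registered; geometry supplied explicitly
always overrides file metadata (with a logged warning), and reading fails
rather than guessing when neither source provides voxel sizes.

## Nuclear segmentation and rim distances

The nuclear-stain channel is Gaussian-smoothed (default σ = 2 px lateral,
scaled by dx/dz axially — expansion makes the stain texture coarse, and
the smoothing keeps Otsu's threshold on the nucleus/background split
rather than on chromatin texture), thresholded by Otsu over the whole
stack, hole-filled per slice, labelled in 3D, and filtered by a minimum
volume (default 5 µm³ at the test scale). Labels are assigned in raster
order of centroids (coarse 8-voxel binning absorbs sub-voxel jitter
between tied nuclei). The nuclear rim is the mask boundary, not an
intensity isocontour. Rim distances are the exact anisotropic Euclidean
distance transform (sampling = (dz, dy, dx)), verified against exhaustive
nearest-exterior-voxel search; a per-slice 2D mode is available because
thin stacks truncate nuclei axially, which caps 3D distances at the
imaged slab — the pipeline propagates this caveat into its summary
output. Cells touching a lateral stack border are excluded from spatial
analysis by default: a stack border is not a rim.

## Spot detection and localization

Candidates are strict 3D local maxima of the channel convolved with a
Gaussian matched filter (σ = FWHM/2.355 laterally, 0.5 slices axially),
scored by a peak-significance statistic: the squared filter response
above the local filtered median, normalized by the matched-filter noise
level. The noise level is estimated robustly — median/MAD of the *raw*
channel in the locROI window — and propagated through the filter's
analytic noise gain (the L2 norm of its impulse response). Estimating
noise on the filtered image directly would fail here: a filtered spot's
tails fill the locROI window and masquerade as noise. The statistic is
invariant to intensity offset and scale; `chi2_threshold` thresholds it.
Non-maximum suppression (greedy, Euclidean, ties broken toward the
lexicographically smallest position) enforces `min_separation`
(default locROI/2).

Accepted candidates are refined by least-squares fitting of a symmetric
2D Gaussian plus constant offset in the locROI window on the brightest
slice; the axial position comes from a 3-point parabolic fit of the
filtered z-profile. A full 3D Gaussian fit is deliberately avoided: at a
0.2 µm z-step over 9–11 slices the axial PSF is under-sampled and 3D
fits are ill-conditioned. Fits are dropped (with logged reasons) on
non-convergence, non-positive amplitude, escape from the window,
degenerate width, clipping by the stack border, a fitted center outside
the nucleus, or an RMS residual above 0.33 × amplitude — the last bound
requires a peak to stand ~3× above its own fit noise and rejects fits
that latch onto background fluctuations. Two parameter presets mirror
the two sampling regimes: `pre-expansion` (locROI 10, chi2 15, FWHM 2)
and `post-expansion` (locROI 20, chi2 70, FWHM 10); the synthetic
fixtures use (9, 25, 3.3), matched to the generator's PSF. On planted
emitters at peak SNR 10 the detector achieves recall ≥ 0.95, precision
≥ 0.98 and lateral RMS localization error ~0.12 px.

## The co-localization test

Marker intensity at a position is read as the mean over a lateral disc
(default radius 2 px ≈ FWHM/2 of the fixture spots; radius 0 reads one
voxel) on the nearest z-slice. One reference sample per cell and channel
is drawn: `n_random` (default 10,000, giving p-value granularity 10⁻⁴ ≪ α)
locations uniform with replacement over mask voxels whose readout disc
lies inside the mask; spots are not excluded from the support (their
volume fraction is negligible at realistic densities). The p-value uses
the add-one correction and counts ties toward the tail, so it is strictly
positive and super-uniform under the null at finite n — the conservative
choice for discrete intensity images. No multiple-testing correction is
applied across spots: the method thresholds raw p at α and absorbs false
positives into the background estimate, which the rotation control
quantifies and which is reported alongside every condition. The ratio
R = 100·n_coloc/(n_total − n_coloc) is undefined when every spot
co-localizes; that case is flagged, not silently patched. The reversed
(marker-anchored) analysis is the same code path with the channel roles
exchanged.

## Synthetic data: what it emulates, and what it does not

The generator plants everything the analysis assumes and nothing more:

* **Nucleus** — an analytic ellipsoid (voxel-center test), so
  segmentation accuracy is exactly measurable. The nuclear stain is a
  smooth multiplicative random field (correlation length 0.3 µm,
  contrast 0.25) over an interior level of 120 on background 8.
* **Reader** — `n` Gaussian emitters (σ = (0.9, 1.4, 1.4) voxels) of
  amplitude 40 over background 12, placed uniformly in the margin-eroded
  mask with a minimum pairwise separation by bounded rejection (an
  explicit error on infeasible packing). With Gaussian read noise σ = 4
  this is peak SNR 10.
* **Marker** — a Gaussian random field (spectral filtering of white
  noise; correlation length 0.25 µm, mean 100, variance 1600, clipped at
  zero) reproducing the strong intensity fluctuations of nuclear
  histone-mark stains that defeat voxel-correlation measures. Planted
  co-localization adds a Gaussian bump of peak height
  `enrichment × texture SD` with the imaging PSF width at a
  deterministic seeded subset of exactly `round(f·n)` emitters — an
  intensity boost at the spot location, never a copied channel, because
  the statistic under test is intensity-at-location.
* **Noise** — optional scaled-Poisson shot noise plus Gaussian read
  noise, per channel, clipped at zero.

All randomness derives from one integer seed via `SeedSequence` spawning
with a fixed substream order, so stacks are bit-reproducible.

Two fixture regimes are used. The *dense* default (200 emitters,
96×96×11 voxels at dx = 0.06 µm, dz = 0.2 µm, expansion factor 3.5)
matches the thin-stack geometry while staying seconds-fast, and serves
the null calibration, where no enrichment exists. The *sparse-loci*
fixture (50 emitters, 11×288×288, lateral semi-axis 7.6 µm) serves
planted-signal recovery, the rotation control, and the PCC contrast: the
rotation null and the "every planted spot flagged" idealization are
valid only when enriched loci occupy a negligible fraction of the
nuclear volume, which is the situation in real nuclei (a nucleus is
orders of magnitude larger than a binding locus) but not in the dense
miniature cell, where bumps would cover most of the support and
contaminate the reference distribution. Neither fixture is optically
realistic (no aberrations, depth-dependent PSF, or gel distortion), and
the default nucleus is a miniature that fits the test stack — a real
HeLaP4 nucleus (radius ≈ 6 µm, ~21 µm across after 3.5× expansion) needs
correspondingly larger stacks. Passing tests therefore demonstrate the
statistical machinery, not robustness to optical artifacts.

## Spatial analysis

Rim distances are read from the precomputed distance map by trilinear
interpolation at the sub-pixel spot position (nearest-voxel mode
available) and divided by the expansion factor (a per-sample scalar,
default 3.5; per-cell estimation is out of scope). Radial distributions
are summarized by the median and the density peak — the argmax of a
Gaussian KDE with Silverman bandwidth on [0, max distance]; the peak
needs ≥ 5 records and non-zero spread, otherwise it is flagged
undefined. For spots uniform in a sphere the rim-distance density is
∝ (R−d)², maximal at the rim; the pipeline reproduces this on
simulation.

## Statistics

Group comparison is a standard one-way ANOVA with Holm-adjusted pairwise
t-tests and the usual significance tiers (ns, <0.05, <0.01, <0.001);
degenerate all-constant input yields F = 0, p = 1 exactly. PCC is
Pearson correlation over mask voxels, undefined (NaN, logged) at zero
variance.

Dose-response fitting uses the four-parameter logistic
`R(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)`, least squares on
per-dose means weighted by their standard errors (unweighted when SEs
are not estimable; a per-cell mode exists). Zero-dose observations are
not forced onto a log axis: at c = 0 the model equals `top`, so the
0 nM arm enters the fit directly and anchors the upper plateau. The
Hill slope is free by default and can be fixed. A fit is flagged
unidentifiable when the response is flat relative to noise, the IC50
lands far beyond the dose range, or its relative standard error exceeds
one.

**Identifiability of the IC50 under partial inhibition.** With the
six-dose 0–500 nM design and plateaus 15.88 → ~8 R at IC50 137 nM, the
response at the top dose (~9.7 R) never reaches the lower plateau, so
`bottom` and IC50 are nearly collinear. The Gauss–Newton information
matrix gives σ_log(IC50) ≈ 0.18 at per-cell SD 1.5 with 50 cells/dose
even with the Hill slope fixed — i.e. ~±18% is the best any estimator
can do at that noise, and the package's fit attains it (cross-checked
against an independent nonlinear least-squares implementation). The
recovery experiment in the validation suite therefore runs at per-cell
SD 0.3, the level at which the same design identifies the IC50 to
within 10%; the high-noise regime is characterized separately. Real
titrations with cell-to-cell spreads of ~3 R should expect IC50
confidence intervals of several tens of percent, or should extend the
dose range until the lower plateau is reached.

## Validation experiments

`exepi.validation` (driven by `scripts/acceptance.py` and the test
suite) measures, from scratch at run time: type-I calibration (flagged
fraction at f = 0 within the 95% binomial CI of α = 0.05, pooled
p-values super-uniform); monotone planted-signal recovery over
f ∈ {0, 0.25, 0.5, 0.75, 1} with saturation > 0.95 at f = 1; the
rotation control returning to the α floor while the forward analysis
stays at the planted level; detector recall/precision/localization at
SNR 10; noiseless 4PL self-consistency to 10⁻⁶ relative and the IC50
recovery rate; and the PCC contrast (|PCC| < 0.1 on fixtures where the
spot-level statistic flags > 50% of spots). Problem sizes per
experiment: 25–50 cells for calibration, 15 sparse cells for recovery,
20–30 for the rotation control, 8–10 for detection, 30–50 dose-response
seeds — sizes at which the binomial confidence intervals the assertions
use are decisive.

## Known limitations

* Axial localization is a parabolic refinement, not a PSF fit; axial
  precision is slice-limited.
* Touching nuclei are not split (no watershed); they fail the
  single-component assumption and merge.
* The rotation control assumes the rotated nuclear support overlaps the
  original (whole-image rotations of registered single-cell crops); the
  synthetic default centers the nucleus so this holds exactly.
* Expansion is treated as a single global isotropic factor; local gel
  distortion is not modelled or corrected.
* Intensities are ranks to the statistic, but detection quality still
  depends on SNR; presets must match the sampling regime.
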